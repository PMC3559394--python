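"""Generator determinism, demographic fidelity and degenerate-case tests."""

import numpy as np
import pytest
from scipy import stats as sps

from pcmckit.ethogram_io import validate_dataset, write_dataset
from pcmckit.synthetic_colony import (
    ColonyConfig,
    ConfigError,
    ResponseModel,
    kin_matrix,
    simulate_affiliation,
    simulate_colony,
    simulate_observation,
    simulate_roster,
)


class TestRoster:
    def test_default_cells_give_36_study_subjects(self):
        roster = simulate_roster(ColonyConfig(), seed=0)
        non_infant = [i for i in roster.values() if not i.is_infant]
        assert len(non_infant) == 36
        assert len(roster) == 42

    def test_cell_counts_exact(self):
        cfg = ColonyConfig(groups={"g": {("F", "adult", "orphan"): 3,
                                         ("M", "juvenile", "mother_reared"): 2}})
        roster = simulate_roster(cfg, seed=1)
        counts = {}
        for ind in roster.values():
            counts[(ind.sex, ind.age_class, ind.rearing)] = (
                counts.get((ind.sex, ind.age_class, ind.rearing), 0) + 1
            )
        assert counts == cfg.groups["g"]

    def test_zero_individuals_empty_roster(self):
        assert simulate_roster(ColonyConfig(groups={"g": {}}), seed=0) == {}

    def test_same_seed_identical(self):
        a = simulate_roster(ColonyConfig(), seed=5)
        b = simulate_roster(ColonyConfig(), seed=5)
        assert a == b

    def test_mother_links_only_to_adult_females(self):
        roster = simulate_roster(ColonyConfig(), seed=2)
        for ind in roster.values():
            if ind.mother_id is not None:
                mother = roster[ind.mother_id]
                assert mother.sex == "F" and mother.age_class == "adult"
                assert ind.rearing == "mother_reared"

    def test_infeasible_kinship_is_config_error(self):
        cfg = ColonyConfig(groups={"g": {("M", "juvenile", "mother_reared"): 3,
                                         ("F", "adult", "orphan"): 1}})
        with pytest.raises(ConfigError, match="mother-offspring"):
            simulate_roster(cfg, seed=0)


class TestAffinity:
    def test_symmetric_and_bounded(self):
        roster = simulate_roster(ColonyConfig(), seed=3)
        aff = simulate_affiliation(roster, seed=3)
        assert np.allclose(aff.values, aff.values.T)
        off_diag = aff.values[~np.eye(len(aff.ids), dtype=bool)]
        assert ((off_diag > 0) & (off_diag < 1)).all()

    def test_kin_boost_raises_kin_affinity(self):
        roster = simulate_roster(ColonyConfig(), seed=4)
        kin = kin_matrix(roster, sorted(roster))
        kin_means, nonkin_means = [], []
        for seed in range(1, 21):
            aff = simulate_affiliation(roster, kin_boost=1.5, seed=seed)
            mask = ~np.eye(len(aff.ids), dtype=bool)
            kin_means.append(aff.values[kin & mask].mean())
            nonkin_means.append(aff.values[~kin & mask].mean())
        assert np.mean(kin_means) > np.mean(nonkin_means) + 0.1

    def test_zero_kin_boost_removes_the_offset(self):
        roster = simulate_roster(ColonyConfig(), seed=4)
        kin = kin_matrix(roster, sorted(roster))
        diffs = []
        for seed in range(1, 21):
            aff = simulate_affiliation(roster, kin_boost=0.0, seed=seed)
            mask = ~np.eye(len(aff.ids), dtype=bool)
            diffs.append(aff.values[kin & mask].mean() - aff.values[~kin & mask].mean())
        assert abs(np.mean(diffs)) < 0.05


class TestObservation:
    def test_determinism_byte_identical_files(self, tmp_path):
        a, _, _ = simulate_colony(hours=20.0, seed=9)
        b, _, _ = simulate_colony(hours=20.0, seed=9)
        write_dataset(a, tmp_path / "a")
        write_dataset(b, tmp_path / "b")
        for name in ("roster.csv", "conflicts.csv", "follows.csv", "scans.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_generated_dataset_passes_validation(self, small_colony):
        ds, _, _ = small_colony
        exclusions = validate_dataset(ds)
        assert exclusions == ds.excluded

    def test_conflict_count_within_poisson_bound(self):
        # 40 h at 0.8/h: Poisson mean 32, +/- 3 SD
        cfg = ColonyConfig(conflict_rate_per_h=0.8)
        for seed in range(1, 6):
            roster = simulate_roster(cfg, seed=seed)
            aff = simulate_affiliation(roster, seed=seed)
            ds = simulate_observation(roster, aff, cfg, ResponseModel(), 40.0,
                                      seed=seed)
            assert abs(len(ds.conflicts) - 32) <= 3 * np.sqrt(32)

    def test_class_shares_recovered(self, study_scale_colony):
        # pooled over three campaigns (~1100 conflicts) so the exact
        # binomial 99% check is not dominated by single-campaign noise
        datasets = [study_scale_colony[0]]
        for seed in (24, 25):
            datasets.append(simulate_colony(hours=453.0, seed=seed)[0])
        n = sum(len(ds.conflicts) for ds in datasets)
        assert n >= 300

        def share(role, age_class, sex):
            return sum(
                1
                for ds in datasets
                for c in ds.conflicts.values()
                if ds.individuals[getattr(c, role)].age_class == age_class
                and ds.individuals[getattr(c, role)].sex == sex
            )

        for role, age_class, sex, p in (
            ("victim_id", "adolescent", "M", 0.331),
            ("victim_id", "juvenile", "F", 0.325),
            ("aggressor_id", "adult", "F", 0.512),
            ("aggressor_id", "adult", "M", 0.254),
        ):
            k = share(role, age_class, sex)
            lo, hi = sps.binom.interval(0.99, n, p)
            assert lo <= k <= hi, (role, age_class, sex, k / n)

    def test_intensity_distribution_follows_config(self, study_scale_colony):
        ds, _, truth = study_scale_colony
        counts = np.bincount([c.intensity for c in ds.conflicts.values()],
                             minlength=7)[1:]
        probs = np.array(truth["colony"]["intensity_probs"])
        probs = probs / probs.sum()
        # chi-square goodness of fit should not reject wildly
        chi2 = (((counts - len(ds.conflicts) * probs) ** 2)
                / (len(ds.conflicts) * probs)).sum()
        assert chi2 < sps.chi2.ppf(0.999, df=5)

    def test_consolation_impossible_gives_no_bystander_contacts(self):
        response = ResponseModel(consolation_intercept=-50.0,
                                 victim_initiation_prob=0.0,
                                 reconciliation_intercept=-50.0)
        ds, _, _ = simulate_colony(response=response, hours=30.0, seed=3)
        for _, pc, _ in ds.retained_pairs():
            assert all(c.recipient_id != pc.focal_id for c in pc.contacts)

    def test_null_model_equalises_scratch_rates(self):
        response = ResponseModel.null()
        pc_rates, mc_rates = [], []
        for seed in range(1, 6):
            ds, _, _ = simulate_colony(response=response, hours=60.0, seed=seed)
            for _, pc, mc in ds.retained_pairs():
                pc_rates.append(sum(1 for s in pc.self_directed
                                    if s.kind == "scratch_bout") / 10.0)
                mc_rates.append(sum(1 for s in mc.self_directed
                                    if s.kind == "scratch_bout") / 10.0)
        # equal rates 0.37/min: means agree within Monte-Carlo error
        se = np.sqrt(0.37 / 10.0 / len(pc_rates)) * 2
        assert abs(np.mean(pc_rates) - np.mean(mc_rates)) < 3 * se

    def test_nonpositive_hours_rejected(self):
        cfg = ColonyConfig()
        roster = simulate_roster(cfg, seed=0)
        aff = simulate_affiliation(roster, seed=0)
        with pytest.raises(ConfigError, match="hours"):
            simulate_observation(roster, aff, cfg, ResponseModel(), 0.0, seed=0)

    def test_mc_failure_fraction_excludes_pairs(self, study_scale_colony):
        ds, _, _ = study_scale_colony
        n_pc = len(ds.follows_by_kind("PC"))
        n_retained = len(ds.retained_pairs())
        assert 0 < n_pc - n_retained < 0.15 * n_pc
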