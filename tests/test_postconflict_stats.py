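"""Wilcoxon, log-rank and stress-proxy tests, each against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pcmckit.ethogram_io import SelfDirectedEvent
from pcmckit.pcmc import (
    CONSOLATION_ANY,
    RECONCILIATION,
    RelationshipSelector,
    label_dataset,
)
from pcmckit.postconflict_stats import (
    bonferroni_alpha,
    logrank_compare,
    mc_contact_control,
    stress_rates,
    wilcoxon_paired,
)
from pcmckit.synthetic_colony import ResponseModel, simulate_colony

from conftest import make_pair_dataset


def exact_wilcoxon_oracle(a, b):
    """Two-tailed signed-rank p by explicit enumeration of all sign patterns."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


class TestWilcoxon:
    def test_identical_vectors(self):
        res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z == 0.0 and res.p == 1.0 and res.undefined

    def test_uniform_dominance_gives_minimal_p(self):
        a = np.arange(1.0, 21.0)
        res = wilcoxon_paired(a + 1.0, a)
        # all 20 differences positive: exact minimal two-sided p = 2 * 2^-20
        assert res.p == pytest.approx(2.0 * 0.5**20)
        assert res.z > 3.5

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for n in range(2, 11):
            for rep in range(6):
                a = rng.integers(0, 6, size=n).astype(float)
                b = rng.integers(0, 6, size=n).astype(float)
                if np.all(a == b):
                    continue
                res = wilcoxon_paired(a, b)
                assert res.p == pytest.approx(exact_wilcoxon_oracle(a, b)), (a, b)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        res = wilcoxon_paired(a, b, exact_threshold=0)
        ref = sps.wilcoxon(a, b, zero_method="wilcox", correction=False,
                           method="approx")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)
        assert abs(res.z) == pytest.approx(abs(ref.zstatistic), rel=1e-10)

    def test_sign_convention(self):
        a = np.arange(1.0, 16.0)
        res = wilcoxon_paired(a - 1.0, a)   # a systematically below b
        assert res.z < 0


class TestLogrank:
    def _records(self, pc_lats, mc_lats):
        from pcmckit.pcmc import PairRecord, classify_pair
        return [
            PairRecord(i, "v", None, pc, mc, classify_pair(pc, mc))
            for i, (pc, mc) in enumerate(zip(pc_lats, mc_lats))
        ]

    def test_identical_arms_give_zero(self):
        lats = [10.0, 50.0, None, 300.0, None, 90.0]
        res = logrank_compare(self._records(lats, lats), fit_curves=False)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_maximal_separation(self):
        res = logrank_compare(
            self._records([1.0] * 20, [None] * 20), fit_curves=False)
        assert res.p < 0.001 and res.chi2 > 10

    def test_textbook_example_hand_computed(self):
        # PC events at 1,2,3 s; MC events at 4,5,6 s; no censoring.
        # By the Mantel-Cox formula: O_PC=3, E_PC=1/2+2/5+1/4=1.15,
        # V=0.25+0.24+0.1875=0.6775, chi2=(3-1.15)^2/0.6775.
        res = logrank_compare(
            self._records([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]), fit_curves=False)
        assert res.chi2 == pytest.approx(3.4225 / 0.6775, abs=1e-6)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        pc = [float(t) if t < 600 else None
              for t in rng.exponential(200, size=30)]
        mc = [float(t) if t < 600 else None
              for t in rng.uniform(0, 900, size=30)]
        a = logrank_compare(self._records(pc, mc), fit_curves=False)
        b = logrank_compare(self._records(mc, pc), fit_curves=False)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-9)

    def test_all_censored_undefined(self):
        with pytest.raises(ValueError, match="censored"):
            logrank_compare(self._records([None] * 5, [None] * 5),
                            fit_curves=False)

    def test_survival_curves_returned(self):
        res = logrank_compare(
            self._records([1.0, 2.0, None], [None, 5.0, 6.0]))
        assert res.km_pc is not None and res.km_mc is not None
        assert res.km_pc["PC"].iloc[-1] <= 1.0


class TestBonferroni:
    def test_three_comparisons_truncates_to_printed_alpha(self):
        assert bonferroni_alpha(0.05, 3) == 0.016

    def test_other_counts(self):
        assert bonferroni_alpha(0.05, 4) == 0.012
        assert bonferroni_alpha(0.05, 1) == 0.05


class TestStressRates:
    def test_rate_arithmetic(self):
        scratch = [SelfDirectedEvent(t, "scratch_bout") for t in
                   (10.0, 50.0, 99.0, 200.0, 340.0, 590.0)]
        groom = [SelfDirectedEvent(100.0, "groom_interval", 60.0)]
        ds = make_pair_dataset([], [], pc_self=scratch + groom, mc_self=[])
        consol = label_dataset(ds, RelationshipSelector(CONSOLATION_ANY))
        recon = label_dataset(ds, RelationshipSelector(RECONCILIATION))
        report = stress_rates(ds, consol, recon)
        pc_row = report.rates.xs("PC_no_affiliation", level="condition")
        assert pc_row["scratch_rate"].iloc[0] == pytest.approx(0.6)
        assert pc_row["groom_rate"].iloc[0] == pytest.approx(6.0)

    def test_outcome_categories_partition_pairs(self, small_colony):
        ds, _, _ = small_colony
        consol = label_dataset(ds, RelationshipSelector(CONSOLATION_ANY))
        recon = label_dataset(ds, RelationshipSelector(RECONCILIATION))
        report = stress_rates(ds, consol, recon)
        assert sum(report.outcome_counts.values()) == len(ds.retained_pairs())
        assert report.alpha_corrected == 0.016

    def test_consoled_pcs_scratch_least(self):
        response = ResponseModel(scratch_rate_pc=0.4, scratch_rate_mc=0.4,
                                 scratch_rate_pc_consoled=0.19)
        for seed in (1, 2, 3):
            ds, _, _ = simulate_colony(response=response, hours=120.0, seed=seed)
            consol = label_dataset(ds, RelationshipSelector(CONSOLATION_ANY))
            recon = label_dataset(ds, RelationshipSelector(RECONCILIATION))
            means = stress_rates(ds, consol, recon).condition_means["scratch_rate"]
            assert means["PC_consolation"] < means["MC"]
            assert means["PC_consolation"] < means["PC_no_affiliation"]


class TestMcContactControl:
    def test_null_rates_give_nonsignificant_result(self, small_colony):
        # contacts are independent of scratch in the generator's MC stream
        ds, _, _ = small_colony
        res, table = mc_contact_control(ds)
        assert res.n_effective >= 2
        assert res.p > 0.01

    def test_type_one_error_calibrated(self):
        # independent normal rates per focal: rejection rate ~ alpha
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            if wilcoxon_paired(a, b).p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.01 <= rate <= 0.10
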