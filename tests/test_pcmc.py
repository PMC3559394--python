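"""Labeling engine: latencies, attracted/dispersed classification, tendencies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcmckit.pcmc import (
    ATTRACTED,
    CONSOLATION_ANY,
    CONSOLATION_SPECIFIC,
    DISPERSED,
    NEUTRAL,
    RECONCILIATION,
    RelationshipSelector,
    classify_pair,
    consolation_index,
    eligible_bystanders,
    first_contact_latency,
    label_bystander_pairs,
    label_dataset,
    tct,
    tendency_scores,
)
from pcmckit.synthetic_colony import ResponseModel, simulate_colony

from conftest import make_pair_dataset


def _pair_parts(ds):
    conflict = ds.conflicts[1]
    pc = ds.follows_by_kind("PC")[1]
    mc = ds.follows_by_kind("MC")[1]
    return conflict, pc, mc


class TestFirstContactLatency:
    def test_victim_initiated_contact_is_not_consolation(self):
        ds = make_pair_dataset(
            pc_contacts=[(45.0, "B1", "V", "touch"), (20.0, "V", "B1", "groom")],
            mc_contacts=[],
        )
        conflict, pc, _ = _pair_parts(ds)
        sel = RelationshipSelector(CONSOLATION_ANY)
        assert first_contact_latency(pc, conflict, sel) == 45.0

    def test_no_contacts_is_censored(self):
        ds = make_pair_dataset([], [])
        conflict, pc, _ = _pair_parts(ds)
        assert first_contact_latency(pc, conflict,
                                     RelationshipSelector(CONSOLATION_ANY)) is None

    def test_minimum_of_qualifying_contacts(self):
        ds = make_pair_dataset(
            pc_contacts=[(30.0, "B1", "V", "embrace"), (12.0, "B2", "V", "touch")],
            mc_contacts=[],
        )
        conflict, pc, _ = _pair_parts(ds)
        assert first_contact_latency(pc, conflict,
                                     RelationshipSelector(CONSOLATION_ANY)) == 12.0

    def test_reconciliation_counts_either_direction(self):
        ds = make_pair_dataset(
            pc_contacts=[(50.0, "V", "A", "groom"), (80.0, "A", "V", "touch")],
            mc_contacts=[],
        )
        conflict, pc, _ = _pair_parts(ds)
        assert first_contact_latency(pc, conflict,
                                     RelationshipSelector(RECONCILIATION)) == 50.0

    def test_specific_bystander_filter(self):
        ds = make_pair_dataset(
            pc_contacts=[(30.0, "B1", "V", "embrace"), (12.0, "B2", "V", "touch")],
            mc_contacts=[],
        )
        conflict, pc, _ = _pair_parts(ds)
        sel = RelationshipSelector(CONSOLATION_SPECIFIC, "B1")
        assert first_contact_latency(pc, conflict, sel) == 30.0


class TestClassifyPair:
    @pytest.mark.parametrize(
        "pc,mc,expected",
        [
            (45.0, None, ATTRACTED),
            (None, None, NEUTRAL),
            (30.0, 30.0, NEUTRAL),
            (None, 45.0, DISPERSED),
            (10.0, 400.0, ATTRACTED),
            (400.0, 10.0, DISPERSED),
            (30.2, 30.4, NEUTRAL),  # same second at 1-s resolution
        ],
    )
    def test_examples(self, pc, mc, expected):
        assert classify_pair(pc, mc) == expected

    @given(
        pc=st.one_of(st.none(), st.floats(0, 600)),
        mc=st.one_of(st.none(), st.floats(0, 600)),
    )
    @settings(derandomize=True, max_examples=200)
    def test_antisymmetry(self, pc, mc):
        flipped = {ATTRACTED: DISPERSED, DISPERSED: ATTRACTED, NEUTRAL: NEUTRAL}
        assert classify_pair(mc, pc) == flipped[classify_pair(pc, mc)]


class TestLabelDataset:
    def test_identical_streams_all_neutral(self):
        contacts = [(45.0, "B1", "V", "touch"), (200.0, "A", "V", "groom")]
        ds = make_pair_dataset(pc_contacts=contacts, mc_contacts=contacts)
        for mode in (CONSOLATION_ANY, RECONCILIATION):
            records = label_dataset(ds, RelationshipSelector(mode))
            assert [r.label for r in records] == [NEUTRAL]

    def test_conservation_on_simulated_data(self, small_colony):
        ds, _, _ = small_colony
        n = len(ds.retained_pairs())
        for mode in (CONSOLATION_ANY, RECONCILIATION):
            records = label_dataset(ds, RelationshipSelector(mode))
            counts = {ATTRACTED: 0, DISPERSED: 0, NEUTRAL: 0}
            for r in records:
                counts[r.label] += 1
            assert sum(counts.values()) == n

    def test_no_mc_contacts_means_no_dispersed(self):
        response = ResponseModel()
        response.p_mc_contact = 1e-9
        response.p_mc_opponent_contact = 1e-9
        response.victim_initiation_prob = 0.0
        ds, _, _ = simulate_colony(response=response, hours=40.0, seed=7)
        records = label_dataset(ds, RelationshipSelector(CONSOLATION_ANY))
        assert all(r.label != DISPERSED for r in records)

    def test_swapping_streams_swaps_labels(self, small_colony):
        ds, _, _ = small_colony
        before = {r.conflict_id: r.label
                  for r in label_dataset(ds, RelationshipSelector(CONSOLATION_ANY))}
        swapped = ds.canonicalize()
        pcs = swapped.follows_by_kind("PC")
        mcs = swapped.follows_by_kind("MC")
        for cid in pcs:
            if cid in mcs:
                pcs[cid].contacts, mcs[cid].contacts = \
                    mcs[cid].contacts, pcs[cid].contacts
        after = {r.conflict_id: r.label
                 for r in label_dataset(swapped, RelationshipSelector(CONSOLATION_ANY))}
        flipped = {ATTRACTED: DISPERSED, DISPERSED: ATTRACTED, NEUTRAL: NEUTRAL}
        assert after == {cid: flipped[lab] for cid, lab in before.items()}

    def test_labels_match_brute_force_oracle(self):
        # exhaustive per-pair re-derivation on many small colonies
        for seed in range(1, 51):
            ds, _, _ = simulate_colony(hours=6.0, seed=seed)
            records = label_dataset(ds, RelationshipSelector(CONSOLATION_ANY))
            by_cid = {r.conflict_id: r for r in records}
            for conflict, pc, mc in ds.retained_pairs():
                v, a = conflict.victim_id, conflict.aggressor_id
                lats = {}
                for name, follow in (("pc", pc), ("mc", mc)):
                    qualifying = sorted(
                        round(c.time_s)
                        for c in follow.contacts
                        if c.recipient_id == v and c.initiator_id not in (v, a)
                    )
                    lats[name] = qualifying[0] if qualifying else math.inf
                if lats["pc"] < lats["mc"]:
                    expected = ATTRACTED
                elif lats["pc"] > lats["mc"]:
                    expected = DISPERSED
                else:
                    expected = NEUTRAL
                assert by_cid[conflict.conflict_id].label == expected


class TestTendencies:
    @pytest.mark.parametrize("a,d,n,expected", [(5, 2, 10, 30.0), (4, 4, 9, 0.0),
                                                (7, 0, 7, 100.0), (0, 3, 6, -50.0)])
    def test_formula(self, a, d, n, expected):
        assert tct(a, d, n) == pytest.approx(expected)

    def test_zero_pairs_undefined(self):
        with pytest.raises(ValueError):
            tct(0, 0, 0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(derandomize=True, max_examples=100)
    def test_formula_identity_random_triples(self, a, d, neutral):
        n = a + d + neutral
        if n == 0:
            return
        assert tct(a, d, n) == pytest.approx(100.0 * (a - d) / n)

    def test_mean_tct_monotone_in_consolation_hazard(self):
        # raising the PC contact hazard (all else equal, common seeds)
        # should not lower the population mean contact tendency
        means = []
        for intercept in (-2.6, -1.75, -0.9):
            response = ResponseModel(consolation_intercept=intercept)
            tcts = []
            for seed in (1, 2, 3, 4, 5):
                ds, _, _ = simulate_colony(response=response, hours=60.0,
                                           seed=seed)
                recs = label_dataset(ds, RelationshipSelector(CONSOLATION_ANY))
                tcts.append(tendency_scores(recs, by="victim")["tct"].mean())
            means.append(np.mean(tcts))
        assert means[0] < means[1] < means[2]

    def test_per_victim_scores_sum_to_total(self, small_colony):
        ds, _, _ = small_colony
        records = label_dataset(ds, RelationshipSelector(CONSOLATION_ANY))
        scores = tendency_scores(records, by="victim")
        assert int(scores["n_pairs"].sum()) == len(records)
        assert ((scores["tct"] >= -100) & (scores["tct"] <= 100)).all()


class TestConsolationIndex:
    def test_handcrafted_fraction(self):
        ds = make_pair_dataset(
            pc_contacts=[(10.0, "B1", "V", "touch"), (40.0, "B2", "V", "embrace")],
            mc_contacts=[],
        )
        table = consolation_index(ds)
        row = table.set_index("bystander_id").loc["B1"]
        assert row["opportunities"] == 1
        assert row["consolation_index"] == 1.0
        row2 = table.set_index("bystander_id").loc["B2"]
        assert row2["consolation_index"] == 0.0  # present but not first

    def test_never_present_dyads_omitted(self):
        ds = make_pair_dataset(pc_contacts=[], mc_contacts=[],
                               bystanders=("B1",), mc_bystanders=("B1",))
        table = consolation_index(ds)
        assert "B2" not in set(table["bystander_id"])

    def test_matches_brute_force_on_simulated_colony(self, small_colony):
        ds, _, _ = small_colony
        table = consolation_index(ds)
        # oracle: recount opportunities and global-first events from raw logs
        opportunities, firsts = {}, {}
        for conflict, pc, mc in ds.retained_pairs():
            v, a = conflict.victim_id, conflict.aggressor_id
            eligible = eligible_bystanders(pc, mc, conflict)
            consolers = [(c.time_s, c.initiator_id) for c in pc.contacts
                         if c.recipient_id == v and c.initiator_id not in (v, a)]
            first = min(consolers)[1] if consolers else None
            for b in eligible:
                opportunities[(v, b)] = opportunities.get((v, b), 0) + 1
                if b == first:
                    firsts[(v, b)] = firsts.get((v, b), 0) + 1
        assert len(table) == len(opportunities)
        for row in table.itertuples(index=False):
            key = (row.victim_id, row.bystander_id)
            assert row.opportunities == opportunities[key]
            assert row.first_consoler_count == firsts.get(key, 0)

    def test_eligibility_requires_presence_in_both(self):
        ds = make_pair_dataset(pc_contacts=[], mc_contacts=[],
                               bystanders=("B1", "B2"), mc_bystanders=("B1",))
        records = label_bystander_pairs(ds)
        assert {r.bystander_id for r in records} == {"B1"}
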