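"""Dyadic affiliation indices from scan samples and covariate assembly.

The affiliation index of a dyad is the number of scans in which the two
were engaged in at least one of five affiliative states (grooming, contact
sitting, sitting within arm's reach, play, sexual contact), divided by the
number of scans in which both were present.  A scan contributes at most
one engagement per dyad regardless of how many states it shows ("any"
encoding, the default); a "sum" encoding that counts each engaged state is
available for sensitivity analyses.  Indices are log-transformed before
modelling so they approximate normality.

Kinship is coded as mother-offspring or none; no other pedigree links are
available for sanctuary-reared animals.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .ethogram_io import Dataset, Individual, ScanSample
from .pcmc import PairRecord, eligible_bystanders, ATTRACTED


class ConfigError(ValueError):
    pass


def kin_pairs(roster: dict[str, Individual]) -> set[frozenset[str]]:
    """Mother-offspring dyads (the only kinship the data can code)."""
    out = set()
    for ind in roster.values():
        if ind.mother_id is not None:
            out.add(frozenset((ind.id, ind.mother_id)))
    return out


def affiliation_matrix(
    scans: Iterable[ScanSample],
    ids: Optional[Iterable[str]] = None,
    method: str = "any",
) -> pd.DataFrame:
    """Per-dyad engagement and co-presence counts with the affiliation index.

    Returns one row per unordered dyad ever co-present, with columns
    ``id_a``/``id_b`` (sorted), ``engaged_scans``, ``copresent_scans`` and
    ``index``.  ``method="any"`` counts a scan once per engaged dyad;
    ``method="sum"`` counts every engaged state (the index may then exceed
    co-presence and is *not* bounded by 1, so "any" is the default).
    """
    if method not in ("any", "sum"):
        raise ConfigError(f"unknown affiliation encoding {method!r}")
    keep = set(ids) if ids is not None else None
    copresent: dict[tuple[str, str], int] = {}
    engaged: dict[tuple[str, str], int] = {}
    for scan in scans:
        present = sorted(scan.present_ids if keep is None
                         else scan.present_ids & keep)
        for a, b in itertools.combinations(present, 2):
            copresent[(a, b)] = copresent.get((a, b), 0) + 1
        counts: dict[tuple[str, str], int] = {}
        for x, y, _beh in scan.engaged:
            if keep is not None and (x not in keep or y not in keep):
                continue
            key = (min(x, y), max(x, y))
            counts[key] = counts.get(key, 0) + 1
        for key, k in counts.items():
            engaged[key] = engaged.get(key, 0) + (k if method == "sum" else 1)
    rows = [
        {
            "id_a": a,
            "id_b": b,
            "engaged_scans": engaged.get((a, b), 0),
            "copresent_scans": n,
            "index": engaged.get((a, b), 0) / n,
        }
        for (a, b), n in sorted(copresent.items())
    ]
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "engaged_scans", "copresent_scans", "index"]
    )


def default_epsilon(indices: Iterable[float]) -> float:
    """Half the smallest positive index — the zero-offset for the log transform."""
    positive = [x for x in indices if x > 0]
    return 0.5 * min(positive) if positive else 0.5


def log_transform(index, epsilon: Optional[float] = None):
    """``log(index + epsilon)``; monotone, finite at zero.

    When ``epsilon`` is omitted it defaults to half the smallest positive
    index in the input.
    """
    arr = np.asarray(index, dtype=float)
    if epsilon is None:
        epsilon = default_epsilon(arr.ravel())
    if epsilon <= 0:
        raise ConfigError("epsilon must be positive")
    return np.log(arr + epsilon)


class AffiliationLookup:
    """Dict-backed view of an affiliation table with a floor for unseen dyads."""

    def __init__(self, table: pd.DataFrame):
        self._idx = {
            (a, b): v
            for a, b, v in zip(table["id_a"], table["id_b"], table["index"])
        }
        positive = [v for v in self._idx.values() if v > 0]
        self.epsilon = 0.5 * min(positive) if positive else 0.5
        self.floor = min(self._idx.values()) if self._idx else 0.0

    def get(self, a: str, b: str) -> tuple[float, bool]:
        """(index, observed?) — unseen dyads get the floor and a flag."""
        key = (min(a, b), max(a, b))
        if key in self._idx:
            return self._idx[key], True
        return self.floor, False

    def log_index(self, a: str, b: str) -> tuple[float, bool]:
        value, seen = self.get(a, b)
        return math.log(value + self.epsilon), seen


def build_opportunity_table(
    dataset: Dataset,
    bystander_records: Iterable[PairRecord],
    reconciliation_records: Iterable[PairRecord],
    affiliation: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (retained conflict x eligible bystander) for the GLMM.

    The binary ``outcome`` is 1 iff that bystander's PC/MC pair label is
    attracted (the operational definition of consolation).  Covariates
    cover the conflict (context, intensity, reconciliation, redirection)
    and the social attributes of bystander, victim and their dyads.
    Dyads without scan co-presence receive the affiliation floor and are
    flagged in ``affil_missing``.
    """
    roster = dataset.individuals
    lookup = AffiliationLookup(affiliation)
    kin = kin_pairs(roster)
    label_by = {
        (r.conflict_id, r.bystander_id): r.label for r in bystander_records
    }
    recon_by = {r.conflict_id: r.label == ATTRACTED for r in reconciliation_records}
    rows = []
    for conflict, pc, mc in dataset.retained_pairs():
        bands = dict(conflict.bystanders)
        victim = roster[conflict.victim_id]
        aggressor = roster[conflict.aggressor_id]
        for bid in eligible_bystanders(pc, mc, conflict):
            label = label_by.get((conflict.conflict_id, bid))
            if label is None:
                continue
            by = roster[bid]
            la_bv, seen_bv = lookup.log_index(bid, victim.id)
            la_ba, seen_ba = lookup.log_index(bid, aggressor.id)
            la_va, seen_va = lookup.log_index(victim.id, aggressor.id)
            band = bands.get(bid, "gt10m")  # MC-only bystanders sit distal
            rows.append(
                {
                    "conflict_id": conflict.conflict_id,
                    "group_id": conflict.group_id,
                    "bystander_id": bid,
                    "victim_id": victim.id,
                    "aggressor_id": aggressor.id,
                    "outcome": int(label == ATTRACTED),
                    "proximity_band": band,
                    "prox_lt5m": float(band == "lt5m"),
                    "prox_5to10m": float(band == "5to10m"),
                    "bystander_age_class": by.age_class,
                    "bystander_juvenile": float(by.age_class == "juvenile"),
                    "bystander_adolescent": float(by.age_class == "adolescent"),
                    "bystander_sex_m": float(by.sex == "M"),
                    "bystander_mother_reared": float(by.rearing == "mother_reared"),
                    "victim_age_class": victim.age_class,
                    "victim_juvenile": float(victim.age_class == "juvenile"),
                    "victim_adolescent": float(victim.age_class == "adolescent"),
                    "victim_sex_m": float(victim.sex == "M"),
                    "victim_mother_reared": float(victim.rearing == "mother_reared"),
                    "kin_bystander_victim": float(frozenset((bid, victim.id)) in kin),
                    "kin_bystander_aggressor": float(frozenset((bid, aggressor.id)) in kin),
                    "log_affiliation_bv": la_bv,
                    "log_affiliation_ba": la_ba,
                    "log_affiliation_va": la_va,
                    "context_feed": float(conflict.context == "feed"),
                    "intensity": float(conflict.intensity),
                    "reconciliation": float(recon_by.get(conflict.conflict_id, False)),
                    "redirection": float(conflict.redirection_target is not None),
                    "affil_missing": float(not (seen_bv and seen_ba and seen_va)),
                }
            )
    return pd.DataFrame(rows)


def build_dyad_table(
    dataset: Dataset,
    dyad_scores: pd.DataFrame,
    consolation_idx: pd.DataFrame,
    affiliation: pd.DataFrame,
) -> pd.DataFrame:
    """Victim-bystander dyad table for the linear mixed models.

    Joins per-dyad contact tendency (from the specific-bystander labels)
    with the consolation index and the dyad's social covariates.  TCT and
    the consolation index are kept on their native scales (percent and
    fraction); the consolation index is also provided in percent for
    comparability with tendency coefficients.
    """
    roster = dataset.individuals
    lookup = AffiliationLookup(affiliation)
    kin = kin_pairs(roster)
    ci = {
        (r.victim_id, r.bystander_id): r
        for r in consolation_idx.itertuples(index=False)
    }
    rows = []
    for (victim_id, bystander_id), score in dyad_scores.iterrows():
        victim = roster[victim_id]
        by = roster[bystander_id]
        la, _ = lookup.log_index(bystander_id, victim_id)
        entry = ci.get((victim_id, bystander_id))
        rows.append(
            {
                "victim_id": victim_id,
                "bystander_id": bystander_id,
                "group_id": victim.group_id,
                "tct": score["tct"],
                "n_pairs": score["n_pairs"],
                "consolation_index": entry.consolation_index if entry else np.nan,
                "consolation_index_pct": 100.0 * entry.consolation_index if entry else np.nan,
                "bystander_juvenile": float(by.age_class == "juvenile"),
                "bystander_adolescent": float(by.age_class == "adolescent"),
                "bystander_sex_m": float(by.sex == "M"),
                "bystander_mother_reared": float(by.rearing == "mother_reared"),
                "victim_juvenile": float(victim.age_class == "juvenile"),
                "victim_adolescent": float(victim.age_class == "adolescent"),
                "victim_sex_m": float(victim.sex == "M"),
                "victim_mother_reared": float(victim.rearing == "mother_reared"),
                "kin": float(frozenset((victim_id, bystander_id)) in kin),
                "log_affiliation": la,
            }
        )
    return pd.DataFrame(rows)
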