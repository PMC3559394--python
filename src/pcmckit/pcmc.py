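"""PC/MC pairing, attracted/dispersed/neutral labels and contact tendencies.

The matched-control comparison labels each retained PC/MC pair by when the
focal affiliative contact happened: *attracted* if it occurred earlier in
the PC than in the MC or only in the PC, *dispersed* if earlier in the MC
or only in the MC, *neutral* if at the same time in both or in neither.
Times are compared at 1-s resolution, the recording granularity.

Three relationship selectors are supported: consolation from any bystander
(contacts initiated by a bystander toward the victim), consolation from a
specific bystander, and reconciliation (contacts between the two former
opponents, either direction).  Tendencies aggregate labels:

    TCT = 100 * (attracted - dispersed) / total pairs

per victim (any-bystander selector) or per victim-bystander dyad (specific
selector); the conciliatory contact tendency (CCT) is the same formula on
opponent-opponent labels.  The consolation index is, per dyad, the number
of PCs in which the bystander was the *first* individual to console the
victim divided by the bystander's opportunities (PCs in which it was
present in both the PC and the MC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .ethogram_io import ConflictEvent, Dataset, FocalFollow

logger = logging.getLogger(__name__)

ATTRACTED = "attracted"
DISPERSED = "dispersed"
NEUTRAL = "neutral"

CONSOLATION_ANY = "consolation_any_bystander"
CONSOLATION_SPECIFIC = "consolation_specific_bystander"
RECONCILIATION = "reconciliation"

#: time resolution (seconds) at which "same time" is evaluated
TIE_RESOLUTION_S = 1.0


@dataclass(frozen=True)
class RelationshipSelector:
    mode: str
    bystander_id: Optional[str] = None

    def __post_init__(self):
        if self.mode not in (CONSOLATION_ANY, CONSOLATION_SPECIFIC, RECONCILIATION):
            raise ValueError(f"unknown selector mode {self.mode!r}")
        if self.mode == CONSOLATION_SPECIFIC and self.bystander_id is None:
            raise ValueError("specific-bystander selector needs a bystander_id")


def first_contact_latency(
    follow: FocalFollow,
    conflict: ConflictEvent,
    selector: RelationshipSelector,
) -> Optional[float]:
    """Latency of the first qualifying contact; ``None`` when censored.

    Consolation selectors count only contacts *initiated by a bystander
    toward the victim* — victim-initiated affiliation is not consolation.
    The reconciliation selector counts contacts between the two opponents
    in either direction.
    """
    if follow.conflict_id != conflict.conflict_id:
        raise ValueError("follow does not belong to the selector's conflict")
    victim, aggressor = conflict.victim_id, conflict.aggressor_id
    best: Optional[float] = None
    for c in follow.contacts:
        if selector.mode == RECONCILIATION:
            ok = {c.initiator_id, c.recipient_id} == {victim, aggressor}
        else:
            ok = (
                c.recipient_id == victim
                and c.initiator_id not in (victim, aggressor)
                and (selector.mode == CONSOLATION_ANY
                     or c.initiator_id == selector.bystander_id)
            )
        if ok and (best is None or c.time_s < best):
            best = c.time_s
    return best


def classify_pair(
    pc_latency: Optional[float],
    mc_latency: Optional[float],
    resolution: float = TIE_RESOLUTION_S,
) -> str:
    """Label a PC/MC latency pair; ``None`` marks a censored (no-event) follow."""
    if pc_latency is None and mc_latency is None:
        return NEUTRAL
    if mc_latency is None:
        return ATTRACTED
    if pc_latency is None:
        return DISPERSED
    pc_r = round(pc_latency / resolution)
    mc_r = round(mc_latency / resolution)
    if pc_r < mc_r:
        return ATTRACTED
    if pc_r > mc_r:
        return DISPERSED
    return NEUTRAL


@dataclass(frozen=True)
class PairRecord:
    conflict_id: int
    victim_id: str
    bystander_id: Optional[str]  # None for any-bystander / reconciliation labels
    pc_latency: Optional[float]
    mc_latency: Optional[float]
    label: str


def eligible_bystanders(pc: FocalFollow, mc: FocalFollow,
                        conflict: ConflictEvent) -> list[str]:
    """Bystanders present in both the PC and the MC for this conflict.

    The former opponents never qualify.  Presence means being listed on the
    follow's bystander roster (i.e. seen at any point of the follow).
    """
    opponents = {conflict.victim_id, conflict.aggressor_id}
    return sorted((set(pc.present_ids()) & set(mc.present_ids())) - opponents)


def label_dataset(
    dataset: Dataset,
    selector: RelationshipSelector,
    resolution: float = TIE_RESOLUTION_S,
) -> list[PairRecord]:
    """One label per retained PC/MC pair (or per eligible bystander pair).

    For the any-bystander and reconciliation selectors this yields exactly
    one record per retained conflict, so attracted + dispersed + neutral
    counts add up to the number of retained pairs.  Passing a
    ``CONSOLATION_SPECIFIC`` selector with ``bystander_id`` restricts to one
    dyad; use :func:`label_bystander_pairs` for the full per-dyad table.
    """
    records = []
    for conflict, pc, mc in dataset.retained_pairs():
        if selector.mode == CONSOLATION_SPECIFIC:
            if selector.bystander_id not in eligible_bystanders(pc, mc, conflict):
                continue
        pc_lat = first_contact_latency(pc, conflict, selector)
        mc_lat = first_contact_latency(mc, conflict, selector)
        records.append(
            PairRecord(conflict.conflict_id, conflict.victim_id,
                       selector.bystander_id, pc_lat, mc_lat,
                       classify_pair(pc_lat, mc_lat, resolution))
        )
    return records


def label_bystander_pairs(
    dataset: Dataset, resolution: float = TIE_RESOLUTION_S
) -> list[PairRecord]:
    """Per (conflict x eligible bystander) attracted/dispersed/neutral labels.

    Only bystanders present in both the PC and the MC are evaluated, which
    controls for variable bystander presence across the two follows.
    """
    records = []
    for conflict, pc, mc in dataset.retained_pairs():
        for bid in eligible_bystanders(pc, mc, conflict):
            sel = RelationshipSelector(CONSOLATION_SPECIFIC, bid)
            pc_lat = first_contact_latency(pc, conflict, sel)
            mc_lat = first_contact_latency(mc, conflict, sel)
            records.append(
                PairRecord(conflict.conflict_id, conflict.victim_id, bid,
                           pc_lat, mc_lat, classify_pair(pc_lat, mc_lat, resolution))
            )
    return records


def tct(attracted: int, dispersed: int, n_pairs: int) -> float:
    """Triadic/conciliatory contact tendency: 100*(A - D)/total pairs."""
    if n_pairs < 1:
        raise ValueError("tendency undefined for zero pairs")
    return 100.0 * (attracted - dispersed) / n_pairs


def tendency_scores(records: Iterable[PairRecord], by: str = "victim") -> pd.DataFrame:
    """A/D/N counts and contact tendency per victim or per victim-bystander dyad.

    Groups with zero pairs cannot arise from grouping; an entirely empty
    record set yields an empty frame with a logged warning.
    """
    rows = [
        {"victim_id": r.victim_id, "bystander_id": r.bystander_id, "label": r.label}
        for r in records
    ]
    if not rows:
        logger.warning("tendency_scores: no labelled pairs; returning empty table")
        return pd.DataFrame(
            columns=["attracted", "dispersed", "neutral", "n_pairs", "tct"]
        )
    df = pd.DataFrame(rows)
    keys = ["victim_id"] if by == "victim" else ["victim_id", "bystander_id"]
    counts = (
        df.groupby(keys)["label"].value_counts().unstack(fill_value=0)
        .reindex(columns=[ATTRACTED, DISPERSED, NEUTRAL], fill_value=0)
    )
    counts.columns = ["attracted", "dispersed", "neutral"]
    counts["n_pairs"] = counts.sum(axis=1)
    counts["tct"] = 100.0 * (counts["attracted"] - counts["dispersed"]) / counts["n_pairs"]
    return counts


def focal_proportions(records: Iterable[PairRecord]) -> pd.DataFrame:
    """Per-focal-victim proportions of attracted and dispersed pairs."""
    scores = tendency_scores(records, by="victim")
    if scores.empty:
        return pd.DataFrame(columns=["prop_attracted", "prop_dispersed", "n_pairs"])
    out = pd.DataFrame(index=scores.index)
    out["prop_attracted"] = scores["attracted"] / scores["n_pairs"]
    out["prop_dispersed"] = scores["dispersed"] / scores["n_pairs"]
    out["n_pairs"] = scores["n_pairs"]
    return out


def consolation_index(dataset: Dataset) -> pd.DataFrame:
    """Per victim-bystander dyad: fraction of opportunities in which the
    bystander was the first individual to provide consolatory contact.

    An opportunity is a retained PC in which the bystander was present in
    both the PC and the MC.  "First" is global within the PC: the earliest
    bystander-initiated contact toward the victim, regardless of whether
    that first consoler itself met the eligibility rule.  Dyads with zero
    opportunities are omitted.
    """
    opportunities: dict[tuple[str, str], int] = {}
    firsts: dict[tuple[str, str], int] = {}
    for conflict, pc, mc in dataset.retained_pairs():
        eligible = eligible_bystanders(pc, mc, conflict)
        victim, aggressor = conflict.victim_id, conflict.aggressor_id
        consolatory = [
            c for c in pc.contacts
            if c.recipient_id == victim and c.initiator_id not in (victim, aggressor)
        ]
        first_consoler = None
        if consolatory:
            best = min(consolatory, key=lambda c: (c.time_s, c.initiator_id))
            first_consoler = best.initiator_id
        for bid in eligible:
            key = (victim, bid)
            opportunities[key] = opportunities.get(key, 0) + 1
            if bid == first_consoler:
                firsts[key] = firsts.get(key, 0) + 1
    rows = [
        {
            "victim_id": v,
            "bystander_id": b,
            "opportunities": n,
            "first_consoler_count": firsts.get((v, b), 0),
            "consolation_index": firsts.get((v, b), 0) / n,
        }
        for (v, b), n in sorted(opportunities.items())
    ]
    return pd.DataFrame(
        rows, columns=["victim_id", "bystander_id", "opportunities",
                       "first_consoler_count", "consolation_index"]
    )
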