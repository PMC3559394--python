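"""Shared fixtures: small simulated colonies and handcrafted datasets."""

from __future__ import annotations

import datetime as dt

import pytest

from pcmckit.ethogram_io import (
    ConflictEvent,
    ContactEvent,
    Dataset,
    FocalFollow,
    Individual,
    validate_dataset,
)
from pcmckit.synthetic_colony import simulate_colony


@pytest.fixture(scope="session")
def small_colony():
    """A 40-hour campaign on the default two-group colony (seed 11)."""
    ds, affinity, truth = simulate_colony(hours=40.0, seed=11)
    return ds, affinity, truth


@pytest.fixture(scope="session")
def study_scale_colony():
    """A full-scale (453 h) campaign, shared across read-only tests."""
    ds, affinity, truth = simulate_colony(hours=453.0, seed=23)
    return ds, affinity, truth


def make_roster():
    """Six-individual single-group roster for handcrafted scenarios."""
    inds = [
        Individual("V", "F", 9.0, "adolescent", "orphan", None, "g"),
        Individual("A", "F", 15.0, "adult", "orphan", None, "g"),
        Individual("B1", "M", 6.0, "juvenile", "mother_reared", "M1", "g"),
        Individual("B2", "F", 14.0, "adult", "orphan", None, "g"),
        Individual("M1", "F", 16.0, "adult", "orphan", None, "g"),
        Individual("I1", "M", 1.0, "infant", "mother_reared", "M1", "g"),
    ]
    return {i.id: i for i in inds}


def make_pair_dataset(pc_contacts, mc_contacts, bystanders=("B1", "B2"),
                      mc_bystanders=None, pc_self=(), mc_self=()):
    """One conflict (victim V, aggressor A) with a valid PC/MC pair.

    Contact tuples are (time_s, initiator, recipient, behavior).
    """
    roster = make_roster()
    day = dt.date(2011, 6, 1)
    conflict = ConflictEvent(
        conflict_id=1, group_id="g", date=day, time_s=1000.0,
        victim_id="V", aggressor_id="A", context="rest", intensity=3,
        bystanders=[(b, "lt5m") for b in bystanders],
    )
    pc = FocalFollow(
        follow_id="pc1", conflict_id=1, kind="PC", focal_id="V",
        date=day, start_time_s=1000.0,
        contacts=[ContactEvent(*c) for c in pc_contacts],
        self_directed=list(pc_self),
        bystanders_present=[(b, "lt5m") for b in bystanders],
    )
    mc_b = list(mc_bystanders if mc_bystanders is not None else bystanders)
    mc = FocalFollow(
        follow_id="mc1", conflict_id=1, kind="MC", focal_id="V",
        date=day + dt.timedelta(days=1), start_time_s=1000.0,
        contacts=[ContactEvent(*c) for c in mc_contacts],
        self_directed=list(mc_self),
        bystanders_present=[(b, "lt5m") for b in mc_b] + [("A", "5to10m")],
    )
    ds = Dataset(individuals=roster, conflicts={1: conflict}, follows=[pc, mc])
    ds.excluded = validate_dataset(ds)
    return ds
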