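"""Agent-based synthetic colony: roster, conflicts, PC/MC follows and scans.

The generator emulates the observational structure of a post-conflict /
matched-control study in a semi-free-ranging bonobo colony: conflicts
arrive as a Poisson process over observation hours; victim and aggressor
classes follow the empirical class shares of the study population
(adolescent males and juvenile females are the modal victims, adult
females the modal aggressors); each conflict draws a context, a six-level
intensity, a bystander roster with three proximity bands and an optional
redirection event.  Each conflict then yields a PC follow whose
bystander-initiated contacts follow a per-bystander logistic model on the
covariates the analysis estimates (proximity, age class, rearing, dyadic
affiliation, kinship, context, reconciliation, redirection), with
exponential first-contact latencies right-censored at the 600-s follow
end, and an MC follow with a flat baseline contact probability and
uniform latencies.  Self-scratching is a piecewise-constant-rate Poisson
process that switches rate at the first consolatory contact; self-grooming
bouts carry exponential durations.  Scan samples are emitted on a fixed
grid with dyadic engagement Bernoulli in the latent affinity.

Identical config + seed reproduces byte-identical output files, and every
generated dataset passes :func:`pcmckit.ethogram_io.validate_dataset`.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ethogram_io import (
    AFFILIATIVE_BEHAVIORS,
    PROXIMITY_BANDS,
    SCAN_BEHAVIORS,
    WITHIN_10M,
    ConflictEvent,
    ContactEvent,
    Dataset,
    FocalFollow,
    Individual,
    ScanSample,
    SelfDirectedEvent,
    validate_dataset,
)


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: demographic cell -> head count, per group, mirroring the two sanctuary
#: groups (36 non-infant subjects plus 6 dependent infants in total)
_DEFAULT_GROUPS = {
    "g1": {
        ("F", "adult", "orphan"): 6,
        ("F", "adolescent", "orphan"): 1,
        ("F", "juvenile", "orphan"): 3,
        ("F", "juvenile", "mother_reared"): 2,
        ("M", "adult", "orphan"): 3,
        ("M", "adolescent", "orphan"): 4,
        ("M", "juvenile", "mother_reared"): 2,
        ("M", "infant", "mother_reared"): 2,
        ("F", "infant", "mother_reared"): 2,
    },
    "g2": {
        ("F", "adult", "orphan"): 3,
        ("F", "adolescent", "orphan"): 1,
        ("F", "juvenile", "orphan"): 1,
        ("M", "adult", "orphan"): 4,
        ("M", "adolescent", "orphan"): 4,
        ("M", "juvenile", "mother_reared"): 2,
        ("M", "infant", "mother_reared"): 2,
    },
}

#: victim / aggressor class shares observed in the study population; the
#: remaining mass is spread uniformly over the unnamed classes
_VICTIM_SHARES = {"adolescent_M": 0.331, "juvenile_F": 0.325}
_AGGRESSOR_SHARES = {"adult_F": 0.512, "adult_M": 0.254}

_ALL_CLASSES = tuple(
    f"{ac}_{sex}" for ac in ("adult", "adolescent", "juvenile") for sex in ("F", "M")
)


def _fill_class_probs(named: dict[str, float]) -> dict[str, float]:
    rest = [c for c in _ALL_CLASSES if c not in named]
    remainder = 1.0 - sum(named.values())
    probs = dict(named)
    for c in rest:
        probs[c] = remainder / len(rest)
    return probs


@dataclass
class ColonyConfig:
    """Study conditions for the generator.

    Defaults reproduce the sanctuary study's scale and composition: a
    conflict rate of 356 conflicts over 453 observation hours, the printed
    victim/aggressor class shares, the printed six-level intensity
    distribution, and a matched-control failure fraction of 10/356.
    """

    groups: dict[str, dict[tuple[str, str, str], int]] = field(
        default_factory=lambda: {g: dict(c) for g, c in _DEFAULT_GROUPS.items()}
    )
    conflict_rate_per_h: float = 356.0 / 453.0
    victim_class_probs: dict[str, float] = field(
        default_factory=lambda: _fill_class_probs(_VICTIM_SHARES)
    )
    aggressor_class_probs: dict[str, float] = field(
        default_factory=lambda: _fill_class_probs(_AGGRESSOR_SHARES)
    )
    # printed shares sum to 0.993 at the published rounding; renormalised on use
    intensity_probs: tuple[float, ...] = (0.142, 0.025, 0.34, 0.32, 0.125, 0.041)
    context_probs: dict[str, float] = field(
        default_factory=lambda: {
            "feed": 0.35, "rest": 0.15, "play": 0.15,
            "object_food_competition": 0.15, "arrival": 0.08,
            "anticipating_feed": 0.07, "social_tension_display": 0.05,
        }
    )
    proximity_probs: tuple[float, float, float] = (0.3, 0.3, 0.4)
    bystander_presence_prob: float = 0.25
    mc_presence_prob: float = 0.8
    mc_failure_prob: float = 10.0 / 356.0
    redirection_prob_adult_female: float = 0.25
    redirection_prob_other: float = 0.08
    obs_day_hours: float = 8.0
    scan_interval_s: float = 1800.0
    scan_presence_prob: float = 0.8
    group_hours_share: Optional[dict[str, float]] = None  # default: by group size

    def validate(self) -> None:
        for name, probs in (
            ("victim_class_probs", self.victim_class_probs.values()),
            ("aggressor_class_probs", self.aggressor_class_probs.values()),
            ("context_probs", self.context_probs.values()),
            ("proximity_probs", self.proximity_probs),
        ):
            vec = list(probs)
            if any(p < 0 for p in vec) or abs(sum(vec) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be a probability vector summing to 1")
        if any(p < 0 for p in self.intensity_probs) or len(self.intensity_probs) != 6:
            raise ConfigError("intensity_probs must be six nonnegative weights")
        for cells in self.groups.values():
            if any(n < 0 for n in cells.values()):
                raise ConfigError("cell counts must be nonnegative")


@dataclass
class ResponseModel:
    """Latent behavioural parameters behind the PC/MC streams.

    ``consolation_coefs`` are log-odds effects on a bystander's per-PC
    probability of initiating contact with the victim; the reference
    bystander is a distal (>10 m) orphan adult in a non-feed context.
    ``p_mc_contact`` is the flat per-bystander matched-control contact
    probability.  Scratch rates are bouts/min; groom means are seconds.
    """

    consolation_intercept: float = -1.75
    consolation_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "proximity_lt5m": 1.2,
            "proximity_5to10m": 0.4,
            "bystander_juvenile": 0.9,
            "bystander_adolescent": 0.4,
            "bystander_mother_reared": 0.8,
            "log_affiliation": 0.5,
            "kin_bystander_victim": 1.2,
            "kin_bystander_aggressor": 0.4,
            "context_feed": -0.6,
            "reconciliation": 0.4,
            "redirection": 0.7,
        }
    )
    reconciliation_intercept: float = -0.5
    reconciliation_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "log_affiliation": 0.5,
            "aggressor_juvenile": 0.8,
            "aggressor_adolescent": 0.2,
            "victim_adolescent": 0.6,
            "victim_mother_reared": 0.8,
        }
    )
    latency_model: str = "exponential"  # "uniform" makes PC latencies MC-like
    latency_scale_pc_s: float = 90.0
    latency_scale_recon_s: float = 120.0
    p_mc_contact: float = 0.09
    p_mc_opponent_contact: float = 0.06
    scratch_rate_mc: float = 0.37
    scratch_rate_pc: float = 0.43
    scratch_rate_pc_consoled: float = 0.19
    groom_bout_rate_per_min: float = 0.08
    groom_mean_s_mc: float = 48.5
    groom_mean_s_pc: float = 36.25
    groom_mean_s_pc_consoled: float = 24.75
    victim_initiation_prob: float = 0.08

    def validate(self) -> None:
        for p in (self.p_mc_contact, self.p_mc_opponent_contact):
            if not 0.0 < p < 1.0:
                raise ConfigError("baseline contact probabilities must lie in (0,1)")
        if self.latency_scale_pc_s <= 0 or self.latency_scale_recon_s <= 0:
            raise ConfigError("latency scales must be positive")
        for lam in (self.scratch_rate_mc, self.scratch_rate_pc,
                    self.scratch_rate_pc_consoled):
            if lam < 0:
                raise ConfigError("scratch rates must be nonnegative")

    @classmethod
    def null(cls, p_contact: float = 0.12) -> "ResponseModel":
        """A no-effect model: PC streams distributed exactly like MC streams.

        Per-bystander contact probability equals the MC baseline, latencies
        are uniform in both conditions, and all scratch/groom rates are
        equal across conditions.  Used for type-I calibration studies.
        """
        return cls(
            consolation_intercept=_logit(p_contact),
            consolation_coefs={k: 0.0 for k in cls().consolation_coefs},
            reconciliation_intercept=_logit(0.06),
            reconciliation_coefs={k: 0.0 for k in cls().reconciliation_coefs},
            latency_model="uniform",
            p_mc_contact=p_contact,
            p_mc_opponent_contact=0.06,
            scratch_rate_pc=0.37,
            scratch_rate_pc_consoled=0.37,
            groom_mean_s_pc=48.5,
            groom_mean_s_pc_consoled=48.5,
        )


def ground_truth(config: ColonyConfig, response: ResponseModel) -> dict:
    """JSON-serialisable record of all latent parameters, for recovery tests."""
    cfg = asdict(config)
    cfg["groups"] = {
        g: {"|".join(k): v for k, v in cells.items()} for g, cells in config.groups.items()
    }
    return {"colony": cfg, "response": asdict(response)}


# ---------------------------------------------------------------------------
# roster
# ---------------------------------------------------------------------------


def simulate_roster(config: ColonyConfig, seed: int = 0) -> dict[str, Individual]:
    """Draw a roster with exactly the configured demographic cell counts.

    Every mother-reared juvenile or infant is linked to a distinct adult
    female of the same group; requesting more links than there are adult
    females is a configuration error.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    age_range = {"adult": (11, 25), "adolescent": (7, 12), "juvenile": (3, 7),
                 "infant": (0, 2)}
    roster: dict[str, Individual] = {}
    counter = itertools.count(1)
    for gid in sorted(config.groups):
        cells = config.groups[gid]
        members: list[Individual] = []
        for (sex, age_class, rearing) in sorted(cells):
            for _ in range(cells[(sex, age_class, rearing)]):
                iid = f"{gid}x{next(counter):03d}"
                lo, hi = age_range[age_class]
                age = float(rng.integers(lo, hi + 1))
                members.append(
                    Individual(id=iid, name=iid, sex=sex, age_years=age,
                               age_class=age_class, rearing=rearing,
                               mother_id=None, group_id=gid)
                )
        mothers = [m for m in members if m.sex == "F" and m.age_class == "adult"]
        need = [m for m in members if m.rearing == "mother_reared"
                and m.age_class in ("juvenile", "infant")]
        # a female can carry one dependent infant alongside an older juvenile
        if len(need) > 2 * len(mothers):
            raise ConfigError(
                f"group {gid}: {len(need)} mother-offspring links requested but "
                f"only {len(mothers)} adult females available"
            )
        order = list(rng.permutation(len(mothers))) * 2
        for child, k in zip(need, order):
            child.mother_id = mothers[k].id
        for m in members:
            roster[m.id] = m
    return roster


# ---------------------------------------------------------------------------
# latent dyadic affinity
# ---------------------------------------------------------------------------


class AffinityMatrix:
    """Symmetric latent dyadic affinity in (0,1), indexable by individual id."""

    def __init__(self, ids: list[str], values: np.ndarray):
        self.ids = list(ids)
        self.index = {i: k for k, i in enumerate(self.ids)}
        self.values = values

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = np.array([self.index[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


def kin_matrix(roster: dict[str, Individual], ids: list[str]) -> np.ndarray:
    """Boolean mother-offspring matrix over ``ids`` (the only kinship coded)."""
    idx = {i: k for k, i in enumerate(ids)}
    out = np.zeros((len(ids), len(ids)), dtype=bool)
    for iid in ids:
        mid = roster[iid].mother_id
        if mid is not None and mid in idx:
            out[idx[iid], idx[mid]] = True
            out[idx[mid], idx[iid]] = True
    return out


def simulate_affiliation(
    roster: dict[str, Individual],
    kin_boost: float = 1.5,
    concentration: float = 40.0,
    seed: int = 0,
) -> AffinityMatrix:
    """Draw a symmetric latent affinity matrix with a kinship offset.

    Dyadic affinity is Beta-distributed around ``expit(mu0 + kin_boost*kin)``
    with the given concentration; a dyad's affinity is also the probability
    that a scan sample finds the dyad engaged in an affiliative state.  With
    ``kin_boost == 0`` kin and non-kin dyads are exchangeable.
    """
    if not roster:
        raise ConfigError("roster is empty")
    rng = np.random.default_rng(seed)
    ids = sorted(roster)
    n = len(ids)
    kin = kin_matrix(roster, ids)
    mu0 = _logit(0.12)
    mean = _expit(mu0 + kin_boost * kin.astype(float))
    a = mean * concentration
    b = (1.0 - mean) * concentration
    draw = rng.beta(a, b)
    vals = np.tril(draw, -1)
    vals = vals + vals.T
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 1e-4, 1.0 - 1e-4)
    np.fill_diagonal(vals, 0.0)
    return AffinityMatrix(ids, vals)


# ---------------------------------------------------------------------------
# observation stream
# ---------------------------------------------------------------------------


@dataclass
class _GroupCache:
    gid: str
    ids: list[str]               # non-infant members, sorted
    all_ids: list[str]           # including infants
    juvenile: np.ndarray
    adolescent: np.ndarray
    mother_reared: np.ndarray
    female: np.ndarray
    age_class: list[str]
    log_aff: np.ndarray          # log affinity among non-infant members
    kin: np.ndarray
    class_members: dict[str, list[int]]


def _build_cache(roster, affinity, gid) -> _GroupCache:
    all_ids = sorted(i for i, ind in roster.items() if ind.group_id == gid)
    ids = [i for i in all_ids if not roster[i].is_infant]
    sub = affinity.submatrix(ids)
    cache = _GroupCache(
        gid=gid,
        ids=ids,
        all_ids=all_ids,
        juvenile=np.array([roster[i].age_class == "juvenile" for i in ids]),
        adolescent=np.array([roster[i].age_class == "adolescent" for i in ids]),
        mother_reared=np.array([roster[i].rearing == "mother_reared" for i in ids]),
        female=np.array([roster[i].sex == "F" for i in ids]),
        age_class=[roster[i].age_class for i in ids],
        log_aff=np.log(np.maximum(sub, 1e-6)),
        kin=kin_matrix(roster, ids),
        class_members={},
    )
    for k, i in enumerate(ids):
        cls = f"{roster[i].age_class}_{roster[i].sex}"
        cache.class_members.setdefault(cls, []).append(k)
    return cache


def _draw_class_individual(rng, cache, probs: dict[str, float], forbid: int = -1) -> int:
    """Draw a class by the configured shares, then an individual uniformly.

    A forbidden index (the victim, when drawing the aggressor) is excluded
    *within* its class so the class shares stay exact; only a class left
    empty by the exclusion forces a class redraw.
    """
    classes = [
        c for c in sorted(probs)
        if any(k != forbid for k in cache.class_members.get(c, ()))
    ]
    if not classes:
        raise ConfigError("cannot draw two distinct opponents from this group")
    weights = np.array([probs[c] for c in classes])
    weights = weights / weights.sum()
    cls = classes[rng.choice(len(classes), p=weights)]
    members = [k for k in cache.class_members[cls] if k != forbid]
    return members[int(rng.integers(len(members)))]


def _scratch_events(rng, rate_before, rate_after, switch_s, duration_s):
    events = []
    span1 = min(switch_s, duration_s)
    n1 = rng.poisson(rate_before / 60.0 * span1)
    events.extend(float(t) for t in rng.uniform(0.0, span1, size=n1))
    if switch_s < duration_s:
        n2 = rng.poisson(rate_after / 60.0 * (duration_s - switch_s))
        events.extend(float(t) for t in rng.uniform(switch_s, duration_s, size=n2))
    return [SelfDirectedEvent(t, "scratch_bout") for t in sorted(events)]


def _groom_events(rng, bout_rate, mean_before, mean_after, switch_s, duration_s):
    n = rng.poisson(bout_rate * duration_s / 60.0)
    out = []
    for t in sorted(float(x) for x in rng.uniform(0.0, duration_s, size=n)):
        mean = mean_before if t < switch_s else mean_after
        dur = min(float(rng.exponential(mean)), duration_s - t)
        out.append(SelfDirectedEvent(t, "groom_interval", dur))
    return out


def simulate_observation(
    roster: dict[str, Individual],
    affinity: AffinityMatrix,
    config: ColonyConfig,
    response: ResponseModel,
    hours: float,
    seed: int = 0,
    start_date: _dt.date = _dt.date(2011, 5, 1),
) -> Dataset:
    """Simulate a full observation campaign and return a validated dataset."""
    if hours <= 0:
        raise ConfigError("hours must be positive")
    config.validate()
    response.validate()
    rng = np.random.default_rng(seed)
    day_s = config.obs_day_hours * 3600.0

    gids = sorted({ind.group_id for ind in roster.values()})
    caches = {g: _build_cache(roster, affinity, g) for g in gids}
    share = config.group_hours_share or {
        g: len(caches[g].ids) / sum(len(caches[h].ids) for h in gids) for g in gids
    }

    intensity_p = np.array(config.intensity_probs, dtype=float)
    intensity_p = intensity_p / intensity_p.sum()
    contexts = sorted(config.context_probs)
    context_p = np.array([config.context_probs[c] for c in contexts])
    prox_p = np.array(config.proximity_probs)

    # ---- conflicts -------------------------------------------------------
    raw: list[tuple[_dt.date, float, str]] = []
    for gid in gids:
        g_hours = hours * share[gid]
        n_days = max(1, math.ceil(g_hours / config.obs_day_hours))
        n_conf = rng.poisson(config.conflict_rate_per_h * g_hours)
        days = rng.integers(0, n_days, size=n_conf)
        times = rng.uniform(0.0, day_s - 700.0, size=n_conf)
        for d, t in zip(days, times):
            raw.append((start_date + _dt.timedelta(days=int(d)), float(t), gid))
    raw.sort(key=lambda r: (r[0], r[1], r[2]))

    conflicts: dict[int, ConflictEvent] = {}
    follows: list[FocalFollow] = []
    meta: list[dict] = []  # per-conflict intermediates for the MC pass

    for cid, (date, t, gid) in enumerate(raw, start=1):
        cache = caches[gid]
        v = _draw_class_individual(rng, cache, config.victim_class_probs)
        a = _draw_class_individual(rng, cache, config.aggressor_class_probs, forbid=v)
        n = len(cache.ids)
        present = rng.random(n) < config.bystander_presence_prob
        present[[v, a]] = False
        b_idx = np.flatnonzero(present)
        bands = [PROXIMITY_BANDS[k] for k in rng.choice(3, size=b_idx.size, p=prox_p)]
        context = contexts[rng.choice(len(contexts), p=context_p)]
        intensity = int(rng.choice(6, p=intensity_p)) + 1

        p_red = (config.redirection_prob_adult_female
                 if (cache.age_class[v] == "adult" and cache.female[v])
                 else config.redirection_prob_other)
        redirection = None
        if b_idx.size and rng.random() < p_red:
            redirection = cache.ids[int(b_idx[int(rng.integers(b_idx.size))])]

        conflicts[cid] = ConflictEvent(
            conflict_id=cid, group_id=gid, date=date, time_s=t,
            victim_id=cache.ids[v], aggressor_id=cache.ids[a], context=context,
            intensity=intensity,
            bystanders=[(cache.ids[int(k)], band) for k, band in zip(b_idx, bands)],
            redirection_target=redirection,
        )

        # ---- reconciliation draw ---------------------------------------
        rc = response.reconciliation_coefs
        recon_logit = (
            response.reconciliation_intercept
            + rc.get("log_affiliation", 0.0) * cache.log_aff[v, a]
            + rc.get("aggressor_juvenile", 0.0) * float(cache.juvenile[a])
            + rc.get("aggressor_adolescent", 0.0) * float(cache.adolescent[a])
            + rc.get("victim_adolescent", 0.0) * float(cache.adolescent[v])
            + rc.get("victim_mother_reared", 0.0) * float(cache.mother_reared[v])
        )
        recon_latency = None
        if rng.random() < _expit(recon_logit):
            if response.latency_model == "uniform":
                recon_latency = float(rng.uniform(0.0, 600.0))
            else:
                lat = float(rng.exponential(response.latency_scale_recon_s))
                recon_latency = lat if lat <= 600.0 else None
        recon_occurred = recon_latency is not None

        # ---- per-bystander consolation hazard ---------------------------
        cc = response.consolation_coefs
        band_arr = np.array(bands) if b_idx.size else np.empty(0, dtype="<U6")
        logit = np.full(b_idx.size, response.consolation_intercept)
        logit += cc.get("proximity_lt5m", 0.0) * (band_arr == "lt5m")
        logit += cc.get("proximity_5to10m", 0.0) * (band_arr == "5to10m")
        logit += cc.get("bystander_juvenile", 0.0) * cache.juvenile[b_idx]
        logit += cc.get("bystander_adolescent", 0.0) * cache.adolescent[b_idx]
        logit += cc.get("bystander_mother_reared", 0.0) * cache.mother_reared[b_idx]
        logit += cc.get("log_affiliation", 0.0) * cache.log_aff[v, b_idx]
        logit += cc.get("kin_bystander_victim", 0.0) * cache.kin[v, b_idx]
        logit += cc.get("kin_bystander_aggressor", 0.0) * cache.kin[a, b_idx]
        logit += cc.get("context_feed", 0.0) * (context == "feed")
        logit += cc.get("reconciliation", 0.0) * recon_occurred
        logit += cc.get("redirection", 0.0) * (redirection is not None)
        contact_draw = rng.random(b_idx.size) < _expit(logit)
        if response.latency_model == "uniform":
            lats = rng.uniform(0.0, 600.0, size=b_idx.size)
        else:
            lats = rng.exponential(response.latency_scale_pc_s, size=b_idx.size)

        pc_contacts = []
        for k, ok, lat in zip(b_idx, contact_draw, lats):
            if ok and lat <= 600.0:
                pc_contacts.append(
                    ContactEvent(float(lat), cache.ids[int(k)], cache.ids[v],
                                 AFFILIATIVE_BEHAVIORS[int(rng.integers(len(AFFILIATIVE_BEHAVIORS)))])
                )
        if recon_latency is not None:
            ini, rec = ((v, a) if rng.random() < 0.5 else (a, v))
            pc_contacts.append(
                ContactEvent(recon_latency, cache.ids[ini], cache.ids[rec],
                             AFFILIATIVE_BEHAVIORS[int(rng.integers(len(AFFILIATIVE_BEHAVIORS)))])
            )
        if b_idx.size and rng.random() < response.victim_initiation_prob:
            k = int(b_idx[int(rng.integers(b_idx.size))])
            pc_contacts.append(
                ContactEvent(float(rng.uniform(0.0, 600.0)), cache.ids[v], cache.ids[k],
                             AFFILIATIVE_BEHAVIORS[int(rng.integers(len(AFFILIATIVE_BEHAVIORS)))])
            )
        consol_times = [c.time_s for c in pc_contacts
                        if c.recipient_id == cache.ids[v] and c.initiator_id != cache.ids[a]]
        switch = min(consol_times) if consol_times else 600.0
        sd = _scratch_events(rng, response.scratch_rate_pc,
                             response.scratch_rate_pc_consoled, switch, 600.0)
        sd += _groom_events(rng, response.groom_bout_rate_per_min,
                            response.groom_mean_s_pc, response.groom_mean_s_pc_consoled,
                            switch, 600.0)
        follows.append(
            FocalFollow(
                follow_id=f"pc{cid:05d}", conflict_id=cid, kind="PC",
                focal_id=cache.ids[v], date=date, start_time_s=t,
                contacts=sorted(pc_contacts, key=lambda c: c.time_s),
                self_directed=sorted(sd, key=lambda s: (s.time_s, s.kind)),
                bystanders_present=[(cache.ids[int(k)], band)
                                    for k, band in zip(b_idx, bands)],
            )
        )
        meta.append({"cid": cid, "gid": gid, "v": v, "a": a, "b_idx": b_idx})

    # ---- matched controls ------------------------------------------------
    history = list(conflicts.values())
    by_focal: dict[str, list[ConflictEvent]] = {}
    for c in history:
        by_focal.setdefault(c.victim_id, []).append(c)
        by_focal.setdefault(c.aggressor_id, []).append(c)

    for m in meta:
        if rng.random() < config.mc_failure_prob:
            continue
        cache = caches[m["gid"]]
        c = conflicts[m["cid"]]
        offset = int(rng.integers(1, 3))
        start = float(np.clip(c.time_s + rng.uniform(-900.0, 900.0), 0.0, day_s - 600.0))
        mc_date = c.date + _dt.timedelta(days=offset)
        # push the MC past any conflict involving the focal in the prior 10 min
        ok = False
        for _ in range(6):
            clash = [
                o.time_s for o in by_focal.get(c.victim_id, ())
                if o.date == mc_date and start - 600.0 <= o.time_s <= start
            ]
            if not clash:
                ok = True
                break
            start = max(clash) + 601.0
            if abs(start - c.time_s) > 3600.0 or start > day_s - 600.0:
                break
        if not ok:
            continue
        v, a = m["v"], m["a"]
        keep = m["b_idx"][rng.random(m["b_idx"].size) < config.mc_presence_prob]
        bands = [PROXIMITY_BANDS[k] for k in rng.choice(3, size=keep.size, p=prox_p)]
        present = [(cache.ids[int(k)], band) for k, band in zip(keep, bands)]
        # the aggressor must be within 10 m for the MC to be valid
        present.append((cache.ids[a], WITHIN_10M[int(rng.integers(2))]))

        contacts = []
        draws = rng.random(keep.size) < response.p_mc_contact
        lats = rng.uniform(0.0, 600.0, size=keep.size)
        for k, okc, lat in zip(keep, draws, lats):
            if okc:
                contacts.append(
                    ContactEvent(float(lat), cache.ids[int(k)], cache.ids[v],
                                 AFFILIATIVE_BEHAVIORS[int(rng.integers(len(AFFILIATIVE_BEHAVIORS)))])
                )
        if rng.random() < response.p_mc_opponent_contact:
            ini, rec = ((v, a) if rng.random() < 0.5 else (a, v))
            contacts.append(
                ContactEvent(float(rng.uniform(0.0, 600.0)), cache.ids[ini], cache.ids[rec],
                             AFFILIATIVE_BEHAVIORS[int(rng.integers(len(AFFILIATIVE_BEHAVIORS)))])
            )
        if keep.size and rng.random() < response.victim_initiation_prob:
            k = int(keep[int(rng.integers(keep.size))])
            contacts.append(
                ContactEvent(float(rng.uniform(0.0, 600.0)), cache.ids[v], cache.ids[k],
                             AFFILIATIVE_BEHAVIORS[int(rng.integers(len(AFFILIATIVE_BEHAVIORS)))])
            )
        sd = _scratch_events(rng, response.scratch_rate_mc, response.scratch_rate_mc,
                             600.0, 600.0)
        sd += _groom_events(rng, response.groom_bout_rate_per_min,
                            response.groom_mean_s_mc, response.groom_mean_s_mc,
                            600.0, 600.0)
        follows.append(
            FocalFollow(
                follow_id=f"mc{m['cid']:05d}", conflict_id=m["cid"], kind="MC",
                focal_id=cache.ids[v], date=mc_date, start_time_s=start,
                contacts=sorted(contacts, key=lambda x: x.time_s),
                self_directed=sorted(sd, key=lambda s: (s.time_s, s.kind)),
                bystanders_present=sorted(present),
            )
        )

    # ---- scan samples ----------------------------------------------------
    scans: list[ScanSample] = []
    for gid in gids:
        cache = caches[gid]
        g_hours = hours * share[gid]
        n_days = max(1, math.ceil(g_hours / config.obs_day_hours))
        counter = 1
        for d in range(n_days):
            date = start_date + _dt.timedelta(days=d)
            t = 300.0
            while t < day_s:
                present = [i for i in cache.all_ids
                           if rng.random() < config.scan_presence_prob]
                engaged = []
                noninf = [i for i in present if i in cache.ids]
                for x in range(len(noninf)):
                    for y in range(x + 1, len(noninf)):
                        if rng.random() < affinity.get(noninf[x], noninf[y]):
                            engaged.append(
                                (noninf[x], noninf[y],
                                 SCAN_BEHAVIORS[int(rng.integers(len(SCAN_BEHAVIORS)))])
                            )
                scans.append(
                    ScanSample(scan_id=f"{gid}s{counter:05d}", group_id=gid, date=date,
                               time_s=t, present_ids=frozenset(present), engaged=engaged)
                )
                counter += 1
                t += config.scan_interval_s

    ds = Dataset(
        individuals={i: roster[i] for i in sorted(roster)},
        conflicts=conflicts,
        follows=follows,
        scans=scans,
    ).canonicalize()
    ds.excluded = validate_dataset(ds)
    return ds


def simulate_colony(
    config: ColonyConfig | None = None,
    response: ResponseModel | None = None,
    hours: float = 453.0,
    kin_boost: float = 1.5,
    concentration: float = 40.0,
    seed: int = 0,
) -> tuple[Dataset, AffinityMatrix, dict]:
    """One-call convenience wrapper: roster -> affinity -> observation.

    Sub-seeds for each stage are derived from ``seed`` so that stages stay
    independently reproducible.  Returns (dataset, latent affinity, truth).
    """
    config = config or ColonyConfig()
    response = response or ResponseModel()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    roster = simulate_roster(config, seed=sub[0])
    affinity = simulate_affiliation(roster, kin_boost=kin_boost,
                                    concentration=concentration, seed=sub[1])
    ds = simulate_observation(roster, affinity, config, response, hours, seed=sub[2])
    truth = ground_truth(config, response)
    truth["kin_boost"] = kin_boost
    truth["concentration"] = concentration
    truth["hours"] = hours
    truth["seed"] = seed
    return ds, affinity, truth


# ---------------------------------------------------------------------------
# direct opportunity-table generator (for estimator checks)
# ---------------------------------------------------------------------------


def simulate_opportunity_table(
    n_obs: int,
    beta: dict[str, float],
    intercept: float = -1.0,
    covariates: dict[str, dict] | None = None,
    random_effects: dict[str, tuple[int, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a binary-outcome table straight from a logistic mixed model.

    ``beta`` maps covariate names to true log-odds effects; covariates not
    named there still appear as noise columns when listed in ``covariates``
    (spec: ``{"kind": "binary", "p": 0.5}`` or ``{"kind": "normal"}``).
    ``random_effects`` maps factor names to (n_levels, sd) for independent
    Gaussian random intercepts.  The result column ``outcome`` is 0/1.
    """
    rng = np.random.default_rng(seed)
    covariates = covariates or {name: {"kind": "normal"} for name in beta}
    random_effects = random_effects or {"conflict_id": (max(n_obs // 8, 2), 1.0)}
    df = pd.DataFrame(index=range(n_obs))
    eta = np.full(n_obs, float(intercept))
    for name in sorted(covariates):
        spec = covariates[name]
        if spec.get("kind", "normal") == "binary":
            x = (rng.random(n_obs) < spec.get("p", 0.5)).astype(float)
        else:
            x = rng.standard_normal(n_obs)
        df[name] = x
        eta += beta.get(name, 0.0) * x
    for factor in sorted(random_effects):
        n_levels, sd = random_effects[factor]
        codes = rng.integers(0, n_levels, size=n_obs)
        df[factor] = codes
        u = rng.normal(0.0, sd, size=n_levels)
        eta += u[codes]
    df["outcome"] = (rng.random(n_obs) < _expit(eta)).astype(int)
    return df
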