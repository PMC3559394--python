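"""Data model, delimited-text I/O and validation for PC/MC observation datasets.

Observational ethology of post-conflict behaviour is organised around four
record types: a roster of individually identified subjects, all-occurrence
conflict records (with opponent identities, context, a six-level intensity
scale and a bystander/proximity roster), ten-minute focal follows of the
victim — one post-conflict (PC) follow starting at conflict end and one
matched-control (MC) follow on a later conflict-free occasion — and
instantaneous scan samples used to build dyadic affiliation indices.

All files are plain CSV with a header row.  Times are encoded as an ISO
date plus seconds-within-session, which keeps files human-auditable and
diff-friendly.  Multi-valued fields (bystander rosters, scan membership)
are packed with ``;`` between items and ``|`` within an item; those two
characters are therefore reserved and may not appear in individual ids.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import yaml

SEXES = ("F", "M")
AGE_CLASSES = ("adult", "adolescent", "juvenile", "infant")
REARING_TYPES = ("mother_reared", "orphan")
CONTEXTS = (
    "feed",
    "rest",
    "play",
    "object_food_competition",
    "arrival",
    "anticipating_feed",
    "social_tension_display",
)
PROXIMITY_BANDS = ("lt5m", "5to10m", "gt10m")
#: bands that count as "within 10 m" for the matched-control presence rule
WITHIN_10M = ("lt5m", "5to10m")
AFFILIATIVE_BEHAVIORS = (
    "embrace",
    "sociosexual",
    "touch",
    "groom",
    "contact_sit",
    "play",
    "hold",
    "pat",
    "inspect",
)
SCAN_BEHAVIORS = ("groom", "contact_sit", "arms_reach", "play", "sexual_contact")
SELF_DIRECTED_KINDS = ("scratch_bout", "groom_interval")

FOLLOW_DURATION_S = 600.0

_RESERVED_ID_CHARS = (";", "|")


class ParseError(ValueError):
    """Schema violation in an input file; carries file and line number."""

    def __init__(self, path, line, message):
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


class IntegrityError(ValueError):
    """Dangling id reference or cross-record inconsistency."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    id: str
    sex: str
    age_years: float
    age_class: str
    rearing: str
    mother_id: Optional[str]
    group_id: str
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = self.id

    @property
    def is_infant(self) -> bool:
        return self.age_class == "infant"


@dataclass
class ConflictEvent:
    conflict_id: int
    group_id: str
    date: _dt.date
    time_s: float  # conflict end, seconds since session start
    victim_id: str
    aggressor_id: str
    context: str
    intensity: int
    bystanders: list[tuple[str, str]] = field(default_factory=list)  # (id, band)
    redirection_target: Optional[str] = None

    def bystander_ids(self) -> list[str]:
        return [b for b, _ in self.bystanders]


@dataclass
class ContactEvent:
    time_s: float
    initiator_id: str
    recipient_id: str
    behavior: str


@dataclass
class SelfDirectedEvent:
    time_s: float
    kind: str  # scratch_bout | groom_interval
    duration_s: float = 0.0  # zero for instantaneous scratch bouts


@dataclass
class FocalFollow:
    follow_id: str
    conflict_id: int
    kind: str  # PC | MC
    focal_id: str
    date: _dt.date
    start_time_s: float
    duration_s: float = FOLLOW_DURATION_S
    contacts: list[ContactEvent] = field(default_factory=list)
    self_directed: list[SelfDirectedEvent] = field(default_factory=list)
    bystanders_present: list[tuple[str, str]] = field(default_factory=list)

    def present_ids(self) -> list[str]:
        return [b for b, _ in self.bystanders_present]


@dataclass
class ScanSample:
    scan_id: str
    group_id: str
    date: _dt.date
    time_s: float
    present_ids: frozenset[str] = frozenset()
    engaged: list[tuple[str, str, str]] = field(default_factory=list)  # (a, b, behavior)


# ---------------------------------------------------------------------------
# matched-control rule configuration
# ---------------------------------------------------------------------------


@dataclass
class MatchConfig:
    """Parameters of the matched-control scheduling rule.

    The MC for a conflict must be run on the same victim 1-2 days later at
    the same or closest possible time of day (within one hour), with both
    former opponents within 10 m of one another, and with the focal free of
    conflict for at least ten minutes beforehand.  ``day_window`` is
    configurable because "the following day (+/- 2 days)" admits more than
    one reading; the default takes offsets of one or two days.
    """

    day_window: tuple[int, int] = (1, 2)
    time_tolerance_s: float = 3600.0
    require_opponents_within_10m: bool = True
    conflict_free_window_s: float = 600.0
    # whether MC bystander eligibility means presence at any point of the
    # follow; per-instant presence is not representable in this record format
    bystander_presence_scope: str = "any"

    @classmethod
    def from_yaml(cls, path) -> "MatchConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("time_tolerance_s", "require_opponents_within_10m",
                    "conflict_free_window_s", "bystander_presence_scope"):
            if key in raw:
                kwargs[key] = raw[key]
        if "day_window" in raw:
            lo, hi = raw["day_window"]
            kwargs["day_window"] = (int(lo), int(hi))
        return cls(**kwargs)


@dataclass(frozen=True)
class MatchResult:
    status: str  # valid | invalid | postpone
    reason: str = ""

    def __bool__(self) -> bool:
        return self.status == "valid"


def validate_matched_control(
    conflict: ConflictEvent,
    pc: FocalFollow,
    mc_candidate: FocalFollow,
    history: Iterable[ConflictEvent],
    config: MatchConfig | None = None,
) -> MatchResult:
    """Check an MC candidate against the matched-control scheduling rule.

    Returns ``valid``, ``invalid`` (with a reason), or ``postpone`` when the
    focal was involved in a conflict within the preceding ten minutes, in
    which case field protocol delays the MC rather than discarding it.
    """
    config = config or MatchConfig()
    if mc_candidate.focal_id != conflict.victim_id:
        raise ValueError(
            f"MC candidate focal {mc_candidate.focal_id!r} does not match "
            f"conflict victim {conflict.victim_id!r}"
        )
    lo, hi = config.day_window
    offset = (mc_candidate.date - conflict.date).days
    if not lo <= offset <= hi:
        return MatchResult("invalid", "day_window")
    if abs(mc_candidate.start_time_s - conflict.time_s) > config.time_tolerance_s:
        return MatchResult("invalid", "time_of_day")
    if config.require_opponents_within_10m:
        bands = dict(mc_candidate.bystanders_present)
        if bands.get(conflict.aggressor_id) not in WITHIN_10M:
            return MatchResult("invalid", "opponents_not_within_10m")
    focal = conflict.victim_id
    window = config.conflict_free_window_s
    for other in history:
        if other.conflict_id == conflict.conflict_id:
            continue
        if focal not in (other.victim_id, other.aggressor_id):
            continue
        if other.date != mc_candidate.date:
            continue
        if mc_candidate.start_time_s - window <= other.time_s <= mc_candidate.start_time_s:
            return MatchResult("postpone", "focal_in_recent_conflict")
    return MatchResult("valid")


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    individuals: dict[str, Individual] = field(default_factory=dict)
    conflicts: dict[int, ConflictEvent] = field(default_factory=dict)
    follows: list[FocalFollow] = field(default_factory=list)
    scans: list[ScanSample] = field(default_factory=list)
    #: conflict_id -> reason, for conflicts whose PC lacks a usable MC
    excluded: dict[int, str] = field(default_factory=dict)

    # -- convenience views ---------------------------------------------------

    def follows_by_kind(self, kind: str) -> dict[int, FocalFollow]:
        return {f.conflict_id: f for f in self.follows if f.kind == kind}

    def analysis_ids(self, exclude_infants: bool = True) -> list[str]:
        """Subject ids entering analyses; dependent infants are excluded."""
        return sorted(
            i for i, ind in self.individuals.items()
            if not (exclude_infants and ind.is_infant)
        )

    def retained_pairs(self) -> list[tuple[ConflictEvent, FocalFollow, FocalFollow]]:
        """(conflict, PC, MC) triples surviving matched-control validation."""
        pcs = self.follows_by_kind("PC")
        mcs = self.follows_by_kind("MC")
        out = []
        for cid in sorted(self.conflicts):
            if cid in self.excluded:
                continue
            if cid in pcs and cid in mcs:
                out.append((self.conflicts[cid], pcs[cid], mcs[cid]))
        return out

    def canonicalize(self) -> "Dataset":
        """Return a copy in the canonical on-disk ordering."""
        follows = []
        for f in sorted(self.follows, key=lambda f: (f.conflict_id, f.kind)):
            follows.append(
                replace(
                    f,
                    contacts=sorted(
                        f.contacts,
                        key=lambda c: (c.time_s, c.initiator_id, c.recipient_id),
                    ),
                    self_directed=sorted(
                        f.self_directed, key=lambda s: (s.time_s, s.kind)
                    ),
                    bystanders_present=sorted(f.bystanders_present),
                )
            )
        conflicts = {}
        for cid in sorted(self.conflicts):
            c = self.conflicts[cid]
            conflicts[cid] = replace(c, bystanders=sorted(c.bystanders))
        scans = [
            replace(s, engaged=sorted(s.engaged))
            for s in sorted(self.scans, key=lambda s: (s.group_id, s.date, s.time_s))
        ]
        individuals = {i: self.individuals[i] for i in sorted(self.individuals)}
        return Dataset(individuals, conflicts, follows, scans, dict(self.excluded))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_id(id_: str, where: str) -> None:
    for ch in _RESERVED_ID_CHARS:
        if ch in id_:
            raise IntegrityError(f"{where}: id {id_!r} contains reserved character {ch!r}")


def validate_dataset(ds: Dataset, match_config: MatchConfig | None = None) -> dict[int, str]:
    """Check referential integrity and record invariants.

    Raises :class:`IntegrityError` on hard violations.  Returns the mapping
    of conflict ids to exclusion reasons for conflicts whose PC lacks a
    valid matched control (these are excluded downstream rather than being
    treated as errors, mirroring field practice).
    """
    match_config = match_config or MatchConfig()
    ids = set(ds.individuals)
    for ind in ds.individuals.values():
        _check_id(ind.id, "roster")
        if ind.sex not in SEXES:
            raise IntegrityError(f"individual {ind.id}: bad sex {ind.sex!r}")
        if ind.age_class not in AGE_CLASSES:
            raise IntegrityError(f"individual {ind.id}: bad age class {ind.age_class!r}")
        if ind.rearing not in REARING_TYPES:
            raise IntegrityError(f"individual {ind.id}: bad rearing {ind.rearing!r}")
        if ind.age_years < 0:
            raise IntegrityError(f"individual {ind.id}: negative age")
        if ind.mother_id is not None:
            mother = ds.individuals.get(ind.mother_id)
            if mother is None:
                raise IntegrityError(f"individual {ind.id}: unknown mother {ind.mother_id!r}")
            if mother.sex != "F" or mother.group_id != ind.group_id:
                raise IntegrityError(
                    f"individual {ind.id}: mother {ind.mother_id} must be a female "
                    "in the same group"
                )

    for c in ds.conflicts.values():
        where = f"conflict {c.conflict_id}"
        if c.victim_id == c.aggressor_id:
            raise IntegrityError(f"{where}: victim equals aggressor")
        for pid in (c.victim_id, c.aggressor_id):
            if pid not in ids:
                raise IntegrityError(f"{where}: unknown individual {pid!r}")
        if not 1 <= c.intensity <= 6:
            raise IntegrityError(f"{where}: intensity {c.intensity} outside 1-6")
        if c.context not in CONTEXTS:
            raise IntegrityError(f"{where}: unknown context {c.context!r}")
        seen = set()
        for bid, band in c.bystanders:
            if bid not in ids:
                raise IntegrityError(f"{where}: unknown bystander {bid!r}")
            if bid in (c.victim_id, c.aggressor_id):
                raise IntegrityError(f"{where}: opponent {bid} listed as bystander")
            if band not in PROXIMITY_BANDS:
                raise IntegrityError(f"{where}: bad proximity band {band!r}")
            if bid in seen:
                raise IntegrityError(f"{where}: duplicate bystander {bid}")
            seen.add(bid)
        if c.redirection_target is not None and c.redirection_target not in seen:
            raise IntegrityError(f"{where}: redirection target not among bystanders")

    pcs: dict[int, FocalFollow] = {}
    mcs: dict[int, FocalFollow] = {}
    for f in ds.follows:
        where = f"follow {f.follow_id}"
        if f.kind not in ("PC", "MC"):
            raise IntegrityError(f"{where}: kind must be PC or MC")
        c = ds.conflicts.get(f.conflict_id)
        if c is None:
            raise IntegrityError(f"{where}: unknown conflict {f.conflict_id}")
        if f.focal_id != c.victim_id:
            raise IntegrityError(f"{where}: focal is not the conflict victim")
        store = pcs if f.kind == "PC" else mcs
        if f.conflict_id in store:
            raise IntegrityError(f"{where}: duplicate {f.kind} for conflict {f.conflict_id}")
        store[f.conflict_id] = f
        if f.kind == "PC":
            if f.date != c.date or abs(f.start_time_s - c.time_s) > 1.0:
                raise IntegrityError(f"{where}: PC must start at conflict end")
        for ev in f.contacts:
            if not 0.0 <= ev.time_s <= f.duration_s:
                raise IntegrityError(f"{where}: contact at {ev.time_s}s outside follow")
            if ev.initiator_id == ev.recipient_id:
                raise IntegrityError(f"{where}: self-contact recorded")
            if ev.behavior not in AFFILIATIVE_BEHAVIORS:
                raise IntegrityError(f"{where}: unknown behavior {ev.behavior!r}")
            for pid in (ev.initiator_id, ev.recipient_id):
                if pid not in ids:
                    raise IntegrityError(f"{where}: unknown individual {pid!r}")
        for ev in f.self_directed:
            if not 0.0 <= ev.time_s <= f.duration_s:
                raise IntegrityError(f"{where}: self-directed event outside follow")
            if ev.kind not in SELF_DIRECTED_KINDS:
                raise IntegrityError(f"{where}: unknown self-directed kind {ev.kind!r}")
        for bid, band in f.bystanders_present:
            if bid not in ids:
                raise IntegrityError(f"{where}: unknown bystander {bid!r}")
            if band not in PROXIMITY_BANDS:
                raise IntegrityError(f"{where}: bad proximity band {band!r}")

    last_scan: dict[tuple[str, _dt.date], float] = {}
    for s in sorted(ds.scans, key=lambda s: (s.group_id, s.date, s.time_s)):
        where = f"scan {s.scan_id}"
        for pid in s.present_ids:
            if pid not in ids:
                raise IntegrityError(f"{where}: unknown individual {pid!r}")
        for a, b, beh in s.engaged:
            if a not in s.present_ids or b not in s.present_ids:
                raise IntegrityError(f"{where}: engaged pair not among present")
            if beh not in SCAN_BEHAVIORS:
                raise IntegrityError(f"{where}: unknown scan behavior {beh!r}")
        key = (s.group_id, s.date)
        if key in last_scan and s.time_s - last_scan[key] < 600.0 - 1e-9:
            raise IntegrityError(f"{where}: scans closer than 10 min within a session")
        last_scan[key] = s.time_s

    # matched-control screening: flag conflicts whose PC lacks a usable MC
    history = list(ds.conflicts.values())
    exclusions: dict[int, str] = {}
    for cid, pc in pcs.items():
        c = ds.conflicts[cid]
        mc = mcs.get(cid)
        if mc is None:
            exclusions[cid] = "no_matched_control"
            continue
        res = validate_matched_control(c, pc, mc, history, match_config)
        if res.status != "valid":
            exclusions[cid] = res.reason or res.status
    return exclusions


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _opt(value: str) -> Optional[str]:
    return value if value else None


def _parse_date(value: str, path, line) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as exc:
        raise ParseError(path, line, f"bad date {value!r}") from exc


def _parse_float(value: str, path, line, name) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(path, line, f"bad {name} {value!r}") from exc


def _unpack_banded(value: str, path, line) -> list[tuple[str, str]]:
    out = []
    if not value:
        return out
    for item in value.split(";"):
        parts = item.split("|")
        if len(parts) != 2:
            raise ParseError(path, line, f"bad id|band item {item!r}")
        out.append((parts[0], parts[1]))
    return out


def _reader(path, expected_cols):
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if rows and not set(expected_cols) <= set(rows[0]):
        missing = sorted(set(expected_cols) - set(rows[0]))
        raise ParseError(path, 1, f"missing columns {missing}")
    return rows


_ROSTER_COLS = ("id", "sex", "age_years", "age_class", "rearing", "mother_id", "group_id")


def read_roster(path) -> dict[str, Individual]:
    individuals: dict[str, Individual] = {}
    for lineno, row in enumerate(_reader(path, _ROSTER_COLS), start=2):
        ind = Individual(
            id=row["id"],
            name=row.get("name", "") or row["id"],
            sex=row["sex"],
            age_years=_parse_float(row["age_years"], path, lineno, "age"),
            age_class=row["age_class"],
            rearing=row["rearing"],
            mother_id=_opt(row["mother_id"]),
            group_id=row["group_id"],
        )
        if ind.id in individuals:
            raise ParseError(path, lineno, f"duplicate id {ind.id!r}")
        individuals[ind.id] = ind
    return individuals


_CONFLICT_COLS = (
    "conflict_id", "group_id", "date", "time_s", "victim_id", "aggressor_id",
    "context", "intensity", "bystanders", "redirection_target",
)


def read_conflicts(path) -> dict[int, ConflictEvent]:
    conflicts: dict[int, ConflictEvent] = {}
    for lineno, row in enumerate(_reader(path, _CONFLICT_COLS), start=2):
        try:
            cid = int(row["conflict_id"])
            intensity = int(row["intensity"])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        c = ConflictEvent(
            conflict_id=cid,
            group_id=row["group_id"],
            date=_parse_date(row["date"], path, lineno),
            time_s=_parse_float(row["time_s"], path, lineno, "time_s"),
            victim_id=row["victim_id"],
            aggressor_id=row["aggressor_id"],
            context=row["context"],
            intensity=intensity,
            bystanders=_unpack_banded(row["bystanders"], path, lineno),
            redirection_target=_opt(row["redirection_target"]),
        )
        if cid in conflicts:
            raise ParseError(path, lineno, f"duplicate conflict_id {cid}")
        conflicts[cid] = c
    return conflicts


_FOLLOW_COLS = (
    "follow_id", "conflict_id", "kind", "focal_id", "date", "start_time_s",
    "duration_s", "record", "time_s", "actor_id", "partner_id", "behavior",
    "event_duration_s", "proximity_band",
)


def read_follows(path) -> list[FocalFollow]:
    follows: dict[str, FocalFollow] = {}
    for lineno, row in enumerate(_reader(path, _FOLLOW_COLS), start=2):
        rec = row["record"]
        fid = row["follow_id"]
        if rec == "follow":
            if fid in follows:
                raise ParseError(path, lineno, f"duplicate follow {fid!r}")
            follows[fid] = FocalFollow(
                follow_id=fid,
                conflict_id=int(row["conflict_id"]),
                kind=row["kind"],
                focal_id=row["focal_id"],
                date=_parse_date(row["date"], path, lineno),
                start_time_s=_parse_float(row["start_time_s"], path, lineno, "start"),
                duration_s=_parse_float(row["duration_s"], path, lineno, "duration"),
            )
            continue
        f = follows.get(fid)
        if f is None:
            raise ParseError(path, lineno, f"event row before follow row for {fid!r}")
        if rec == "bystander":
            f.bystanders_present.append((row["actor_id"], row["proximity_band"]))
        elif rec == "contact":
            f.contacts.append(
                ContactEvent(
                    time_s=_parse_float(row["time_s"], path, lineno, "time_s"),
                    initiator_id=row["actor_id"],
                    recipient_id=row["partner_id"],
                    behavior=row["behavior"],
                )
            )
        elif rec == "self_directed":
            f.self_directed.append(
                SelfDirectedEvent(
                    time_s=_parse_float(row["time_s"], path, lineno, "time_s"),
                    kind=row["behavior"],
                    duration_s=_parse_float(
                        row["event_duration_s"] or "0", path, lineno, "duration"
                    ),
                )
            )
        else:
            raise ParseError(path, lineno, f"unknown record type {rec!r}")
    return list(follows.values())


_SCAN_COLS = ("scan_id", "group_id", "date", "time_s", "present_ids", "engaged")


def read_scans(path) -> list[ScanSample]:
    scans = []
    for lineno, row in enumerate(_reader(path, _SCAN_COLS), start=2):
        engaged = []
        if row["engaged"]:
            for item in row["engaged"].split(";"):
                parts = item.split("|")
                if len(parts) != 3:
                    raise ParseError(path, lineno, f"bad engaged item {item!r}")
                engaged.append((parts[0], parts[1], parts[2]))
        present = frozenset(row["present_ids"].split(";")) if row["present_ids"] else frozenset()
        scans.append(
            ScanSample(
                scan_id=row["scan_id"],
                group_id=row["group_id"],
                date=_parse_date(row["date"], path, lineno),
                time_s=_parse_float(row["time_s"], path, lineno, "time_s"),
                present_ids=present,
                engaged=engaged,
            )
        )
    return scans


def load_dataset(
    roster_path,
    conflicts_path=None,
    follows_path=None,
    scans_path=None,
    match_config: MatchConfig | None = None,
) -> Dataset:
    """Load and validate a dataset from its CSV files.

    Conflicts whose PC lacks a valid matched control are flagged in
    ``Dataset.excluded`` and dropped from downstream pairing, not errors.
    """
    ds = Dataset(individuals=read_roster(roster_path))
    if conflicts_path is not None and Path(conflicts_path).exists():
        ds.conflicts = read_conflicts(conflicts_path)
    if follows_path is not None and Path(follows_path).exists():
        ds.follows = read_follows(follows_path)
    if scans_path is not None and Path(scans_path).exists():
        ds.scans = read_scans(scans_path)
    ds.excluded = validate_dataset(ds, match_config)
    return ds


def load_dataset_dir(directory, match_config: MatchConfig | None = None) -> Dataset:
    d = Path(directory)
    return load_dataset(
        d / "roster.csv", d / "conflicts.csv", d / "follows.csv", d / "scans.csv",
        match_config=match_config,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _pack_banded(items: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{i}|{b}" for i, b in items)


def write_dataset(ds: Dataset, directory) -> list[Path]:
    """Write a dataset to CSV files in canonical order; returns paths written.

    Only sections with content are written (a roster-only dataset produces a
    roster file only).  ``load_dataset_dir(write_dataset(d)) == d.canonicalize()``.
    """
    ds = ds.canonicalize()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    path = directory / "roster.csv"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("id", "name", "sex", "age_years", "age_class", "rearing",
                    "mother_id", "group_id"))
        for ind in ds.individuals.values():
            w.writerow((ind.id, ind.name, ind.sex, _fmt(ind.age_years), ind.age_class,
                        ind.rearing, _fmt(ind.mother_id), ind.group_id))
    written.append(path)

    if ds.conflicts:
        path = directory / "conflicts.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_CONFLICT_COLS)
            for c in ds.conflicts.values():
                w.writerow((c.conflict_id, c.group_id, c.date.isoformat(), _fmt(c.time_s),
                            c.victim_id, c.aggressor_id, c.context, c.intensity,
                            _pack_banded(c.bystanders), _fmt(c.redirection_target)))
        written.append(path)

    if ds.follows:
        path = directory / "follows.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_FOLLOW_COLS)
            for f in ds.follows:
                meta = (f.follow_id, f.conflict_id, f.kind, f.focal_id,
                        f.date.isoformat(), _fmt(f.start_time_s), _fmt(f.duration_s))
                w.writerow(meta + ("follow", "", "", "", "", "", ""))
                for bid, band in f.bystanders_present:
                    w.writerow(meta + ("bystander", "", bid, "", "", "", band))
                for ev in f.contacts:
                    w.writerow(meta + ("contact", _fmt(ev.time_s), ev.initiator_id,
                                       ev.recipient_id, ev.behavior, "", ""))
                for ev in f.self_directed:
                    w.writerow(meta + ("self_directed", _fmt(ev.time_s), "", "",
                                       ev.kind, _fmt(ev.duration_s), ""))
        written.append(path)

    if ds.scans:
        path = directory / "scans.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_SCAN_COLS)
            for s in ds.scans:
                w.writerow((s.scan_id, s.group_id, s.date.isoformat(), _fmt(s.time_s),
                            ";".join(sorted(s.present_ids)),
                            ";".join(f"{a}|{b}|{beh}" for a, b, beh in s.engaged)))
        written.append(path)
    return written
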