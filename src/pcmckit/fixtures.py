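"""Packaged reference data: the sanctuary roster and published study tallies."""

from __future__ import annotations

import json
from importlib import resources

from .ethogram_io import Individual, read_roster

_DATA = resources.files("pcmckit.data")


def reference_roster_path():
    """Path-like handle to the packaged two-group sanctuary roster CSV."""
    return _DATA / "roster_lola.csv"


def load_reference_roster() -> dict[str, Individual]:
    """Roster of the two semi-free-ranging bonobo study groups.

    Contains 36 named study subjects plus the dependent infants carried by
    their mothers (bringing group totals to 25 and 17).  Infants are loaded
    like any other individual and excluded from analyses by filter.
    """
    with resources.as_file(reference_roster_path()) as path:
        return read_roster(path)


def load_study_reference() -> dict:
    """Published summary tallies used for consistency checks and defaults."""
    return json.loads((_DATA / "study_reference.json").read_text())
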