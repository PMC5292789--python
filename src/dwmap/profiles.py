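"""Core EQ-5D data model: dimensions, severity levels, parsing, validation.

An EQ-5D health-state profile records one ordinal severity level for each
of five dimensions, in this fixed order:

====  ====================  ====
code  dimension             pos.
====  ====================  ====
mo    mobility              D1
sc    self-care             D2
ua    usual activities      D3
pd    pain/discomfort       D4
ad    anxiety/depression    D5
====  ====================  ====

The 3-level variant (``"3L"``) admits levels 1..3 per dimension, the
5-level variant (``"5L"``) levels 1..5; level 1 always means "no
problems".  Profiles are written as five-digit strings, e.g. ``"21345"``,
whose digits map *positionally* to D1..D5 — dimension order is never
inferred from column names alone, and readers map named columns to
positions explicitly.

Missing levels are rejected, not imputed: a response row with an empty or
non-numeric level is an error (complete answers are a precondition of the
valuation step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)
DIMENSION_CODES = ("mo", "sc", "ua", "pd", "ad")

#: maximum admissible level per instrument version
MAX_LEVEL = {"3L": 3, "5L": 5}

FULL_HEALTH_LEVELS = (1, 1, 1, 1, 1)

#: columns a response table must provide, in canonical order
REQUIRED_COLUMNS = ("respondent_id", "health_state_id") + DIMENSION_CODES

_DIGITS = frozenset("0123456789")


class ProfileError(ValueError):
    """An EQ-5D profile is malformed (wrong length, level out of range...)."""


class ResponseTableError(ValueError):
    """A response table cannot be read (missing columns, bad rows, empty)."""


def _normalize_version(version: str) -> str:
    v = str(version).upper()
    if v not in MAX_LEVEL:
        raise ProfileError(f"unknown EQ-5D version {version!r}; expected '3L' or '5L'")
    return v


@dataclass(frozen=True)
class EQ5DProfile:
    """One EQ-5D health-state description.

    Parameters
    ----------
    version : {"3L", "5L"}
        Instrument variant; bounds the admissible levels.
    levels : tuple of 5 int
        Severity levels for (mobility, self-care, usual activities,
        pain/discomfort, anxiety/depression), each in ``1..3`` (3L) or
        ``1..5`` (5L).
    """

    version: str
    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        version = _normalize_version(self.version)
        try:
            levels = tuple(int(l) for l in self.levels)
        except (TypeError, ValueError) as exc:
            raise ProfileError(f"levels must be integers, got {self.levels!r}") from exc
        if len(levels) != 5:
            raise ProfileError(f"expected exactly 5 levels, got {len(levels)}")
        hi = MAX_LEVEL[version]
        for pos, level in enumerate(levels, start=1):
            if not 1 <= level <= hi:
                raise ProfileError(
                    f"level {level} invalid for {version} (dimension D{pos}; "
                    f"admissible range 1..{hi})"
                )
        object.__setattr__(self, "version", version)
        object.__setattr__(self, "levels", levels)

    @property
    def is_full_health(self) -> bool:
        return self.levels == FULL_HEALTH_LEVELS

    def __str__(self) -> str:
        return format_profile(self)


def parse_profile(text: str, version: str = "5L") -> EQ5DProfile:
    """Parse a five-digit profile string into a validated :class:`EQ5DProfile`.

    Digits map positionally to D1..D5, e.g. ``parse_profile("54321", "5L")``
    gives levels ``(5, 4, 3, 2, 1)``.

    Raises
    ------
    ProfileError
        If the string is not exactly five ASCII digits or any digit is
        outside the version's level range.
    """
    if not isinstance(text, str):
        raise ProfileError(f"profile must be a string, got {type(text).__name__}")
    if len(text) != 5:
        raise ProfileError(f"profile string must have length 5, got {len(text)} ({text!r})")
    if not set(text) <= _DIGITS:
        raise ProfileError(f"profile string must be all digits, got {text!r}")
    return EQ5DProfile(version, tuple(int(c) for c in text))


def format_profile(profile: EQ5DProfile) -> str:
    """Inverse of :func:`parse_profile`: the five-digit string for a profile."""
    return "".join(str(l) for l in profile.levels)


@dataclass
class ResponseRecord:
    """One respondent's evaluation of one health state.

    ``health_state_id`` refers to a row of the health-state reference
    table (GBD numbering); validation against a loaded reference happens
    at scoring time, where a reference is available.
    """

    respondent_id: str
    health_state_id: int
    profile: EQ5DProfile
    demographics: Mapping[str, object] | None = field(default=None)


# ---------------------------------------------------------------------------
# delimited response tables

def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_responses(path, version: str = "5L") -> list[ResponseRecord]:
    """Read a delimited response table (comma- or tab-separated, header row).

    Required columns: ``respondent_id, health_state_id, mo, sc, ua, pd, ad``.
    Any additional columns are carried along as demographics.  Invalid rows
    are reported with their line number; missing levels are an error.
    """
    version = _normalize_version(version)
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"respondent_id": str})
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise ResponseTableError(f"no responses: {path} is empty") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseTableError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ResponseTableError(f"no responses in {path}")

    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    records: list[ResponseRecord] = []
    # +2: header line plus 1-based numbering
    for i, row in enumerate(df.to_dict("records")):
        line_no = i + 2
        raw_levels = [row[c] for c in DIMENSION_CODES]
        if any(pd.isna(v) for v in raw_levels) or pd.isna(row["health_state_id"]):
            raise ResponseTableError(f"{path}, line {line_no}: missing level or state id")
        try:
            profile = EQ5DProfile(version, tuple(raw_levels))
        except ProfileError as exc:
            raise ResponseTableError(f"{path}, line {line_no}: {exc}") from exc
        demographics = {c: row[c] for c in extra_cols if not pd.isna(row[c])} or None
        records.append(
            ResponseRecord(
                respondent_id=str(row["respondent_id"]),
                health_state_id=int(row["health_state_id"]),
                profile=profile,
                demographics=demographics,
            )
        )
    return records


def responses_to_frame(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Tabulate records into the canonical response-table layout."""
    rows = []
    for rec in records:
        row = {"respondent_id": rec.respondent_id, "health_state_id": rec.health_state_id}
        row.update(dict(zip(DIMENSION_CODES, rec.profile.levels)))
        if rec.demographics:
            row.update(rec.demographics)
        rows.append(row)
    if not rows:
        raise ResponseTableError("no responses to write")
    return pd.DataFrame(rows)


def write_responses(records: Iterable[ResponseRecord], path, sep: str = ",") -> None:
    """Write records as a delimited table readable by :func:`read_responses`."""
    responses_to_frame(records).to_csv(path, sep=sep, index=False)
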