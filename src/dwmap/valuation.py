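"""Utility valuation of EQ-5D profiles: crosswalk and additive tariff engine.

A *value set* (tariff) turns a 3L profile into a utility on a scale where
1 is full health and 0 is death; states judged worse than death come out
negative and are passed through unclipped.  The engine is the standard
additive decrement form used by European 3L value sets such as the
Belgian one:

    U(p) = 1 - c * [p != 11111] - sum_d delta(d, level_d) - sum_k gamma_k * I_k(p)

where ``c`` is a constant decrement for any departure from full health,
``delta(d, l)`` the decrement for dimension ``d`` at level ``l`` in
{2, 3}, and the ``I_k`` indicator terms (e.g. "any dimension at level 3")
carry extra decrements ``gamma_k``.

Because no 3L-style tariff exists natively for the 5L descriptive system,
5L profiles are first translated into the 3L valuation space by a
*crosswalk*: either the EuroQol row-stochastic probability matrix mapping
each of the 3125 5L profiles onto the 243 3L profiles (supplied as a data
file), or a deterministic level collapse (1→1, {2,3}→2, {4,5}→3) that is
an explicitly labelled stand-in and warns on use.

Coefficients are data, not code: value sets load from YAML documents and
probability crosswalks from delimited matrices, so a properly transcribed
published tariff drops in without touching the engine.
"""

from __future__ import annotations

import importlib.resources
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .profiles import (
    DIMENSION_CODES,
    EQ5DProfile,
    ProfileError,
    ResponseRecord,
    parse_profile,
)

__all__ = [
    "ValueSet",
    "IndicatorTerm",
    "CrosswalkTable",
    "StandInCrosswalkWarning",
    "apply_value_set",
    "crosswalk_5to3",
    "utility_5l",
    "score_responses",
    "UtilityScorer",
    "load_value_set",
    "save_value_set",
    "load_crosswalk",
    "save_crosswalk",
    "load_packaged_value_set",
    "all_3l_profiles",
]

#: deterministic 5L -> 3L level collapse
COLLAPSE_LEVEL_MAP = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3}

#: named indicator predicates a value set may reference (over 3L levels)
INDICATOR_PREDICATES: dict[str, Callable[[tuple[int, ...]], bool]] = {
    "any_level_2": lambda levels: any(l == 2 for l in levels),
    "any_level_3": lambda levels: any(l == 3 for l in levels),
    "all_level_3": lambda levels: all(l == 3 for l in levels),
}


class StandInCrosswalkWarning(UserWarning):
    """The deterministic level collapse is a stand-in, not the published matrix."""


@dataclass(frozen=True)
class IndicatorTerm:
    """A named on/off decrement, e.g. ``any_level_3``."""

    name: str
    decrement: float

    def triggered(self, profile: EQ5DProfile) -> bool:
        return INDICATOR_PREDICATES[self.name](profile.levels)


@dataclass
class ValueSet:
    """Additive 3L tariff coefficients.

    ``level_decrements`` is keyed by ``(dimension 1..5, level 2..3)``; the
    utility of full health ``11111`` is exactly 1 by construction (no term
    applies).  Decrements are typically positive; resulting utilities may
    be negative (worse than death) and are never clipped.
    """

    name: str
    intercept_constant: float
    level_decrements: Mapping[tuple[int, int], float]
    indicator_terms: tuple[IndicatorTerm, ...] = ()

    def __post_init__(self) -> None:
        decs = {}
        for key, value in dict(self.level_decrements).items():
            d, l = (int(key[0]), int(key[1]))
            if not (1 <= d <= 5 and 2 <= l <= 3):
                raise ValueError(f"level_decrements key {key!r}: expected dimension 1..5, level 2..3")
            decs[(d, l)] = float(value)
        expected = {(d, l) for d in range(1, 6) for l in (2, 3)}
        missing = expected - set(decs)
        if missing:
            raise ValueError(f"value set {self.name!r} missing decrements for {sorted(missing)}")
        if not np.isfinite(list(decs.values())).all() or not np.isfinite(self.intercept_constant):
            raise ValueError(f"value set {self.name!r} has non-finite coefficients")
        terms = tuple(self.indicator_terms)
        for t in terms:
            if t.name not in INDICATOR_PREDICATES:
                raise ValueError(
                    f"unknown indicator term {t.name!r}; known: {sorted(INDICATOR_PREDICATES)}"
                )
            if not np.isfinite(t.decrement):
                raise ValueError(f"indicator term {t.name!r} has non-finite decrement")
        self.level_decrements = decs
        self.indicator_terms = terms


def apply_value_set(profile: EQ5DProfile, value_set: ValueSet) -> float:
    """Evaluate the additive tariff for a 3L profile.

    Raises ``ValueError`` for a 5L profile (use :func:`utility_5l`, which
    routes through a crosswalk first).
    """
    if profile.version != "3L":
        raise ValueError(
            "apply_value_set expects a 3L profile; pass 5L profiles through a "
            "crosswalk (utility_5l) first"
        )
    if profile.is_full_health:
        return 1.0
    u = 1.0 - value_set.intercept_constant
    for d, level in enumerate(profile.levels, start=1):
        if level >= 2:
            u -= value_set.level_decrements[(d, level)]
    for term in value_set.indicator_terms:
        if term.triggered(profile):
            u -= term.decrement
    return u


def all_3l_profiles() -> list[EQ5DProfile]:
    """All 243 3L profiles in lexicographic order of their digit strings."""
    return [EQ5DProfile("3L", levels) for levels in itertools.product((1, 2, 3), repeat=5)]


@dataclass
class CrosswalkTable:
    """A 5L -> 3L translation.

    ``kind="probability_matrix"`` wraps a row-stochastic table (rows keyed
    by 5L profile strings, columns by 3L profile strings, rows summing to
    1 within 1e-9); ``kind="deterministic_collapse"`` is the fixed level
    map 1→1, {2,3}→2, {4,5}→3, shipped as an explicitly labelled stand-in
    for the published matrix — it warns once per table on first use.
    """

    kind: str
    matrix: pd.DataFrame | None = None
    _warned: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("deterministic_collapse", "probability_matrix"):
            raise ValueError(f"unknown crosswalk kind {self.kind!r}")
        if self.kind == "probability_matrix":
            if self.matrix is None:
                raise ValueError("probability_matrix crosswalk requires a matrix")
            m = self.matrix
            for col in m.columns:
                parse_profile(str(col), "3L")  # validates digits and range
            for idx in m.index:
                parse_profile(str(idx), "5L")
            if (m.values < -1e-12).any():
                raise ValueError("crosswalk matrix has negative weights")
            bad = np.abs(m.sum(axis=1).to_numpy() - 1.0) > 1e-9
            if bad.any():
                raise ValueError(
                    f"crosswalk matrix rows must sum to 1 (±1e-9); offending rows: "
                    f"{list(m.index[bad][:5])}"
                )
        elif self.matrix is not None:
            raise ValueError("deterministic_collapse takes no matrix")

    @classmethod
    def collapse(cls) -> "CrosswalkTable":
        """The deterministic level-collapse stand-in."""
        return cls(kind="deterministic_collapse")

    def _warn_stand_in(self) -> None:
        if self.kind == "deterministic_collapse" and not self._warned:
            warnings.warn(
                "using the deterministic 5L->3L level collapse, a stand-in for the "
                "published EuroQol crosswalk matrix; supply a probability-matrix "
                "crosswalk file for published-tariff scoring",
                StandInCrosswalkWarning,
                stacklevel=3,
            )
            self._warned = True


def crosswalk_5to3(profile: EQ5DProfile, crosswalk: CrosswalkTable):
    """Translate one 5L profile into the 3L valuation space.

    Returns a single :class:`EQ5DProfile` for the deterministic collapse,
    or a list of ``(EQ5DProfile, weight)`` pairs (weights > 0, summing to
    1) for a probability matrix.
    """
    if profile.version != "5L":
        raise ValueError("crosswalk_5to3 expects a 5L profile")
    if crosswalk.kind == "deterministic_collapse":
        crosswalk._warn_stand_in()
        return EQ5DProfile("3L", tuple(COLLAPSE_LEVEL_MAP[l] for l in profile.levels))
    key = str(profile)
    try:
        row = crosswalk.matrix.loc[key]
    except KeyError as exc:
        raise ValueError(f"crosswalk matrix has no row for 5L profile {key!r}") from exc
    return [
        (parse_profile(str(col), "3L"), float(w))
        for col, w in row.items()
        if float(w) > 0.0
    ]


def utility_5l(profile: EQ5DProfile, crosswalk: CrosswalkTable, value_set: ValueSet) -> float:
    """Score a 5L profile: crosswalk to 3L, then apply the tariff.

    With a probability-matrix crosswalk the result is the expected utility,
    i.e. the weight row dotted with the 3L utility vector.
    """
    mapped = crosswalk_5to3(profile, crosswalk)
    if isinstance(mapped, EQ5DProfile):
        return apply_value_set(mapped, value_set)
    return float(sum(w * apply_value_set(p3, value_set) for p3, w in mapped))


def score_responses(
    records: Iterable[ResponseRecord],
    crosswalk: CrosswalkTable,
    value_set: ValueSet,
    reference_ids: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Score a batch of responses; one row per response with its utility.

    If ``reference_ids`` is given, every record's ``health_state_id`` must
    be in it (the reference-table invariant).
    """
    records = list(records)
    if not records:
        raise ValueError("no responses to score")
    if reference_ids is not None:
        known = set(int(i) for i in reference_ids)
        unknown = sorted({r.health_state_id for r in records} - known)
        if unknown:
            raise ValueError(f"health_state_id(s) {unknown} not in the reference table")
    rows = []
    for rec in records:
        if rec.profile.version == "5L":
            u = utility_5l(rec.profile, crosswalk, value_set)
        else:
            u = apply_value_set(rec.profile, value_set)
        rows.append(
            {
                "respondent_id": rec.respondent_id,
                "health_state_id": rec.health_state_id,
                "profile": str(rec.profile),
                "utility": u,
            }
        )
    return pd.DataFrame(rows)


class UtilityScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: EQ-5D profiles -> utilities.

    Parameters
    ----------
    value_set : ValueSet or None
        Tariff to apply; ``None`` loads the packaged synthetic
        Belgian-style 3L set.
    crosswalk : CrosswalkTable or None
        5L -> 3L translation; ``None`` uses the deterministic level
        collapse stand-in (which warns on use).

    After :meth:`fit`, the resolved components are available as
    ``value_set_`` and ``crosswalk_``.  :meth:`transform` accepts an
    iterable of :class:`EQ5DProfile`, five-digit strings (assumed 5L), or
    a DataFrame with the ``mo..ad`` level columns, and returns a float
    array of utilities.
    """

    def __init__(self, value_set: ValueSet | None = None, crosswalk: CrosswalkTable | None = None):
        self.value_set = value_set
        self.crosswalk = crosswalk

    def fit(self, X=None, y=None) -> "UtilityScorer":
        self.value_set_ = self.value_set if self.value_set is not None else load_packaged_value_set()
        self.crosswalk_ = self.crosswalk if self.crosswalk is not None else CrosswalkTable.collapse()
        return self

    def _coerce(self, x) -> EQ5DProfile:
        if isinstance(x, EQ5DProfile):
            return x
        if isinstance(x, str):
            return parse_profile(x, "5L")
        if isinstance(x, Sequence) and len(x) == 5:
            return EQ5DProfile("5L", tuple(int(v) for v in x))
        raise ProfileError(f"cannot interpret {x!r} as an EQ-5D profile")

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "value_set_"):
            raise ValueError("UtilityScorer is not fitted; call fit() first")
        if isinstance(X, pd.DataFrame):
            profiles = [
                EQ5DProfile("5L", tuple(int(v) for v in row))
                for row in X[list(DIMENSION_CODES)].itertuples(index=False)
            ]
        else:
            profiles = [self._coerce(x) for x in X]
        out = np.empty(len(profiles), dtype=float)
        for i, p in enumerate(profiles):
            if p.version == "5L":
                out[i] = utility_5l(p, self.crosswalk_, self.value_set_)
            else:
                out[i] = apply_value_set(p, self.value_set_)
        return out


# ---------------------------------------------------------------------------
# file formats

def load_value_set(path) -> ValueSet:
    """Load a tariff from a YAML document.

    Layout::

        name: ...
        intercept_constant: 0.152
        level_decrements:
          d1: {l2: 0.096, l3: 0.322}
          ...
          d5: {l2: 0.062, l3: 0.204}
        indicator_terms:
          - {name: any_level_3, decrement: 0.256}
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _value_set_from_dict(doc, fallback_name=str(path))


def _value_set_from_dict(doc: Mapping, fallback_name: str = "unnamed") -> ValueSet:
    decs = {}
    for dkey, levels in doc["level_decrements"].items():
        d = int(str(dkey).lstrip("dD"))
        for lkey, val in levels.items():
            decs[(d, int(str(lkey).lstrip("lL")))] = float(val)
    terms = tuple(
        IndicatorTerm(name=t["name"], decrement=float(t["decrement"]))
        for t in doc.get("indicator_terms", []) or []
    )
    return ValueSet(
        name=str(doc.get("name", fallback_name)),
        intercept_constant=float(doc["intercept_constant"]),
        level_decrements=decs,
        indicator_terms=terms,
    )


def save_value_set(value_set: ValueSet, path) -> None:
    doc = {
        "name": value_set.name,
        "intercept_constant": float(value_set.intercept_constant),
        "level_decrements": {
            f"d{d}": {
                f"l{l}": float(value_set.level_decrements[(d, l)]) for l in (2, 3)
            }
            for d in range(1, 6)
        },
        "indicator_terms": [
            {"name": t.name, "decrement": float(t.decrement)} for t in value_set.indicator_terms
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_crosswalk(path) -> CrosswalkTable:
    """Load a probability-matrix crosswalk from a delimited file.

    First column ``profile5`` holds 5L profile strings; remaining column
    names are 3L profile strings; each row is a weight vector over 3L
    profiles summing to 1.
    """
    df = pd.read_csv(path, dtype={"profile5": str})
    if "profile5" not in df.columns:
        raise ValueError(f"{path}: crosswalk file needs a 'profile5' key column")
    df = df.set_index("profile5")
    df.columns = [str(c) for c in df.columns]
    return CrosswalkTable(kind="probability_matrix", matrix=df.astype(float))


def save_crosswalk(crosswalk: CrosswalkTable, path) -> None:
    if crosswalk.kind != "probability_matrix":
        raise ValueError("only probability-matrix crosswalks serialize to file")
    crosswalk.matrix.rename_axis("profile5").to_csv(path)


def load_packaged_value_set() -> ValueSet:
    """The packaged *synthetic* Belgian-style 3L value set.

    Synthetic: plausible magnitudes in the published Belgian set's additive
    form (constant + per-dimension decrements + an any-level-3 term,
    negative utilities possible for the worst states), packaged so the
    pipeline runs end to end with zero external material.  Substitute a
    transcribed published tariff file for real valuation work.
    """
    ref = importlib.resources.files("dwmap.data") / "value_set_be3l_synthetic.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_value_set(path)
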