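"""Descriptive and inferential comparisons of utilities against GBD DWs.

The pilot-study analyses this module reproduces:

* per-state utility summaries (mean, sample SD, median, range, fraction
  negative / equal to 1);
* Spearman rank correlation between state mean utilities and the GBD
  2010/2013 disability weights, with an exact permutation p-value for
  very small samples (n <= 8, full n! enumeration) and the usual
  t-approximation otherwise;
* a paired t-test of the utility complements (1 - u) against the DWs;
* the complement-difference table d_s = (1 - mean u_s) - DW_s with its
  mean, SD and named extremes;
* severity rank tables (rank 1 = least severe: lowest DW, highest
  utility; midranks on ties) with above/below-median flags;
* dimension-by-level response frequency tables.

All tests are two-sided.  State-level means are the default unit of
analysis; respondent-level utilities can be fed in wherever a plain
vector is accepted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import DIMENSION_CODES, ResponseRecord

__all__ = [
    "UtilitySummary",
    "PairedTResult",
    "DiffTable",
    "ComparisonReport",
    "summarize_utilities",
    "summarize_by_state",
    "spearman_rho",
    "spearman_p",
    "paired_t",
    "complement_difference_table",
    "rank_table",
    "dimension_level_frequencies",
    "compare_to_reference",
]

EXACT_P_MAX_N = 8  # full-permutation enumeration bound (n! <= 40320)


@dataclass(frozen=True)
class UtilitySummary:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    fraction_negative: float
    fraction_equal_one: float
    health_state_id: int | None = None


def summarize_utilities(values: Sequence[float], health_state_id: int | None = None) -> UtilitySummary:
    """Textbook summary statistics of a utility vector (SD uses n-1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list of utilities")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return UtilitySummary(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        fraction_negative=float(np.mean(arr < 0.0)),
        fraction_equal_one=float(np.mean(arr == 1.0)),
        health_state_id=health_state_id,
    )


def summarize_by_state(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-state summaries from a scored response table.

    ``scored`` needs columns ``health_state_id`` and ``utility`` (the
    output of :func:`dwmap.valuation.score_responses`).
    """
    if scored.empty:
        raise ValueError("no scored responses to summarize")
    rows = []
    for sid, grp in scored.groupby("health_state_id", sort=True):
        s = summarize_utilities(grp["utility"].to_numpy(), health_state_id=int(sid))
        rows.append(
            {
                "health_state_id": s.health_state_id,
                "n": s.n,
                "mean_utility": s.mean,
                "sd_utility": s.sd,
                "median_utility": s.median,
                "min_utility": s.min,
                "max_utility": s.max,
                "fraction_negative": s.fraction_negative,
                "fraction_equal_one": s.fraction_equal_one,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank correlation

def _check_paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise ValueError("need at least 2 paired observations")
    return xa, ya


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    xa, ya = _check_paired(x, y)
    if np.ptp(stats.rankdata(xa)) == 0 or np.ptp(stats.rankdata(ya)) == 0:
        raise ValueError("zero rank variance: a vector is constant")
    return float(stats.spearmanr(xa, ya).statistic)


def spearman_p(x: Sequence[float], y: Sequence[float], method: str = "t_approx") -> float:
    """Two-sided p-value for Spearman's rho.

    ``method="exact_permutation"`` enumerates all n! permutations of one
    vector (n <= 8) and reports the fraction attaining |rho| at least as
    large as observed; ``"t_approx"`` uses the usual t transform with
    n - 2 degrees of freedom.
    """
    xa, ya = _check_paired(x, y)
    rho_obs = spearman_rho(xa, ya)
    if method == "t_approx":
        return float(stats.spearmanr(xa, ya).pvalue)
    if method != "exact_permutation":
        raise ValueError(f"unknown method {method!r}")
    n = xa.size
    if n > EXACT_P_MAX_N:
        raise ValueError(f"exact permutation p-value needs n <= {EXACT_P_MAX_N}, got {n}")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rxc = rx - rx.mean()
    denom_x = math.sqrt(float(rxc @ rxc))
    ryc = ry - ry.mean()
    denom_y = math.sqrt(float(ryc @ ryc))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho_perm = float(rxc @ ryc[list(perm)]) / (denom_x * denom_y)
        if abs(rho_perm) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# paired t-test

@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    df: int
    p_value: float | None
    degenerate: bool = False


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Classic paired t-test on a - b (df = n - 1), two-sided.

    Zero-variance differences are reported as degenerate (no p-value)
    rather than raising: a == b is a legitimate, if extreme, outcome.
    """
    aa, ba = _check_paired(a, b)
    d = aa - ba
    if np.std(d, ddof=1) == 0.0:
        return PairedTResult(statistic=float("nan"), df=int(d.size - 1), p_value=None, degenerate=True)
    res = stats.ttest_rel(aa, ba)
    return PairedTResult(
        statistic=float(res.statistic), df=int(d.size - 1), p_value=float(res.pvalue)
    )


# ---------------------------------------------------------------------------
# complement differences and ranks

def _means_series(mean_utilities) -> pd.Series:
    if isinstance(mean_utilities, pd.Series):
        s = mean_utilities.astype(float)
    elif isinstance(mean_utilities, Mapping):
        s = pd.Series({int(k): float(v) for k, v in mean_utilities.items()})
    else:
        raise TypeError("mean_utilities must be a mapping or Series keyed by health_state_id")
    if s.empty:
        raise ValueError("no state mean utilities supplied")
    s.index = s.index.astype(int)
    return s


def _align_ref(means: pd.Series, ref: pd.DataFrame) -> pd.DataFrame:
    ref = ref.set_index(ref["id"].astype(int), drop=False)
    missing = sorted(set(means.index) - set(ref.index))
    if missing:
        raise ValueError(f"health state id(s) {missing} missing from the reference table")
    return ref.loc[means.index]


@dataclass
class DiffTable:
    """Per-state complement differences d = (1 - mean u) - DW, plus aggregates."""

    dw_column: str
    table: pd.DataFrame = field(repr=False)
    mean: float = 0.0
    sd: float = 0.0
    min: float = 0.0
    min_state: str = ""
    max: float = 0.0
    max_state: str = ""


def complement_difference_table(
    mean_utilities, ref: pd.DataFrame, dw_column: str = "dw2010"
) -> DiffTable:
    """Differences between utility complements (1 - u) and the DWs.

    A difference near 0 means the study's severity judgement agrees with
    the GBD one; positive differences mean the study judged the state
    more severe than its DW implies.
    """
    means = _means_series(mean_utilities)
    aligned = _align_ref(means, ref)
    diffs = (1.0 - means) - aligned[dw_column]
    table = pd.DataFrame(
        {
            "health_state_id": means.index,
            "name": aligned["name"].to_numpy(),
            "mean_utility": means.to_numpy(),
            dw_column: aligned[dw_column].to_numpy(),
            "difference": diffs.to_numpy(),
        }
    ).reset_index(drop=True)
    i_min = int(table["difference"].idxmin())
    i_max = int(table["difference"].idxmax())
    sd = float(table["difference"].std(ddof=1)) if len(table) > 1 else float("nan")
    return DiffTable(
        dw_column=dw_column,
        table=table,
        mean=float(table["difference"].mean()),
        sd=sd,
        min=float(table.loc[i_min, "difference"]),
        min_state=str(table.loc[i_min, "name"]),
        max=float(table.loc[i_max, "difference"]),
        max_state=str(table.loc[i_max, "name"]),
    )


def _median_flag(values: np.ndarray, higher_is_severe: bool) -> list[str]:
    med = np.median(values)
    out = []
    for v in values:
        if v == med:
            out.append("equal")
        elif (v > med) == higher_is_severe:
            out.append("more_severe")
        else:
            out.append("less_severe")
    return out


def rank_table(mean_utilities, ref: pd.DataFrame) -> pd.DataFrame:
    """Severity ranks per state; rank 1 = least severe.

    DW ranks ascend with the DW; utility ranks descend with mean utility
    (highest utility = rank 1).  Ties get average ranks.  The
    ``*_vs_median`` columns flag each state against the study-specific
    median, the comparison drawn in the published ranking table.
    """
    means = _means_series(mean_utilities)
    if means.size < 2:
        raise ValueError("ranking needs at least 2 states")
    aligned = _align_ref(means, ref)
    u = means.to_numpy()
    out = pd.DataFrame(
        {
            "health_state_id": means.index,
            "name": aligned["name"].to_numpy(),
            "mean_utility": u,
            "utility_rank": stats.rankdata(-u, method="average"),
            "utility_vs_median": _median_flag(u, higher_is_severe=False),
        }
    )
    for col in ("dw2010", "dw2013"):
        dw = aligned[col].to_numpy(dtype=float)
        out[col] = dw
        out[f"{col}_rank"] = stats.rankdata(dw, method="average")
        out[f"{col}_vs_median"] = _median_flag(dw, higher_is_severe=True)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# dimension/level frequencies

def dimension_level_frequencies(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Percent of responses at each level, per state and dimension.

    One row per (health_state_id, dimension) with columns
    ``pct_level_1..pct_level_5``, the mean and sample SD of the integer
    levels, and the group size.  Percentages sum to 100 per row (up to
    float rounding).
    """
    records = list(records)
    if not records:
        raise ValueError("no responses")
    max_level = max(5 if r.profile.version == "5L" else 3 for r in records)
    rows = []
    by_state: dict[int, list[ResponseRecord]] = {}
    for rec in records:
        by_state.setdefault(rec.health_state_id, []).append(rec)
    for sid in sorted(by_state):
        grp = by_state[sid]
        levels = np.array([r.profile.levels for r in grp], dtype=float)  # (n, 5)
        n = levels.shape[0]
        for j, code in enumerate(DIMENSION_CODES):
            col = levels[:, j]
            row = {"health_state_id": sid, "dimension": code, "n": n}
            for lev in range(1, max_level + 1):
                row[f"pct_level_{lev}"] = 100.0 * float(np.mean(col == lev))
            row["mean_level"] = float(np.mean(col))
            row["sd_level"] = float(np.std(col, ddof=1)) if n > 1 else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full comparison

@dataclass
class ComparisonReport:
    """Everything the study's comparison section computes, for one DW column."""

    dw_column: str
    n: int
    rho: float
    rho_p: float
    p_method: str
    t: PairedTResult
    diffs: DiffTable = field(repr=False)
    ranks: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "dw_column": self.dw_column,
            "n": self.n,
            "rho": self.rho,
            "rho_p": self.rho_p,
            "p_method": self.p_method,
            "t_statistic": self.t.statistic,
            "t_df": self.t.df,
            "t_p": self.t.p_value,
            "t_degenerate": self.t.degenerate,
            "diff_mean": self.diffs.mean,
            "diff_sd": self.diffs.sd,
            "diff_min": self.diffs.min,
            "diff_min_state": self.diffs.min_state,
            "diff_max": self.diffs.max,
            "diff_max_state": self.diffs.max_state,
            "differences": self.diffs.table.to_dict("records"),
            "ranks": self.ranks.to_dict("records"),
        }


def compare_to_reference(
    mean_utilities,
    ref: pd.DataFrame,
    dw_column: str = "dw2010",
    p_method: str = "auto",
) -> ComparisonReport:
    """Run the full comparison of state mean utilities against one DW set.

    ``p_method="auto"`` picks the exact permutation p-value when n <= 8
    and the t approximation otherwise.
    """
    means = _means_series(mean_utilities)
    aligned = _align_ref(means, ref)
    dw = aligned[dw_column].to_numpy(dtype=float)
    u = means.to_numpy()
    if p_method == "auto":
        p_method = "exact_permutation" if u.size <= EXACT_P_MAX_N else "t_approx"
    rho = spearman_rho(u, dw)
    rho_p = spearman_p(u, dw, method=p_method)
    t = paired_t(1.0 - u, dw)
    diffs = complement_difference_table(means, ref, dw_column)
    ranks = rank_table(means, ref)
    return ComparisonReport(
        dw_column=dw_column,
        n=int(u.size),
        rho=rho,
        rho_p=rho_p,
        p_method=p_method,
        t=t,
        diffs=diffs,
        ranks=ranks,
    )
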