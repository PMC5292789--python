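"""Synthetic EQ-5D-5L response generator and the packaged reference table.

The generator emulates the structure the pipeline assumes of a valuation
survey: each health state has a true disability weight; respondents asked
to imagine the state answer the five EQ-5D dimensions; more severe states
draw systematically higher (worse) ordinal levels, so the expected derived
utility decreases as the true DW increases.

Mechanism: a latent-variable ordinal model with a shared severity signal.
For respondent x state x dimension d,

    latent = loading_d * logit(true_dw) + Normal(0, noise_sd)

and the observed level is 1 plus the number of cutpoints below the
latent value (levels 1..5).  The loadings set how strongly each dimension
tracks overall severity; the cutpoints partition the latent scale; the
noise models between-respondent disagreement.  Parameters are exposed so
tests can deliberately break monotonicity (e.g. a negative loading).

One root seed drives everything, with per-state streams derived
deterministically from (seed, state id) — adding a state never reshuffles
the draws of existing ones.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import logit_clamped
from .profiles import EQ5DProfile, ResponseRecord, write_responses

__all__ = [
    "SimulationConfig",
    "simulate_responses",
    "simulate_to_file",
    "make_reference_fixture",
    "load_reference",
    "default_states",
    "STUDY1_STATE_IDS",
]

#: the four states evaluated in the first (written-questionnaire) pilot
STUDY1_STATE_IDS = (1, 55, 111, 220)

_REFERENCE_FILENAME = "gbd27_reference.csv"

# Default survey conditions mirror the second (web) pilot: 27 states,
# 393 respondents x 4 states each ~= 58 evaluations per state.
_DEFAULT_N_PER_STATE = 58
_DEFAULT_LOADINGS = (1.0, 1.0, 1.0, 1.0, 1.0)
_DEFAULT_CUTPOINTS = (-4.0, -1.5, 1.5, 4.0)
_DEFAULT_NOISE_SD = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated valuation survey.

    ``states`` is a sequence of ``(health_state_id, true_dw)`` with DWs in
    the open unit interval; ``None`` selects the packaged 27-state
    reference with its GBD 2010 DWs.
    """

    states: tuple[tuple[int, float], ...] | None = None
    n_respondents_per_state: int = _DEFAULT_N_PER_STATE
    dimension_loadings: tuple[float, float, float, float, float] = _DEFAULT_LOADINGS
    cutpoints: tuple[float, float, float, float] = _DEFAULT_CUTPOINTS
    noise_sd: float = _DEFAULT_NOISE_SD
    seed: int = 1

    def resolved_states(self) -> tuple[tuple[int, float], ...]:
        if self.states is None:
            ref = make_reference_fixture()
            return tuple(
                (int(i), float(dw)) for i, dw in zip(ref["id"], ref["dw2010"])
            )
        return tuple((int(i), float(dw)) for i, dw in self.states)

    def validate(self) -> None:
        states = self.resolved_states()
        if not states:
            raise ValueError("states list must be non-empty")
        for sid, dw in states:
            if not 0.0 < dw < 1.0:
                raise ValueError(f"state {sid}: true_dw must be in (0, 1), got {dw}")
        if self.n_respondents_per_state < 1:
            raise ValueError("n_respondents_per_state must be >= 1")
        if len(self.dimension_loadings) != 5 or any(l <= 0 for l in self.dimension_loadings):
            raise ValueError("dimension_loadings must be 5 positive reals")
        cps = tuple(self.cutpoints)
        if len(cps) != 4 or any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("cutpoints must be 4 strictly increasing reals")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")


def simulate_responses(cfg: SimulationConfig) -> list[ResponseRecord]:
    """Draw one full synthetic survey; deterministic given ``cfg.seed``."""
    cfg.validate()
    loadings = np.asarray(cfg.dimension_loadings, dtype=float)
    cutpoints = np.asarray(cfg.cutpoints, dtype=float)
    records: list[ResponseRecord] = []
    for sid, true_dw in cfg.resolved_states():
        rng = np.random.default_rng([int(cfg.seed), int(sid)])
        signal = logit_clamped(true_dw, 1e-3)
        n = cfg.n_respondents_per_state
        latent = loadings[None, :] * signal + rng.normal(0.0, cfg.noise_sd, size=(n, 5))
        levels = 1 + (latent[:, :, None] > cutpoints[None, None, :]).sum(axis=2)
        for i in range(n):
            records.append(
                ResponseRecord(
                    respondent_id=f"s{sid:03d}_r{i:04d}",
                    health_state_id=sid,
                    profile=EQ5DProfile("5L", tuple(int(l) for l in levels[i])),
                )
            )
    return records


def simulate_to_file(cfg: SimulationConfig, path) -> list[ResponseRecord]:
    """Simulate and write the canonical response-table format; returns the records."""
    records = simulate_responses(cfg)
    write_responses(records, path)
    return records


def default_states() -> tuple[tuple[int, float], ...]:
    """(id, GBD 2010 DW) pairs of the packaged 27-state reference."""
    return SimulationConfig().resolved_states()


def make_reference_fixture() -> pd.DataFrame:
    """The packaged 27-health-state reference table.

    Columns: ``id``, ``name``, pilot-study mean/SD utilities
    (``mean_utility_study1``/``sd_utility_study1`` for the four states of
    the written pilot, ``mean_utility_study2``/``sd_utility_study2`` for
    all 27 states of the web pilot) and the GBD ``dw2010``/``dw2013``
    disability weights.
    """
    ref = importlib.resources.files("dwmap.data") / _REFERENCE_FILENAME
    with importlib.resources.as_file(ref) as path:
        return load_reference(path)


def load_reference(path) -> pd.DataFrame:
    """Read a health-state reference table and validate its DW columns."""
    df = pd.read_csv(path)
    required = {"id", "name", "dw2010", "dw2013"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: reference table missing columns {sorted(missing)}")
    for col in ("dw2010", "dw2013"):
        vals = df[col].to_numpy(dtype=float)
        if np.any((vals < 0.0) | (vals > 1.0)) or not np.isfinite(vals).all():
            raise ValueError(f"{path}: {col} values must lie in [0, 1]")
    df["id"] = df["id"].astype(int)
    return df
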