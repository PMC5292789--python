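"""Anchored loess mapping between utilities and disability weights.

Disability weights (DWs) live in [0, 1], so the mapping is fitted on the
logit scale: training DWs are clamped to [eps, 1 - eps], transformed with
``logit``, smoothed against utility by locally weighted polynomial
regression (loess), and predictions return through the inverse logit —
which also guarantees every predicted DW lies strictly inside (0, 1).

Two pseudo-observations anchor the curve's endpoints: utility 0 maps to
DW 1 (a state as bad as death) and utility 1 to DW 0 (full health).  They
enter the training set as ordinary points, one each.

The loess prediction at a query point ``x0`` is fully specified: take the
``k = ceil(span * n)`` nearest training utilities (ties at the boundary
all included), weight them by the tricube kernel

    w_i = (1 - (|u_i - x0| / d_max)^3)^3,

and evaluate the weighted least-squares polynomial of the configured
degree at ``x0``.  This is deliberately a direct implementation of that
contract so it can be checked point-for-point against a naive solver.
"""

from __future__ import annotations

import json
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "logit_clamped",
    "inv_logit",
    "LoessLogitMapper",
    "ExtrapolationWarning",
    "fit_mapping",
    "predict_dw",
    "linear_comparator",
]


class ExtrapolationWarning(UserWarning):
    """A query utility lies outside the training utility range."""


def logit_clamped(p, epsilon: float = 1e-3):
    """``log(q / (1-q))`` with ``q = clip(p, epsilon, 1-epsilon)``.

    ``p`` must lie in [0, 1]; the clamp keeps the transform finite at the
    endpoints (logit of exactly 0 or 1 is undefined).  Scalar in, scalar
    out; arrays pass through elementwise.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    arr = np.asarray(p, dtype=float)
    if np.any(np.isnan(arr)) or np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError(f"probabilities must lie in [0, 1], got {p!r}")
    q = np.clip(arr, epsilon, 1.0 - epsilon)
    out = np.log(q / (1.0 - q))
    return float(out) if np.ndim(p) == 0 else out


def inv_logit(x):
    """Inverse logit ``1 / (1 + exp(-x))``; strictly increasing, range (0, 1)."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if np.ndim(x) == 0 else out


class LoessLogitMapper(BaseEstimator, RegressorMixin):
    """Loess regression of logit(DW) on utility, with endpoint anchors.

    Parameters
    ----------
    span : float in (0, 1], default 0.75
        Fraction of training points in each local neighbourhood.
    degree : {0, 1, 2}, default 2
        Local polynomial degree.
    epsilon : float in (0, 0.5), default 1e-3
        Clamp bound applied to DWs before the logit transform.
    include_anchors : bool, default True
        Append the pseudo-observations (u=0, dw=1) and (u=1, dw=0).
    weights : {"tricube", "uniform"}, default "tricube"
        Kernel over the local neighbourhood.  ``"uniform"`` exists for the
        closed-form limit check (degree 0, span 1 -> global mean of the
        transformed responses).

    Attributes
    ----------
    u_train_, dw_train_ : ndarray
        Training utilities / DWs after anchor augmentation.
    z_train_ : ndarray
        Clamped-logit responses actually smoothed.
    n_points_ : int
        Training size after augmentation.
    u_input_, dw_input_ : ndarray
        The pairs as passed in (pre-anchor), kept for serialization.
    """

    def __init__(
        self,
        span: float = 0.75,
        degree: int = 2,
        epsilon: float = 1e-3,
        include_anchors: bool = True,
        weights: str = "tricube",
    ):
        self.span = span
        self.degree = degree
        self.epsilon = epsilon
        self.include_anchors = include_anchors
        self.weights = weights

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y) -> "LoessLogitMapper":
        """Store the (utility, DW) training pairs; smoothing is lazy.

        ``X`` is the utility vector (1-d, or a single-column 2-d array for
        sklearn pipeline compatibility); ``y`` the DWs in [0, 1].
        Utilities outside [0, 1] (worse-than-death respondents) are legal
        predictors and pass through untransformed.
        """
        self._validate_params()
        u = _as_1d(X, "X")
        dw = _as_1d(y, "y")
        if u.shape != dw.shape:
            raise ValueError(f"X and y lengths differ: {u.size} vs {dw.size}")
        if not np.isfinite(u).all():
            raise ValueError("utilities must be finite")
        if np.any((dw < 0.0) | (dw > 1.0)) or not np.isfinite(dw).all():
            raise ValueError("disability weights must lie in [0, 1]")
        self.u_input_ = u.copy()
        self.dw_input_ = dw.copy()
        if self.include_anchors:
            u = np.append(u, [0.0, 1.0])
            dw = np.append(dw, [1.0, 0.0])
        if u.size < self.degree + 2:
            raise ValueError(
                f"need at least degree + 2 = {self.degree + 2} training points "
                f"(after anchor augmentation), got {u.size}"
            )
        self.u_train_ = u
        self.dw_train_ = dw
        self.z_train_ = logit_clamped(dw, self.epsilon)
        self.n_points_ = int(u.size)
        return self

    def _validate_params(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if self.degree not in (0, 1, 2):
            raise ValueError(f"degree must be 0, 1 or 2, got {self.degree}")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in (0, 0.5), got {self.epsilon}")
        if self.weights not in ("tricube", "uniform"):
            raise ValueError(f"weights must be 'tricube' or 'uniform', got {self.weights!r}")

    # -- prediction -------------------------------------------------------

    def _local_fit(self, x0: float) -> float:
        """Weighted polynomial fit at one query point; returns logit(DW)."""
        u, z = self.u_train_, self.z_train_
        d = np.abs(u - x0)
        k = int(np.ceil(self.span * self.n_points_))
        d_max = np.partition(d, k - 1)[k - 1]
        if d_max == 0.0:
            # all selected neighbours coincide with x0
            w = (d == 0.0).astype(float)
        elif self.weights == "uniform":
            w = (d <= d_max).astype(float)
        else:
            r = d / d_max
            w = np.where(r < 1.0, (1.0 - np.minimum(r, 1.0) ** 3) ** 3, 0.0)
        if np.count_nonzero(w) < self.degree + 1:
            raise ValueError(
                f"span {self.span} too small: local neighbourhood at u={x0} has "
                f"fewer than degree + 1 = {self.degree + 1} weighted points"
            )
        # centred basis: the fitted value at x0 is the constant coefficient
        A = np.vander(u - x0, N=self.degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        return float(beta[0])

    def predict_with_flags(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predicted DWs plus a boolean extrapolation flag per query."""
        if not hasattr(self, "u_train_"):
            raise ValueError("model is not fitted; call fit() first")
        x = _as_1d(X, "X")
        if np.any(np.isnan(x)):
            raise ValueError("query utilities must not be NaN")
        z_hat = np.array([self._local_fit(float(x0)) for x0 in x])
        dw_hat = expit(z_hat)
        lo, hi = self.u_train_.min(), self.u_train_.max()
        extrapolated = (x < lo) | (x > hi)
        if extrapolated.any():
            warnings.warn(
                f"{int(extrapolated.sum())} query point(s) outside the training "
                f"utility range [{lo:.3f}, {hi:.3f}]",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return dw_hat, extrapolated

    def predict(self, X) -> np.ndarray:
        """Predicted DWs, strictly inside (0, 1)."""
        dw_hat, _ = self.predict_with_flags(X)
        return dw_hat

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        """A structured document from which predictions are reproducible bit-for-bit."""
        if not hasattr(self, "u_input_"):
            raise ValueError("model is not fitted; call fit() first")
        return {
            "model": "loess_logit_mapper",
            "span": self.span,
            "degree": self.degree,
            "epsilon": self.epsilon,
            "include_anchors": self.include_anchors,
            "weights": self.weights,
            "u": [float(v) for v in self.u_input_],
            "dw": [float(v) for v in self.dw_input_],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LoessLogitMapper":
        est = cls(
            span=doc["span"],
            degree=doc["degree"],
            epsilon=doc["epsilon"],
            include_anchors=doc["include_anchors"],
            weights=doc.get("weights", "tricube"),
        )
        return est.fit(doc["u"], doc["dw"])

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "LoessLogitMapper":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr.ravel()
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-d (or a single-column 2-d array)")
    return arr


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_mapping(
    pairs: Iterable[tuple[float, float]],
    span: float = 0.75,
    degree: int = 2,
    epsilon: float = 1e-3,
    include_anchors: bool = True,
) -> LoessLogitMapper:
    """Fit the anchored loess mapping from (utility, DW) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no training pairs")
    u, dw = zip(*pairs)
    return LoessLogitMapper(
        span=span, degree=degree, epsilon=epsilon, include_anchors=include_anchors
    ).fit(np.asarray(u), np.asarray(dw))


def predict_dw(model: LoessLogitMapper, u):
    """Predict DW(s) for one utility or a sequence of utilities."""
    scalar = np.ndim(u) == 0
    vals, _ = model.predict_with_flags(np.atleast_1d(np.asarray(u, dtype=float)))
    return float(vals[0]) if scalar else vals


def linear_comparator(pairs: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least squares of logit(DW) on utility: ``(slope, intercept)``.

    The global linear fit drawn alongside the loess curve for comparison.
    ``pairs`` are (utility, logit-transformed DW).
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    u, z = map(np.asarray, zip(*pairs))
    if np.ptp(u) == 0:
        raise ValueError("degenerate regression: all utilities equal")
    res = stats.linregress(u, z)
    return float(res.slope), float(res.intercept)
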