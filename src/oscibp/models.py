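"""Blood-pressure estimation models: fixed-ratio MAA, MLR and linear nu-SVR.

All three models predict the characteristic ratios (SBPR, DBPR); pressures
are then obtained by inverting the predicted ratio on the envelope — SBP is
the cuff pressure on the high-pressure limb where the spline equals
``SBPR * MA``, and DBP its counterpart on the low-pressure limb.  Regressing
ratios rather than pressures follows the variable-characteristic-ratio idea:
the conventional maximum amplitude algorithm fixes both ratios at their
training-population means, whereas MLR (ordinary least squares on the normal
equations) and linear nu-SVR let them vary with envelope features.

The regression layer is written as scikit-learn estimators
(:class:`FixedRatio`, :class:`RatioMLR`, :class:`RatioNuSVR`) so they compose
with sklearn model selection; the module-level functions are thin wrappers
that return a plain :class:`LinearModel` record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import qr
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import NuSVR

from .envelope import GRID_STEP, OWE
from .features import RatioPair

logger = logging.getLogger(__name__)

#: default nu-SVR hyperparameters, reading the printed settings as base-2
#: exponents (nu itself must lie in (0, 1])
DEFAULT_SVR_C = 2.0**14.49
DEFAULT_SVR_NU = 2.0**-1.89

#: predicted ratios are clipped into this interval before envelope inversion
RATIO_CLIP = (0.05, 1.0)


class RankDeficientError(ValueError):
    """Design matrix is rank-deficient; names the collinear columns."""

    def __init__(self, columns: list[int], names: Optional[Sequence[str]] = None):
        self.columns = columns
        label = [names[c] for c in columns] if names else columns
        super().__init__(f"design matrix is rank-deficient in columns {label}")


class EnvelopeCrossingError(ValueError):
    """The required ratio level never crosses the envelope on one limb."""

    def __init__(self, side: str, level: float):
        self.side = side
        super().__init__(
            f"envelope truncated: no {side}-pressure crossing at amplitude {level:.3f} mmHg"
        )


@dataclass(frozen=True)
class LinearModel:
    """A fitted linear ratio model ``y = intercept + X @ weights``."""

    kind: str
    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    hyperparams: dict = field(default_factory=dict)
    train_residual_sd: float = float("nan")


@dataclass(frozen=True)
class BPEstimate:
    """One recording's estimated pressures (mmHg)."""

    sbp: float
    dbp: float
    map: float
    ratios_used: RatioPair
    method: str = ""

    def __post_init__(self) -> None:
        if not (self.dbp <= self.map <= self.sbp):
            raise ValueError("estimate must satisfy dbp <= map <= sbp")


# ---------------------------------------------------------------------------
# scikit-learn estimators


class FixedRatio(RegressorMixin, BaseEstimator):
    """Conventional MAA regressor: predicts the training-mean ratio for all."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if y.size < 1:
            raise ValueError("need at least one training ratio")
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 0
        self.ratio_ = float(np.mean(y))
        self.coef_ = np.zeros(self.n_features_in_)
        self.intercept_ = self.ratio_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.full(X.shape[0], self.ratio_)


class RatioMLR(RegressorMixin, BaseEstimator):
    """Ordinary least squares on the normal equations ``(X'X)^-1 X'y``.

    Solved with a numerically stable least-squares routine; rank deficiency
    raises :class:`RankDeficientError` naming the collinear columns.
    """

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per target")
        A = np.column_stack([np.ones(X.shape[0]), X])
        if A.shape[0] < A.shape[1]:
            raise ValueError("need at least as many measurements as coefficients")
        _check_rank(A, feature_names)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_features_in_ = X.shape[1]
        resid = y - A @ beta
        dof = max(1, A.shape[0] - A.shape[1])
        self.residual_sd_ = float(np.sqrt(resid @ resid / dof))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef_.size:
            raise ValueError("feature dimension mismatch")
        return self.intercept_ + X @ self.coef_


class RatioNuSVR(RegressorMixin, BaseEstimator):
    """Linear nu-SVR on internally standardized features.

    ``nu`` bounds the support-vector fraction from below and the
    margin-violation fraction from above; ``C`` trades flatness against
    tolerated deviations.  Features are standardized to zero mean and unit
    variance before the convex program is solved (areas in mmHg*s would
    otherwise dominate dimensionless ratios); the returned primal ``(w, b)``
    is expressed back in the original feature space.
    """

    def __init__(self, C: float = DEFAULT_SVR_C, nu: float = DEFAULT_SVR_NU):
        self.C = C
        self.nu = nu

    def fit(self, X, y):
        if not 0.0 < self.nu <= 1.0:
            raise ValueError(f"nu must lie in (0, 1], got {self.nu}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per target")
        if X.shape[0] < 2:
            raise ValueError("need at least two training points")
        self.scale_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_sd_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.scale_mean_) / self.scale_sd_
        svr = NuSVR(kernel="linear", C=self.C, nu=self.nu, tol=1e-4, max_iter=2_000_000)
        with warnings.catch_warnings():
            # the iteration cap is deliberate: at very large C the dual
            # converges slowly and the capped solution is already stable
            warnings.simplefilter("ignore", ConvergenceWarning)
            svr.fit(Xs, y)
        w_std = svr.coef_.ravel()
        b_std = float(svr.intercept_[0])
        self.coef_ = w_std / self.scale_sd_
        self.intercept_ = b_std - float(np.sum(w_std * self.scale_mean_ / self.scale_sd_))
        self.sv_fraction_ = svr.support_.size / X.shape[0]
        self.n_features_in_ = X.shape[1]
        resid = y - self.predict(X)
        self.residual_sd_ = float(np.std(resid, ddof=1)) if y.size > 1 else float("nan")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef_.size:
            raise ValueError("feature dimension mismatch")
        return self.intercept_ + X @ self.coef_


ESTIMATOR_KINDS = ("maa", "mlr", "nusvr")


def make_estimator(kind: str, **kwargs):
    """Instantiate a ratio estimator by kind ('maa', 'mlr' or 'nusvr')."""
    if kind == "maa":
        return FixedRatio()
    if kind == "mlr":
        return RatioMLR()
    if kind == "nusvr":
        return RatioNuSVR(**kwargs)
    raise ValueError(f"unknown estimator kind {kind!r}")


# ---------------------------------------------------------------------------
# functional surface


def _check_rank(A: np.ndarray, names: Optional[Sequence[str]] = None) -> None:
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    bad = np.flatnonzero(diag <= tol)
    if bad.size:
        cols = sorted(int(piv[i]) for i in bad)
        raise RankDeficientError(cols, names)


def maa_fixed_ratios(training: Sequence[RatioPair]) -> RatioPair:
    """Component-wise mean of training characteristic ratios (conventional MAA)."""
    if len(training) == 0:
        raise ValueError("need at least one training ratio pair")
    return RatioPair(
        sbpr=float(np.mean([r.sbpr for r in training])),
        dbpr=float(np.mean([r.dbpr for r in training])),
    )


def fit_mlr(X: np.ndarray, y: np.ndarray, feature_names: tuple[str, ...] = ()) -> LinearModel:
    """Least-squares fit; ``X`` carries a leading ones column for the intercept."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or not np.allclose(X[:, 0], 1.0):
        raise ValueError("X must be 2-D with a leading ones column")
    est = RatioMLR().fit(X[:, 1:], y, feature_names=("intercept",) + tuple(feature_names))
    return LinearModel(
        kind="mlr",
        feature_names=tuple(feature_names) or tuple(f"x{i}" for i in range(X.shape[1] - 1)),
        weights=est.coef_,
        intercept=est.intercept_,
        train_residual_sd=est.residual_sd_,
    )


def fit_nusvr(
    X: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_SVR_C,
    nu: float = DEFAULT_SVR_NU,
    feature_names: tuple[str, ...] = (),
) -> LinearModel:
    """Fit the linear nu-SVR convex program; returns the primal ``(w, b)``."""
    est = RatioNuSVR(C=C, nu=nu).fit(X, y)
    return LinearModel(
        kind="nusvr",
        feature_names=tuple(feature_names) or tuple(f"x{i}" for i in range(np.asarray(X).shape[1])),
        weights=est.coef_,
        intercept=est.intercept_,
        hyperparams={
            "C": C,
            "nu": nu,
            "sv_fraction": est.sv_fraction_,
            "scale_mean": est.scale_mean_,
            "scale_sd": est.scale_sd_,
        },
        train_residual_sd=est.residual_sd_,
    )


def predict_linear(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Evaluate ``intercept + X @ weights`` row-wise."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.weights.size:
        raise ValueError(
            f"feature dimension mismatch: model has {model.weights.size}, X has "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    return model.intercept + X @ model.weights


def clip_ratio(r: float, bounds: tuple[float, float] = RATIO_CLIP) -> float:
    """Clip a predicted ratio into ``(0.05, 1]``; clipping events are logged."""
    lo, hi = bounds
    if r < lo or r > hi:
        logger.info("predicted characteristic ratio %.4f clipped to [%g, %g]", r, lo, hi)
        return float(np.clip(r, lo, hi))
    return float(r)


def _cross_on_limb(owe: OWE, level: float, side: str) -> float:
    """Cuff pressure nearest MAP where the spline crosses ``level``."""
    f = lambda c: float(owe.spline(c)) - level
    if side == "high":
        grid = np.arange(owe.map, owe.cp_max + GRID_STEP / 2, GRID_STEP)
        grid[-1] = owe.cp_max
    else:
        grid = np.arange(owe.map, owe.cp_min - GRID_STEP / 2, -GRID_STEP)
        grid[-1] = owe.cp_min
    vals = owe.spline(grid) - level
    if vals[0] < 0:  # MAP itself already below the level (ratio ~ 1)
        return float(owe.map)
    below = np.flatnonzero(vals <= 0)
    if below.size == 0:
        raise EnvelopeCrossingError(side, level)
    i = int(below[0])
    if vals[i] == 0:
        return float(grid[i])
    a, b = sorted((grid[i - 1], grid[i]))
    return float(brentq(f, a, b, xtol=1e-3))


def estimate_bp_from_ratios(
    owe: OWE, ratios: RatioPair, method: str = ""
) -> BPEstimate:
    """Invert predicted characteristic ratios on the envelope.

    SBP is the crossing of ``sbpr * MA`` on the high-pressure limb nearest
    MAP, DBP the crossing of ``dbpr * MA`` on the low-pressure limb; both are
    refined by bisection to 0.01 mmHg.  An envelope that never descends to
    the required level on a limb raises :class:`EnvelopeCrossingError`
    identifying the failing side.
    """
    if owe.spline is None:
        raise ValueError("envelope must be fitted")
    sbp = owe.map if ratios.sbpr >= 1.0 else _cross_on_limb(owe, ratios.sbpr * owe.ma, "high")
    dbp = owe.map if ratios.dbpr >= 1.0 else _cross_on_limb(owe, ratios.dbpr * owe.ma, "low")
    return BPEstimate(sbp=sbp, dbp=dbp, map=float(owe.map), ratios_used=ratios, method=method)
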