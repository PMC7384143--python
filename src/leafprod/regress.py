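"""Candidate model families linking climate, leaf size and productivity.

Five families are supported: ``linear`` (y = a + b*x), ``sqrt_linear``
(sqrt(y) = a + b*x), ``exponential`` (y = a*b**x), ``power`` (y = a*x**b)
and ``logistic`` (y = K / (1 + exp(alpha - r*x)), defined for responses
below the asymptote K).  Linear families are fitted by ordinary least
squares; the nonlinear families by least squares seeded from a
log-linearised warm start, so that noiseless data are recovered to
machine precision and the fitted sum of squares never exceeds the warm
start's.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LogisticParams",
    "ModelFit",
    "FAMILIES",
    "fit_model",
    "predict_model",
    "r_squared",
    "DegenerateInputError",
    "FitConvergenceError",
]

FAMILIES = ("linear", "sqrt_linear", "exponential", "power", "logistic")

#: lower bound on K as a multiple of max(y); keeps ln(K/y - 1) defined
K_BOUND_MULTIPLIER = 1.0 + 1e-6
#: upper bound on K as a multiple of max(y); a runaway asymptote means the
#: logistic is indistinguishable from its rising limb on the observed range
K_UPPER_MULTIPLIER = 50.0


class DegenerateInputError(ValueError):
    """Raised when the response is constant or otherwise unfittable."""


class FitConvergenceError(RuntimeError):
    """Raised when the nonlinear optimiser fails; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic curve y = K / (1 + exp(alpha - r*x)).

    The same triple parameterises the inverse-logistic transfer function
    y = (1/r) * (alpha - ln(K/x - 1)); there K is an upper bound on the
    *predictor* (leaf size) rather than the response.

    Attributes
    ----------
    K : float
        Upper asymptote, in units of the logistic response.
    alpha : float
        Dimensionless location parameter.
    r : float
        Rate, per unit of the predictor.
    """

    K: float
    alpha: float
    r: float

    def __post_init__(self):
        if not (self.K > 0):
            raise ValueError(f"K must be > 0, got {self.K}")
        if not (self.r > 0):
            raise ValueError(f"r must be > 0, got {self.r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.K, self.alpha, self.r)


@dataclass
class ModelFit:
    """A fitted trait-climate or trait-productivity model.

    ``r2`` is computed on the raw response scale except for
    ``sqrt_linear``, where it refers to the sqrt scale (``transform``
    records which).
    """

    family: str
    params: dict[str, float]
    r2: float
    n: int
    transform: str = "none"
    residual_se: float = float("nan")
    aic: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=float)

    @classmethod
    def from_json(cls, s: str) -> "ModelFit":
        return cls(**json.loads(s))


def r_squared(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSE/SST, SST about mean(y).

    May be negative for predictions not nested in the data's mean
    (e.g. cross-region application of a fixed model).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise DegenerateInputError("var(y) = 0: R^2 undefined")
    sse = np.sum((y - y_hat) ** 2)
    return 1.0 - sse / sst


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares intercept and slope of y on x."""
    X = np.column_stack([np.ones_like(x), x])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(a), float(b)


def _logistic(x, K, alpha, r):
    return K / (1.0 + np.exp(alpha - r * x))


def _logistic_warm_start(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Seed (K, alpha, r) by log-linearising with K0 = 1.05*max(y)."""
    K0 = 1.05 * float(np.max(y))
    z = np.log(K0 / y - 1.0)
    a, b = _ols(x, z)  # z = alpha - r*x
    r0 = -b
    if r0 <= 0:
        r0 = 1e-6
    return K0, a, r0


def _nls(residual_fn, p0, bounds, max_nfev=500 * 10):
    sol = least_squares(
        residual_fn, p0, bounds=bounds, method="trf", x_scale="jac",
        ftol=1e-12, xtol=1e-12, gtol=None, max_nfev=max_nfev,
    )
    return sol


def fit_model(x, y, family: str, seed: int = 0) -> ModelFit:
    """Fit one of the candidate families by (nonlinear) least squares.

    Nonlinear families use a log-linearised warm start; the logistic
    family additionally runs three jittered warm starts (seeded) and
    keeps the best sum of squares.

    Raises
    ------
    DegenerateInputError
        If y is constant, or positivity requirements are violated.
    FitConvergenceError
        If the optimiser reports failure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    n = x.size
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant response")
    if family in ("linear", "sqrt_linear"):
        if n < 3:
            raise ValueError("need n >= 3 for linear families")
    else:
        if n < 5:
            raise ValueError("need n >= 5 for nonlinear families")
    if family in ("sqrt_linear", "exponential", "power", "logistic") and np.any(y <= 0):
        raise DegenerateInputError(f"family {family!r} requires y > 0")
    if family == "power" and np.any(x <= 0):
        raise DegenerateInputError("power family requires x > 0")

    if family == "linear":
        a, b = _ols(x, y)
        y_hat = a + b * x
        params = {"a": a, "b": b}
        r2 = r_squared(y, y_hat)
        resid = y - y_hat
    elif family == "sqrt_linear":
        sy = np.sqrt(y)
        a, b = _ols(x, sy)
        sy_hat = a + b * x
        params = {"a": a, "b": b}
        r2 = r_squared(sy, sy_hat)  # sqrt scale, flagged via transform
        resid = sy - sy_hat
    elif family == "exponential":
        # y = a * b**x ; warm start ln y = ln a + x ln b
        la, lb = _ols(x, np.log(y))
        p0 = [math.exp(la), math.exp(lb)]
        sol = _nls(lambda p: p[0] * np.power(p[1], x) - y, p0,
                   ([0, 0], [np.inf, np.inf]))
        _check_sol(sol, "exponential")
        a, b = sol.x
        params = {"a": float(a), "b": float(b)}
        y_hat = a * np.power(b, x)
        r2 = r_squared(y, y_hat)
        resid = y - y_hat
    elif family == "power":
        la, b0 = _ols(np.log(x), np.log(y))
        p0 = [math.exp(la), b0]
        sol = _nls(lambda p: p[0] * np.power(x, p[1]) - y, p0,
                   ([0, -np.inf], [np.inf, np.inf]))
        _check_sol(sol, "power")
        a, b = sol.x
        params = {"a": float(a), "b": float(b)}
        y_hat = a * np.power(x, b)
        r2 = r_squared(y, y_hat)
        resid = y - y_hat
    else:  # logistic
        params, y_hat, diag = _fit_logistic(x, y, seed)
        r2 = r_squared(y, y_hat)
        resid = y - y_hat

    dof = max(n - len(params), 1)
    sse = float(np.sum(resid**2))
    fit = ModelFit(
        family=family,
        params=params,
        r2=float(r2),
        n=int(n),
        transform="sqrt" if family == "sqrt_linear" else "none",
        residual_se=math.sqrt(sse / dof),
        aic=n * math.log(sse / n) + 2 * (len(params) + 1) if sse > 0 else -math.inf,
    )
    if family == "logistic":
        fit.diagnostics = diag
    return fit


def _check_sol(sol, family):
    if not sol.success:
        raise FitConvergenceError(
            f"{family} fit did not converge: {sol.message}",
            {"status": sol.status, "nfev": sol.nfev},
        )


def _fit_logistic(x, y, seed):
    K0, a0, r0 = _logistic_warm_start(x, y)
    k_lo = K_BOUND_MULTIPLIER * float(np.max(y))
    k_hi = K_UPPER_MULTIPLIER * float(np.max(y))
    rng = np.random.default_rng(seed)
    starts = [(max(K0, k_lo), a0, r0)]
    for _ in range(2):
        jit = rng.uniform(0.8, 1.3, size=3)
        starts.append((max(K0 * jit[0], k_lo), a0 * jit[1], r0 * jit[2]))

    def resid(p):
        return _logistic(x, *p) - y

    warm_sse = float(np.sum(resid(starts[0]) ** 2))
    best = None
    for p0 in starts:
        sol = _nls(resid, p0, ([k_lo, -np.inf, 1e-12], [k_hi, np.inf, np.inf]))
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitConvergenceError("logistic fit did not converge from any start",
                                  {"starts": starts})
    K, alpha, r = best.x
    sse = 2 * best.cost
    # monotone improvement over the warm start is guaranteed when the warm
    # start is feasible; record both for audit
    diag = {"warm_start_sse": warm_sse, "sse": float(sse), "n_starts": len(starts)}
    params = {"K": float(K), "alpha": float(alpha), "r": float(r)}
    return params, _logistic(x, K, alpha, r), diag


def predict_model(fit: ModelFit, x) -> np.ndarray:
    """Evaluate a fitted family at new predictor values.

    For ``sqrt_linear`` a negative predicted sqrt-response is clipped to
    zero before squaring (the fitted line can cross zero outside the
    training range).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    p = fit.params
    if fit.family == "linear":
        return p["a"] + p["b"] * x
    if fit.family == "sqrt_linear":
        s = np.clip(p["a"] + p["b"] * x, 0.0, None)
        return s**2
    if fit.family == "exponential":
        return p["a"] * np.power(p["b"], x)
    if fit.family == "power":
        return p["a"] * np.power(x, p["b"])
    if fit.family == "logistic":
        return _logistic(x, p["K"], p["alpha"], p["r"])
    raise ValueError(f"unknown family {fit.family!r}")
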