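"""Leaf size -> productivity transfer functions and their validation.

The central form is the inverse logistic

    y = (1/r) * (alpha - ln(K/x - 1)),   0 < x < K,

mapping community mean leaf size x (cm or cm^2) to annual productivity y
(gC m^-2 yr^-1).  It is the functional inverse of the forward logistic
x = K / (1 + exp(alpha - r*y)) describing how leaf size saturates with
productivity-favourable conditions; K is therefore an upper bound on the
*trait*, and predictions are only defined for traits below K.  Linear and
sqrt-linear forms are provided for comparison.

Accuracy of a transfer function is summarised by the standard error of
estimate SE = sqrt(sum((y_est - y_real)^2) / (n - 1)) and its percentage
of the observed productivity range (SE%), plus R^2 and the slope and
intercept of the observed-on-predicted regression for comparison with
the 1:1 line.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .regress import (
    LogisticParams,
    DegenerateInputError,
    FitConvergenceError,
    K_BOUND_MULTIPLIER,
    _ols,
    r_squared,
)

__all__ = [
    "TransferModel",
    "TransferEvaluation",
    "inverse_logistic",
    "fit_transfer",
    "predict_transfer",
    "evaluate_transfer",
    "cross_region_validate",
]

TRANSFER_FORMS = ("inv_logistic", "linear", "sqrt_linear")


def inverse_logistic(x, K: float, alpha: float, r: float) -> np.ndarray:
    """Evaluate y = (1/r)(alpha - ln(K/x - 1)); NaN outside 0 < x < K."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = (x > 0) & (x < K)
    out[ok] = (alpha - np.log(K / x[ok] - 1.0)) / r
    return out


@dataclass
class TransferModel:
    """A fitted transfer function from a trait surface to productivity."""

    trait: str                      # length | width | lw_product
    productivity: str               # GPP | NPP
    form: str                       # inv_logistic | linear | sqrt_linear
    params: dict[str, float]
    n: int                          # cells used (after x < K exclusion)
    r2: float
    region: str = ""
    n_excluded: int = 0             # cells dropped by the x < K domain rule
    se: float = float("nan")
    se_pct: float = float("nan")

    @property
    def logistic_params(self) -> LogisticParams:
        if self.form != "inv_logistic":
            raise ValueError("logistic_params only defined for inv_logistic form")
        return LogisticParams(self.params["K"], self.params["alpha"], self.params["r"])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    @classmethod
    def from_json(cls, s: str) -> "TransferModel":
        return cls(**json.loads(s))


@dataclass
class TransferEvaluation:
    """Accuracy of predicted vs. observed productivity.

    ``slope``/``intercept`` come from regressing observed on predicted,
    so a perfect transfer sits on the 1:1 line (slope 1, intercept 0).
    """

    se: float
    se_pct: float
    r2: float
    n: int
    slope: float
    intercept: float
    flags: dict = field(default_factory=dict)


def fit_transfer(x, y, form: str = "inv_logistic", *, trait: str = "length",
                 productivity: str = "GPP", region: str = "",
                 max_rounds: int = 5, seed: int = 0) -> TransferModel:
    """Least-squares fit of productivity y on trait x under ``form``.

    For ``inv_logistic`` the asymptote K is bounded below by
    max(x)*(1+1e-6); non-positive traits are excluded up front, and cells
    whose trait ends up at or above the fitted K are excluded and the
    model refitted, up to ``max_rounds`` rounds (the count of exclusions
    is recorded on the model).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if form not in TRANSFER_FORMS:
        raise ValueError(f"unknown form {form!r}")
    n_excluded = 0
    if form == "inv_logistic":
        pos = x > 0
        n_excluded += int((~pos).sum())
        x, y = x[pos], y[pos]
    if x.size < 10:
        raise ValueError(f"fewer than 10 usable cells (n={x.size})")

    if form == "linear":
        a, b = _ols(x, y)
        y_hat = a + b * x
        return TransferModel(trait, productivity, form, {"a": a, "b": b},
                             int(x.size), float(r_squared(y, y_hat)), region,
                             n_excluded)
    if form == "sqrt_linear":
        if np.any(y < 0):
            raise DegenerateInputError("sqrt_linear requires y >= 0")
        sy = np.sqrt(y)
        a, b = _ols(x, sy)
        y_hat = np.clip(a + b * x, 0, None) ** 2
        return TransferModel(trait, productivity, form, {"a": a, "b": b},
                             int(x.size), float(r_squared(y, y_hat)), region,
                             n_excluded)

    # inv_logistic with iterative domain exclusion
    params = None
    for _ in range(max_rounds):
        params = _fit_inv_logistic(x, y, seed)
        inside = x < params["K"]
        if inside.all():
            break
        n_excluded += int((~inside).sum())
        x, y = x[inside], y[inside]
        if x.size < 10:
            raise ValueError("domain exclusion left fewer than 10 cells")
    y_hat = inverse_logistic(x, **params)
    return TransferModel(trait, productivity, form, params, int(x.size),
                         float(r_squared(y, y_hat)), region, n_excluded)


def _fit_inv_logistic(x, y, seed):
    from .regress import K_UPPER_MULTIPLIER
    k_lo = K_BOUND_MULTIPLIER * float(np.max(x))
    k_hi = K_UPPER_MULTIPLIER * float(np.max(x))
    # warm start: ln(K0/x - 1) = alpha - r*y, K0 slightly above max(x)
    K0 = 1.05 * float(np.max(x))
    z = np.log(K0 / x - 1.0)
    a0, b0 = _ols(y, z)
    r0 = -b0 if b0 < 0 else 1e-4

    def resid(p):
        K, alpha, r = p
        return (alpha - np.log(K / x - 1.0)) / r - y

    rng = np.random.default_rng(seed)
    starts = [(max(K0, k_lo), a0, r0)]
    for _ in range(2):
        j = rng.uniform(0.85, 1.25, 3)
        starts.append((max(K0 * j[0], k_lo), a0 * j[1], r0 * j[2]))
    best = None
    for p0 in starts:
        sol = least_squares(resid, p0,
                            bounds=([k_lo, -np.inf, 1e-12], [k_hi, np.inf, np.inf]),
                            method="trf", x_scale="jac", ftol=1e-12, xtol=1e-12,
                            max_nfev=5000)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitConvergenceError("inverse-logistic fit did not converge")
    K, alpha, r = best.x
    return {"K": float(K), "alpha": float(alpha), "r": float(r)}


def predict_transfer(model: TransferModel, x) -> np.ndarray:
    """Apply a transfer model; out-of-domain traits yield NaN (warned)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    p = model.params
    if model.form == "inv_logistic":
        y = inverse_logistic(x, p["K"], p["alpha"], p["r"])
        n_bad = int(np.isnan(y).sum() - np.isnan(x).sum())
        if n_bad > 0:
            warnings.warn(
                f"{n_bad} trait values outside (0, K={p['K']:.3f}); "
                "predictions set to NaN", stacklevel=2)
        return y
    if model.form == "linear":
        return p["a"] + p["b"] * x
    if model.form == "sqrt_linear":
        return np.clip(p["a"] + p["b"] * x, 0, None) ** 2
    raise ValueError(f"unknown form {model.form!r}")


def evaluate_transfer(y_est, y_real) -> TransferEvaluation:
    """SE, SE%, R^2 and the observed-on-predicted line, NaN-pairs dropped."""
    y_est = np.asarray(y_est, dtype=float)
    y_real = np.asarray(y_real, dtype=float)
    if y_est.shape != y_real.shape:
        raise ValueError("y_est and y_real must have equal length")
    ok = np.isfinite(y_est) & np.isfinite(y_real)
    flags = {"n_dropped": int((~ok).sum())}
    y_est, y_real = y_est[ok], y_real[ok]
    n = y_est.size
    if n < 2:
        raise ValueError("need at least 2 finite pairs")
    se = float(np.sqrt(np.sum((y_est - y_real) ** 2) / (n - 1)))
    rng = float(np.ptp(y_real))
    if rng > 0:
        se_pct = 100.0 * se / rng
    else:
        se_pct = float("nan")
        flags["zero_observed_range"] = True
    r2 = float(r_squared(y_real, y_est))
    b, a = (float("nan"),) * 2
    if np.ptp(y_est) > 0:
        a, b = _ols(y_est, y_real)
    return TransferEvaluation(se=se, se_pct=se_pct, r2=r2, n=int(n),
                              slope=float(b), intercept=float(a), flags=flags)


def cross_region_validate(model: TransferModel, cells: pd.DataFrame,
                          trait_col: str, prod_col: str
                          ) -> tuple[TransferEvaluation, pd.DataFrame]:
    """Predict one region's productivity with another region's model.

    Returns the evaluation against the region's observed productivity and
    the per-cell paired table (trait, observed, predicted) for plotting
    against the 1:1 line.
    """
    x = cells[trait_col].to_numpy(dtype=float)
    y = cells[prod_col].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y_hat = predict_transfer(model, x)
    if not np.isfinite(y_hat).any():
        raise ValueError("no cells inside the transfer function's domain")
    paired = pd.DataFrame({
        "cell_id": cells.index if cells.index.name == "cell_id"
        else cells.get("cell_id", pd.RangeIndex(len(cells))),
        "trait": x, "observed": y, "predicted": y_hat,
    })
    return evaluate_transfer(y_hat, y), paired
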