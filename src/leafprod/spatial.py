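"""Spatially corrected significance tests and variance partitioning.

Gridded trait and climate surfaces are strongly spatially autocorrelated,
so classical correlation tests overstate significance.  The modified
t-test corrects the degrees of freedom through an effective sample size

    M_hat = 1 + tr(B S_A) * tr(B S_B) / tr(B S_A B S_B),

where B = I - 11'/n is the centering matrix and S_A, S_B are spatial
correlation matrices estimated from distance-class correlograms of the
two surfaces.  With S_A = S_B = I the classical test (M_hat = n) is
recovered exactly.

Attribution of explained variance uses hierarchical partitioning
(independent/joint effects averaged over all predictor subsets) and, for
three predictors, the commonality (Venn) decomposition whose seven
components sum exactly to the full-model R^2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .regress import DegenerateInputError

__all__ = [
    "SpatialCovariance",
    "ModifiedTTestResult",
    "PartitionResult",
    "VennPartition3",
    "estimate_spatial_covariance",
    "modified_t_test",
    "hierarchical_partition",
    "venn_partition3",
    "soil_pca",
]


@dataclass
class SpatialCovariance:
    """Correlogram-estimated spatial correlation matrices for two surfaces."""

    sigma_a: np.ndarray
    sigma_b: np.ndarray
    class_breaks: np.ndarray
    autocorr_a: np.ndarray      # per-class Moran-type estimates
    autocorr_b: np.ndarray
    merged_classes: int = 0


@dataclass
class ModifiedTTestResult:
    r: float
    m_hat: float
    t: float
    df: float
    p: float
    n: int
    clamped: bool = False
    flags: dict = field(default_factory=dict)


def _sturges_classes(n_pairs: int) -> int:
    return max(int(math.ceil(math.log2(n_pairs))) + 1, 2)


def _class_autocorr(z: np.ndarray, member: list[np.ndarray]) -> np.ndarray:
    """Moran-type autocorrelation per distance class for centred values."""
    denom = float(np.mean(z * z))
    out = np.empty(len(member))
    for k, idx in enumerate(member):
        i, j = idx
        out[k] = float(np.mean(z[i] * z[j])) / denom
    return out


def estimate_spatial_covariance(values_a, values_b, coords, n_classes: int | None = None
                                ) -> SpatialCovariance:
    """Estimate spatial correlation matrices from distance-class correlograms.

    Pairwise distances are binned into ``n_classes`` equal-width classes
    (default: Sturges' rule on the pair count); per class, a Moran-type
    autocorrelation is estimated for each surface and written into every
    matrix entry of that class.  Negative estimates are retained.  Empty
    classes are merged into their lower neighbour.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = a.size
    if n < 10:
        raise ValueError("need n >= 10")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant surface: zero variance")
    d = pdist(coords)
    if np.any(d == 0):
        raise ValueError("coordinates must be distinct")
    n_pairs = d.size
    if n_classes is None:
        n_classes = _sturges_classes(n_pairs)
    breaks = np.linspace(0.0, d.max(), n_classes + 1)
    breaks[-1] = np.nextafter(breaks[-1], np.inf)
    cls = np.digitize(d, breaks) - 1  # 0-based class per pair

    iu = np.triu_indices(n, k=1)
    member, kept_breaks, merged = [], [breaks[0]], 0
    pending = None
    for k in range(n_classes):
        sel = cls == k
        idx = (iu[0][sel], iu[1][sel])
        if pending is not None:
            idx = (np.concatenate([pending[0], idx[0]]),
                   np.concatenate([pending[1], idx[1]]))
            pending = None
        if idx[0].size == 0:
            pending = idx
            merged += 1
            continue
        member.append(idx)
        kept_breaks.append(breaks[k + 1])
    if pending is not None and pending[0].size and member:
        member[-1] = (np.concatenate([member[-1][0], pending[0]]),
                      np.concatenate([member[-1][1], pending[1]]))

    za, zb = a - a.mean(), b - b.mean()
    rho_a = _class_autocorr(za, member)
    rho_b = _class_autocorr(zb, member)

    def build(rho):
        S = np.eye(n)
        for k, idx in enumerate(member):
            S[idx] = rho[k]
            S[idx[1], idx[0]] = rho[k]
        return S

    return SpatialCovariance(build(rho_a), build(rho_b),
                             np.asarray(kept_breaks), rho_a, rho_b, merged)


def modified_t_test(values_a, values_b, coords=None, *,
                    covariance: SpatialCovariance | None = None,
                    n_classes: int | None = None) -> ModifiedTTestResult:
    """Correlation test with autocorrelation-corrected degrees of freedom.

    Either grid coordinates (from which the spatial covariance is
    estimated) or a precomputed :class:`SpatialCovariance` must be given.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n = a.size
    if covariance is None:
        if coords is None:
            raise ValueError("need coords or a precomputed covariance")
        covariance = estimate_spatial_covariance(a, b, coords, n_classes)
    Sa, Sb = covariance.sigma_a, covariance.sigma_b
    B = np.eye(n) - np.full((n, n), 1.0 / n)
    BSa = B @ Sa
    BSb = B @ Sb
    denom = np.trace(BSa @ BSb)
    m_hat = 1.0 + np.trace(BSa) * np.trace(BSb) / denom
    clamped = False
    if not (2.0 < m_hat <= n):
        m_hat = min(max(m_hat, np.nextafter(2.0, np.inf)), float(n))
        clamped = True
    r = float(np.corrcoef(a, b)[0, 1])
    df = m_hat - 2.0
    flags = {}
    if df <= 0 or abs(r) >= 1.0:
        t = math.inf if abs(r) >= 1 else 0.0
        p = 1.0 if df <= 0 else 0.0
        flags["degenerate"] = True
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return ModifiedTTestResult(r=r, m_hat=float(m_hat), t=float(t),
                               df=float(df), p=float(p), n=n,
                               clamped=clamped, flags=flags)


# ---------------------------------------------------------------------------
# variance partitioning


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...],
               allow_singular: bool = False) -> float:
    """R^2 of the OLS fit of y on the given predictor columns + intercept.

    With ``allow_singular`` a rank-deficient design is fitted by least
    norm (R^2 of the projection is still well defined); otherwise it is
    an error naming the offending subset.
    """
    M = np.column_stack([np.ones(len(y))] + [X[:, c] for c in cols])
    coef, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1] and not allow_singular:
        raise np.linalg.LinAlgError(f"singular design for subset {cols}")
    resid = y - M @ coef
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise DegenerateInputError("constant response")
    return float(1.0 - np.sum(resid**2) / sst)


@dataclass
class PartitionResult:
    """Hierarchical partitioning of a model's R^2 over its predictors."""

    names: list[str]
    independent: np.ndarray         # I_i, R^2 units
    joint: np.ndarray               # J_i = R^2({i}) - I_i
    full_r2: float
    subset_r2: dict[tuple[int, ...], float]

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({"predictor": self.names,
                             "independent": self.independent,
                             "joint": self.joint})


def hierarchical_partition(y, X, names: list[str] | None = None) -> PartitionResult:
    """Independent and joint effects by averaging R^2 increments.

    All 2^k - 1 subset models are fitted; the independent effect of
    predictor i averages, over hierarchy levels, the mean R^2 gain from
    adding i to subsets of that size not containing i.  Their sum equals
    the full-model R^2 (an exact identity for this scheme).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if k < 1 or k > 8:
        raise ValueError("k must be between 1 and 8 (2^k subset fits)")
    if n <= k + 2:
        raise ValueError("need n > k + 2")
    names = names or [f"x{i+1}" for i in range(k)]

    ledger: dict[tuple[int, ...], float] = {}
    for size in range(1, k + 1):
        for cols in itertools.combinations(range(k), size):
            ledger[cols] = _subset_r2(y, X, cols)
    ledger[()] = 0.0

    I = np.zeros(k)
    for i in range(k):
        others = [j for j in range(k) if j != i]
        level_means = []
        for size in range(0, k):
            gains = [
                ledger[tuple(sorted(S + (i,)))] - ledger[S]
                for S in itertools.combinations(others, size)
            ]
            level_means.append(np.mean(gains))
        I[i] = np.mean(level_means)
    marg = np.array([ledger[(i,)] for i in range(k)])
    full = ledger[tuple(range(k))]
    del ledger[()]
    return PartitionResult(names, I, marg - I, full, ledger)


@dataclass
class VennPartition3:
    """Commonality components of a three-predictor R^2 (may be negative)."""

    unique: dict[str, float]
    pairwise: dict[str, float]
    triple: float
    full_r2: float

    def components(self) -> np.ndarray:
        return np.array(list(self.unique.values())
                        + list(self.pairwise.values()) + [self.triple])


def venn_partition3(y, A, B, C, names: tuple[str, str, str] = ("A", "B", "C")
                    ) -> VennPartition3:
    """Commonality (Venn) decomposition for three predictors.

    Solves the linear system expressing each subset R^2 as the sum of the
    commonality components its predictors touch; components can be
    negative under suppression and are reported as-is.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([A, B, C]).astype(float)
    subsets = [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]
    r2 = {s: _subset_r2(y, X, s, allow_singular=True) for s in subsets}
    # unknown order: uA, uB, uC, cAB, cAC, cBC, cABC
    comps = [{0}, {1}, {2}, {0, 1}, {0, 2}, {1, 2}, {0, 1, 2}]
    M = np.array([[1.0 if set(s) & c else 0.0 for c in comps] for s in subsets])
    sol = np.linalg.solve(M, np.array([r2[s] for s in subsets]))
    a, b, c = names
    return VennPartition3(
        unique={a: sol[0], b: sol[1], c: sol[2]},
        pairwise={a + b: sol[3], a + c: sol[4], b + c: sol[5]},
        triple=float(sol[6]),
        full_r2=r2[(0, 1, 2)],
    )


def soil_pca(ph, organic_carbon, cation_exchange):
    """First principal component of the three standardised soil variables.

    Returns (PC1 scores, fraction of variance on PC1).  Sign convention:
    the organic-carbon loading is non-negative.
    """
    X = np.column_stack([ph, organic_carbon, cation_exchange]).astype(float)
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 3:
        raise ValueError("need >= 3 complete rows")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateInputError("zero-variance soil column")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    v1 = vecs[:, -1]
    if v1[1] < 0:
        v1 = -v1
    return Z @ v1, float(vals[-1] / vals.sum())
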