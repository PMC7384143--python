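"""Phylogenetic signal and evolutionary-age analyses of leaf size.

Blomberg's K compares the observed partitioning of trait variance on a
tree with the Brownian-motion expectation.  With V the phylogenetic
covariance matrix (shared root-to-MRCA path lengths), GLS mean
a = (1'V^-1 y)/(1'V^-1 1):

    MSE0 = sum((y - a)^2) / (n - 1)
    MSE  = (y - a)' V^-1 (y - a) / (n - 1)
    K    = (MSE0/MSE) / [ (tr(V) - n / sum(V^-1)) / (n - 1) ]

K = 1 is the Brownian expectation; K near 0 means trait values are
independent of phylogeny (a star tree gives K = 1 for any trait, since
V = I makes observed and expected ratios coincide).  Significance comes
from permuting trait values across tips.

The module also computes per-grid-cell mean clade (family/genus) stem
age and the standardised leaf-size x clade-age interaction on
productivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Phylogeny",
    "PhyloSignalResult",
    "blomberg_k",
    "blomberg_k_test",
    "cell_mean_clade_age",
    "age_interaction_model",
]

ZERO_BRANCH_EPS = 1e-8  # Myr added to zero-length terminal branches


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in Myr and its covariance matrix."""

    taxa: list[str]
    vcv: np.ndarray                 # shared path length to root, n x n
    tree: dendropy.Tree | None = None
    ultrametric: bool = False

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        tree = tree.clone(depth=1)
        leaves = tree.leaf_nodes()
        taxa = [lf.taxon.label for lf in leaves]
        n = len(taxa)
        idx = {id(lf): k for k, lf in enumerate(leaves)}
        V = np.zeros((n, n))
        # accumulate each edge's length onto all tip pairs descending from it
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                node._depth = 0.0
                continue
            elen = node.edge.length or 0.0
            node._depth = node.parent_node._depth + elen
            tips = [idx[id(lf)] for lf in node.leaf_iter()]
            if len(tips) == 1 and elen == 0.0:
                elen = ZERO_BRANCH_EPS
            tips = np.asarray(tips)
            V[np.ix_(tips, tips)] += elen
        depths = np.diag(V)
        ultra = np.allclose(depths, depths[0], rtol=1e-6)
        return cls(taxa=taxa, vcv=V, tree=tree, ultrametric=bool(ultra))

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @property
    def n(self) -> int:
        return len(self.taxa)


@dataclass
class PhyloSignalResult:
    k: float
    mse0: float
    mse: float
    expected_ratio: float           # Brownian expectation of MSE0/MSE
    p: float | None = None
    n_perm: int = 0
    seed: int | None = None
    n: int = 0
    flags: dict = field(default_factory=dict)


def _k_statistic(Vinv: np.ndarray, expected_ratio: float, y: np.ndarray) -> tuple:
    n = y.size
    one = np.ones(n)
    w = Vinv @ one
    a = float(one @ Vinv @ y) / float(one @ w)
    d = y - a
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ Vinv @ d) / (n - 1)
    return (mse0 / mse) / expected_ratio, mse0, mse


def _prepare(tree: Phylogeny, traits: pd.Series | dict):
    traits = pd.Series(traits)
    common = [t for t in tree.taxa if t in traits.index]
    if len(common) < 3:
        raise ValueError("need >= 3 taxa matched between tree and traits")
    dropped = tree.n - len(common)
    keep = [tree.taxa.index(t) for t in common]
    V = tree.vcv[np.ix_(keep, keep)]
    y = traits.loc[common].to_numpy(dtype=float)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance matrix (zero-length branches?)"
        ) from e
    n = len(common)
    expected = (np.trace(V) - n / Vinv.sum()) / (n - 1)
    return y, Vinv, expected, n, dropped


def blomberg_k(tree: Phylogeny, traits: pd.Series | dict) -> PhyloSignalResult:
    """Blomberg's K for trait values on a tree (no significance test).

    Tips absent from the trait vector are pruned (count recorded in
    ``flags``).  K is invariant to affine transforms of the trait.
    """
    y, Vinv, expected, n, dropped = _prepare(tree, traits)
    k, mse0, mse = _k_statistic(Vinv, expected, y)
    return PhyloSignalResult(k=float(k), mse0=mse0, mse=mse,
                             expected_ratio=float(expected), n=n,
                             flags={"n_pruned": dropped} if dropped else {})


def blomberg_k_test(tree: Phylogeny, traits: pd.Series | dict,
                    n_perm: int = 999, seed: int = 0) -> PhyloSignalResult:
    """K with a permutation p-value (trait values shuffled across tips).

    p = (1 + #{K_perm >= K_obs}) / (n_perm + 1).
    """
    import warnings
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse",
                      stacklevel=2)
    y, Vinv, expected, n, dropped = _prepare(tree, traits)
    k_obs, mse0, mse = _k_statistic(Vinv, expected, y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        k_p, _, _ = _k_statistic(Vinv, expected, rng.permutation(y))
        if k_p >= k_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return PhyloSignalResult(k=float(k_obs), mse0=mse0, mse=mse,
                             expected_ratio=float(expected), p=float(p),
                             n_perm=n_perm, seed=seed, n=n,
                             flags={"n_pruned": dropped} if dropped else {})


def cell_mean_clade_age(presence: pd.DataFrame, species_clade: pd.Series | dict,
                        clade_ages: pd.Series | dict) -> pd.Series:
    """Unweighted mean clade stem age (Myr) of the species in each cell.

    Every species contributes its clade's age individually, so three
    congeners of a 40-Myr genus contribute 40 three times (which leaves
    the mean at 40).  Species without a mapped, dated clade are excluded
    (their count is attached as ``attrs['n_unmapped']``).
    """
    species_clade = pd.Series(species_clade)
    clade_ages = pd.Series(clade_ages, dtype=float)
    if (clade_ages <= 0).any():
        raise ValueError("clade ages must be positive")
    age_per_species = species_clade.map(clade_ages)
    cols = presence.columns
    ages = age_per_species.reindex(cols)
    ok = ages.notna().to_numpy()
    P = presence.to_numpy(dtype=float)
    num = P[:, ok] @ ages.to_numpy(dtype=float)[ok]
    den = P[:, ok].sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = pd.Series(np.where(den > 0, num / np.where(den > 0, den, 1), np.nan),
                        index=presence.index, name="mean_clade_age")
    out.attrs["n_unmapped"] = int((~ok).sum())
    return out


def age_interaction_model(productivity, leaf_size, clade_age) -> pd.DataFrame:
    """OLS of productivity on standardised leaf size, age and their product.

    All three predictors are z-scored before the interaction term is
    built, so coefficients are standardised and the interaction sign is
    directly interpretable (the quantity of interest: a negative sign
    means older assemblages couple leaf size to productivity more
    weakly).
    """
    y = np.asarray(productivity, dtype=float)
    ls = np.asarray(leaf_size, dtype=float)
    ag = np.asarray(clade_age, dtype=float)
    ok = np.isfinite(y) & np.isfinite(ls) & np.isfinite(ag)
    y, ls, ag = y[ok], ls[ok], ag[ok]
    if ls.std() == 0 or ag.std() == 0:
        raise ValueError("constant predictor: interaction model undefined")

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    zy, zl, za = z(y), z(ls), z(ag)
    X = sm.add_constant(np.column_stack([zl, za, zl * za]))
    if np.linalg.cond(X) > 1e6:
        raise ValueError("ill-conditioned design (collinear predictors)")
    res = sm.OLS(zy, X).fit()
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues},
        index=["intercept", "leaf_size", "clade_age", "leaf_size:clade_age"],
    )
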