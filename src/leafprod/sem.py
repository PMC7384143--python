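"""Piecewise structural equation models on a DAG of cell-table variables.

Each endogenous variable (one with incoming edges) is fitted by OLS on
its parents after optional response transforms (productivity is
square-root transformed by default in the study designs) and
z-standardisation of every variable, so path coefficients are
standardised: with a single parent the coefficient equals the Pearson
correlation.  Models are saturated by construction here, so no
d-separation goodness-of-fit test is run; inference is on the path
coefficients themselves.

Effects decomposition is exact path arithmetic: the indirect effect of a
source on a sink is the sum over all directed paths of length >= 2 of
the product of edge coefficients; total = direct + indirect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["SEMSpec", "SEMFit", "fit_piecewise_sem", "effects_decomposition"]

TRANSFORMS = {"sqrt": np.sqrt, "log": np.log, "none": lambda v: v}


@dataclass(frozen=True)
class SEMSpec:
    """Node list, directed edges and per-variable response transforms."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    transforms: tuple[tuple[str, str], ...] = ()

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> nx.DiGraph:
        g = self.graph()
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("SEM graph contains a cycle")
        for var, tname in self.transforms:
            if var not in self.nodes:
                raise ValueError(f"transform references unknown node {var!r}")
            if tname not in TRANSFORMS:
                raise ValueError(f"unknown transform {tname!r}")
        return g

    @classmethod
    def from_dict(cls, d: dict) -> "SEMSpec":
        return cls(nodes=tuple(d["nodes"]),
                   edges=tuple((u, v) for u, v in d["edges"]),
                   transforms=tuple(d.get("transforms", {}).items()))


@dataclass
class SEMFit:
    spec: SEMSpec
    coefficients: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    component_r2: dict[str, float]
    n: int
    effects: pd.DataFrame | None = field(default=None, repr=False)


def fit_piecewise_sem(spec: SEMSpec, data: pd.DataFrame) -> SEMFit:
    """Fit each endogenous node's OLS component on standardised data.

    Complete cases only; transforms are applied before standardisation.
    """
    g = spec.validate()
    missing = [v for v in spec.nodes if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks SEM variables {missing}")
    df = data[list(spec.nodes)].dropna().copy()
    n = len(df)
    if n < len(spec.nodes) + 2:
        raise ValueError("too few complete cases")
    for var, tname in spec.transforms:
        df[var] = TRANSFORMS[tname](df[var])
    z = (df - df.mean()) / df.std(ddof=1)
    if z.isna().any().any():
        bad = z.columns[z.isna().any()].tolist()
        raise ValueError(f"zero variance or invalid transform for {bad}")

    coefs, pvals, r2 = {}, {}, {}
    for node in spec.nodes:
        parents = sorted(g.predecessors(node))
        if not parents:
            continue
        X = sm.add_constant(z[parents].to_numpy())
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(f"singular component regression for {node}")
        res = sm.OLS(z[node].to_numpy(), X).fit()
        for i, p in enumerate(parents, start=1):
            coefs[(p, node)] = float(res.params[i])
            pvals[(p, node)] = float(res.pvalues[i])
        r2[node] = float(res.rsquared)
    fit = SEMFit(spec, coefs, pvals, r2, n)
    fit.effects = effects_decomposition(fit)
    return fit


def effects_decomposition(fit: SEMFit) -> pd.DataFrame:
    """Direct, indirect (path products) and total effects per node pair.

    Rows cover every ordered (source, sink) pair connected by at least
    one directed path.
    """
    g = fit.spec.graph()
    rows = []
    for src in fit.spec.nodes:
        for snk in fit.spec.nodes:
            if src == snk:
                continue
            direct = fit.coefficients.get((src, snk), 0.0)
            indirect = 0.0
            for path in nx.all_simple_paths(g, src, snk):
                if len(path) < 3:
                    continue
                prod = 1.0
                for u, v in zip(path[:-1], path[1:]):
                    prod *= fit.coefficients[(u, v)]
                indirect += prod
            if direct == 0.0 and indirect == 0.0 and not g.has_edge(src, snk):
                if not nx.has_path(g, src, snk):
                    continue
            rows.append({"source": src, "sink": snk, "direct": direct,
                         "indirect": indirect, "total": direct + indirect})
    return pd.DataFrame(rows)
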