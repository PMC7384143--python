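"""The analysis grid: rasterisation, resampling, richness filtering.

All coordinates are planar kilometres; a cell of :class:`GridSpec` is
half-open (a point at the shared edge belongs to the higher-index cell),
indices are 0-based and ``cell_id = j * nx + i``.  A *cell table* is a
pandas DataFrame with one row per cell, indexed by ``cell_id``, carrying
cell-centre coordinates, environmental and productivity columns, species
richness and community trait means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "rasterize_occurrences",
    "resample_surface",
    "filter_richness",
    "ranked_year_mean",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular analysis grid of nx * ny square cells.

    Default cell size is 50 km, the resolution at which species ranges
    are rasterised to presence/absence.
    """

    nx: int
    ny: int
    cell_size: float = 50.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_index(self, x, y):
        """(i, j) column/row index of each point; half-open membership."""
        i = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_size).astype(int)
        j = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell_size).astype(int)
        return i, j

    def cell_id(self, x, y):
        i, j = self.cell_index(x, y)
        return j * self.nx + i

    def in_bounds(self, x, y):
        i, j = self.cell_index(x, y)
        return (i >= 0) & (i < self.nx) & (j >= 0) & (j < self.ny)

    def centres(self) -> pd.DataFrame:
        """Cell-centre table indexed by cell_id."""
        ids = np.arange(self.n_cells)
        i = ids % self.nx
        j = ids // self.nx
        return pd.DataFrame(
            {"x": self.x0 + (i + 0.5) * self.cell_size,
             "y": self.y0 + (j + 0.5) * self.cell_size},
            index=pd.Index(ids, name="cell_id"),
        )


def rasterize_occurrences(occurrences: pd.DataFrame, grid: GridSpec,
                          strict: bool = True) -> pd.DataFrame:
    """Occurrence points -> boolean presence matrix (cell_id x species).

    ``occurrences`` needs columns ``species``, ``x``, ``y``.  Duplicated
    records are idempotent.  Out-of-bounds records raise in strict mode,
    otherwise they are dropped with a warning carrying the count.
    """
    for col in ("species", "x", "y"):
        if col not in occurrences.columns:
            raise ValueError(f"occurrences must have a {col!r} column")
    ok = grid.in_bounds(occurrences["x"], occurrences["y"])
    if not ok.all():
        bad = occurrences.index[~ok].tolist()
        if strict:
            raise ValueError(f"{len(bad)} occurrence records outside grid "
                             f"bounds (rows {bad[:10]}{'...' if len(bad) > 10 else ''})")
        warnings.warn(f"dropped {len(bad)} out-of-bounds occurrence records",
                      stacklevel=2)
        occurrences = occurrences[ok]
    ids = grid.cell_id(occurrences["x"], occurrences["y"])
    flags = pd.crosstab(pd.Index(ids, name="cell_id"),
                        occurrences["species"]) > 0
    return flags


def resample_surface(fine: pd.DataFrame, coarse: GridSpec,
                     value_cols: list[str] | None = None) -> pd.DataFrame:
    """Average a fine-resolution cell table onto a coarser grid.

    Each fine cell centre is assigned to the coarse cell containing it;
    the coarse value is the mean of contributing fine values (NaN where a
    coarse cell receives none, counted in a warning).
    """
    if fine.empty:
        warnings.warn("empty fine table: empty resample", stacklevel=2)
        return coarse.centres()
    value_cols = value_cols or [c for c in fine.columns if c not in ("x", "y")]
    inb = coarse.in_bounds(fine["x"], fine["y"])
    fine = fine[inb]
    ids = coarse.cell_id(fine["x"], fine["y"])
    agg = fine[value_cols].groupby(pd.Index(ids, name="cell_id")).mean()
    out = coarse.centres().join(agg)
    n_empty = int(out[value_cols].isna().all(axis=1).sum())
    if n_empty:
        warnings.warn(f"{n_empty} coarse cells received no fine cells",
                      stacklevel=2)
    return out


def filter_richness(cells: pd.DataFrame, min_species: int = 20
                    ) -> tuple[pd.DataFrame, int]:
    """Drop cells with fewer than ``min_species`` species.

    The boundary cell (richness exactly ``min_species``) is kept: the
    rule removes cells with *less than* the threshold.  Returns the
    filtered table and the number of cells removed.
    """
    if "richness" not in cells.columns:
        raise ValueError("cell table has no 'richness' column")
    keep = cells["richness"] >= min_species
    n_removed = int((~keep).sum())
    out = cells[keep]
    if out.empty:
        warnings.warn("all cells fall below the richness threshold",
                      stacklevel=2)
    return out, n_removed


def ranked_year_mean(stack: pd.DataFrame, m: int, side: str = "highest"
                     ) -> pd.Series:
    """Per-cell mean of the m highest (or lowest) yearly values.

    ``stack`` has one row per cell and one column per year.  Ties are
    broken by year order (earlier year first), which cannot change the
    mean but fixes which years are nominally selected.
    """
    if side not in ("highest", "lowest"):
        raise ValueError("side must be 'highest' or 'lowest'")
    n_years = stack.shape[1]
    if m > n_years:
        raise ValueError(f"m={m} exceeds the {n_years} available years")
    vals = stack.to_numpy(dtype=float)
    srt = np.sort(vals, axis=1, kind="stable")
    sel = srt[:, -m:] if side == "highest" else srt[:, :m]
    return pd.Series(sel.mean(axis=1), index=stack.index,
                     name=f"{side}_{m}yr_mean")
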