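"""Species leaf-size scalars and unweighted community means.

Floras report leaf length and width as min-max ranges; the per-species
"median" is taken as the range midpoint and the "maximum" as the upper
bound.  Leaf area is approximated by the elliptical-shape proxy
(2/3) * length * width (cm^2); the correction factor is configurable
(3/4 is the common alternative for more rhomboid leaves).

Community means are unweighted arithmetic means over the species present
in a cell — presence/absence only, no abundance weighting — optionally
restricted to a life form (habit and/or phenology).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LeafTraitRecord",
    "leaf_area_proxy",
    "species_trait_scalar",
    "species_scalar_table",
    "community_mean",
]

HABITS = ("tree", "shrub", "liana")
PHENOLOGIES = ("deciduous", "evergreen", "unknown")
MEASURES = ("length", "width", "lw_product")
STATISTICS = ("median", "maximum")


@dataclass(frozen=True)
class LeafTraitRecord:
    """One species' flora-reported leaf dimensions and life form."""

    species: str
    habit: str
    phenology: str = "unknown"
    length_min: float | None = None
    length_max: float | None = None
    width_min: float | None = None
    width_max: float | None = None

    def __post_init__(self):
        for lo, hi in ((self.length_min, self.length_max),
                       (self.width_min, self.width_max)):
            if lo is not None and hi is not None and not (0 < lo <= hi):
                raise ValueError(f"invalid trait range ({lo}, {hi}) "
                                 f"for {self.species}")


def leaf_area_proxy(length: float, width: float, factor: float = 2.0 / 3.0) -> float:
    """Leaf area proxy = factor * length * width (cm^2), default 2/3."""
    if np.any(np.asarray(length) <= 0) or np.any(np.asarray(width) <= 0):
        raise ValueError("length and width must be positive")
    return factor * length * width


class MissingBoundError(ValueError):
    pass


def species_trait_scalar(record: LeafTraitRecord, measure: str,
                         statistic: str = "median",
                         area_factor: float = 2.0 / 3.0) -> float:
    """One scalar per species: range midpoint ('median') or upper bound.

    ``lw_product`` applies :func:`leaf_area_proxy` to the chosen
    statistic of length and of width.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")

    def scalar(lo, hi):
        if lo is None or hi is None:
            raise MissingBoundError(
                f"{record.species}: missing bound for {measure}")
        return (lo + hi) / 2.0 if statistic == "median" else hi

    if measure == "length":
        return scalar(record.length_min, record.length_max)
    if measure == "width":
        return scalar(record.width_min, record.width_max)
    L = scalar(record.length_min, record.length_max)
    W = scalar(record.width_min, record.width_max)
    return leaf_area_proxy(L, W, area_factor)


def species_scalar_table(records: list[LeafTraitRecord] | pd.DataFrame,
                         statistic: str = "median",
                         area_factor: float = 2.0 / 3.0) -> pd.DataFrame:
    """Per-species scalars for all three measures, plus life-form labels.

    Species with a missing bound for a measure get NaN there and are
    counted in the returned frame's ``attrs['n_skipped']`` (floras cover
    length/width for only ~93-94% of species; the gap must be tracked).
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_frame(records)
    rows, n_skipped = [], {m: 0 for m in MEASURES}
    for rec in records:
        row = {"species": rec.species, "habit": rec.habit,
               "phenology": rec.phenology}
        for m in MEASURES:
            try:
                row[m] = species_trait_scalar(rec, m, statistic, area_factor)
            except MissingBoundError:
                row[m] = np.nan
                n_skipped[m] += 1
        rows.append(row)
    out = pd.DataFrame(rows).set_index("species")
    out.attrs["n_skipped"] = n_skipped
    out.attrs["statistic"] = statistic
    return out


def records_from_frame(df: pd.DataFrame) -> list[LeafTraitRecord]:
    """Build records from a traits CSV frame (see synthetic.write_csvs)."""
    recs = []
    for _, r in df.iterrows():
        def get(col):
            v = r.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        recs.append(LeafTraitRecord(
            species=str(r["species"]), habit=str(r["habit"]),
            phenology=str(r.get("phenology", "unknown")),
            length_min=get("length_min"), length_max=get("length_max"),
            width_min=get("width_min"), width_max=get("width_max")))
    return recs


def community_mean(presence: pd.DataFrame, scalars: pd.DataFrame,
                   habit: str | None = None, phenology: str | None = None
                   ) -> pd.DataFrame:
    """Unweighted community mean of each trait measure per cell.

    Parameters
    ----------
    presence : DataFrame
        Boolean cell_id x species matrix.
    scalars : DataFrame
        Output of :func:`species_scalar_table`.
    habit, phenology : str, optional
        Life-form filter.  A species with unknown phenology is *not*
        excluded from habit-only subsets.

    Returns a frame indexed like ``presence`` with ``mean_length``,
    ``mean_width``, ``mean_lw_product`` and ``richness`` (count of
    contributing species, i.e. present, passing the filter, with at
    least one non-missing scalar).  Cells with no contributing species
    get NaN means and richness 0.
    """
    unknown = presence.columns.difference(scalars.index)
    if len(unknown):
        warnings.warn(f"{len(unknown)} species in the presence matrix have "
                      "no trait record; ignored", stacklevel=2)
        presence = presence.drop(columns=unknown)
    sc = scalars.loc[presence.columns]
    mask = pd.Series(True, index=sc.index)
    if habit is not None:
        mask &= sc["habit"] == habit
    if phenology is not None:
        mask &= sc["phenology"] == phenology
    sc = sc[mask]
    P = presence.loc[:, sc.index].to_numpy(dtype=float)

    out = {}
    vals = sc[list(MEASURES)].to_numpy(dtype=float)
    has_any = ~np.isnan(vals).all(axis=1)
    for k, m in enumerate(MEASURES):
        v = vals[:, k]
        ok = ~np.isnan(v)
        num = P[:, ok] @ v[ok]
        den = P[:, ok].sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[f"mean_{m}"] = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    out["richness"] = P[:, has_any].sum(axis=1).astype(int)
    return pd.DataFrame(out, index=presence.index)
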