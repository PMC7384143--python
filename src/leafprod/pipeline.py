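"""End-to-end orchestration of the synthetic leaf-size study.

``run_pipeline`` sequences the stages — simulate, grid/traits,
trait-climate fits with spatially corrected tests and hierarchical
partitioning, transfer-function fits (a parameter table with K, alpha,
r, R^2, n, SE, SE%), cross-region validation, phylogenetic signal and
SEMs — and writes a machine-readable results JSON plus a plain-text
summary.  The ``leafprod`` console script exposes the stages as
composable commands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import synthetic, traits as traits_mod, spatial, transfer as transfer_mod
from .gridding import filter_richness
from .phylo import blomberg_k_test, cell_mean_clade_age, age_interaction_model
from .regress import fit_model
from .sem import SEMSpec, fit_piecewise_sem
from .synthetic import SyntheticScenario, generate_region
from .transfer import fit_transfer, cross_region_validate, inverse_logistic, \
    evaluate_transfer

log = logging.getLogger("leafprod")

CLIMATE_VARS = ["MAP", "MPWQ", "AI", "MAT", "MTWQ", "MTCQ", "AET", "SRAD"]
TRAIT_COLS = {"length": "mean_length", "width": "mean_width",
              "lw_product": "mean_lw_product"}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    out_dir: str = "results/pipeline"
    min_richness: int = 20
    bonferroni_divisor: int = 48     # alpha = 0.05 / 48 for Fig-1-style grids
    n_distance_classes: int | None = None
    n_permutations: int = 199
    phylo_tips: int = 100
    clade_cut_age: float | None = None   # default: half the tree depth
    stages: tuple[str, ...] = ("simulate", "traits", "climate", "transfer",
                               "validate", "phylo", "sem")

    def __post_init__(self):
        if self.bonferroni_divisor < 1:
            raise ValueError("Bonferroni divisor must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "scenario" in d:
            sc = d["scenario"]
            if isinstance(sc, str):
                p = Path(sc)
                if not p.exists():
                    raise FileNotFoundError(f"scenario file {sc} not found")
                d["scenario"] = SyntheticScenario.from_json(p.read_text())
            else:
                d["scenario"] = SyntheticScenario(**sc)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _prepare_cells(region: dict, min_richness: int) -> pd.DataFrame:
    cells, n_removed = filter_richness(region["cells"], min_richness)
    log.info("richness filter (< %d species): removed %d of %d cells",
             min_richness, n_removed, len(region["cells"]))
    soil = spatial.soil_pca(cells["soil_ph"], cells["soil_oc"], cells["soil_cec"])
    cells = cells.copy()
    cells["soilPC1"] = soil[0]
    cells.attrs["soil_pc1_variance_fraction"] = soil[1]
    cells.attrs["n_removed_richness"] = n_removed
    return cells


def climate_stage(cells: pd.DataFrame, cfg: RunConfig) -> dict:
    """Trait-climate R^2 matrix with modified t-test significance.

    For each trait x climate pair the logistic and linear families are
    fitted (logistic falls back to linear for decreasing relationships,
    which the rising logistic cannot represent); significance of the
    pairwise correlation uses the Dutilleul-corrected test at the
    Bonferroni-adjusted level alpha = 0.05 / divisor.
    """
    alpha = 0.05 / cfg.bonferroni_divisor
    coords = cells[["x", "y"]].to_numpy()
    out = {}
    for tname, tcol in TRAIT_COLS.items():
        y = cells[tcol].to_numpy()
        for cv in CLIMATE_VARS:
            x = cells[cv].to_numpy()
            lin = fit_model(x, y, "linear")
            try:
                logi = fit_model(x, y, "logistic")
                r2 = max(logi.r2, lin.r2)
                family = "logistic" if logi.r2 >= lin.r2 else "linear"
            except Exception:
                r2, family = lin.r2, "linear"
            mt = spatial.modified_t_test(x, y, coords,
                                         n_classes=cfg.n_distance_classes)
            out[f"{tname}~{cv}"] = {
                "r2": r2, "family": family, "r": mt.r, "m_hat": mt.m_hat,
                "p": mt.p, "significant": bool(mt.p < alpha), "n": mt.n,
            }
    log.info("climate stage: alpha = 0.05/%d = %.2e applied to %d tests",
             cfg.bonferroni_divisor, alpha, len(out))
    # hierarchical partitioning of mean length on the main climate axes
    X = cells[["AET", "MAP", "MAT", "SRAD"]].to_numpy()
    hp = spatial.hierarchical_partition(cells["mean_length"].to_numpy(), X,
                                        ["AET", "MAP", "MAT", "SRAD"])
    out["hierarchical_partition_mean_length"] = {
        "independent": dict(zip(hp.names, hp.independent.tolist())),
        "joint": dict(zip(hp.names, hp.joint.tolist())),
        "full_r2": hp.full_r2,
    }
    out["soil_pc1_variance_fraction"] = cells.attrs.get(
        "soil_pc1_variance_fraction")
    return out


def transfer_stage(cells: pd.DataFrame, region_label: str = "A") -> dict:
    """Fit the six trait x productivity transfer rows (table analogue)."""
    rows = []
    for prod in ("GPP", "NPP"):
        for tname, tcol in TRAIT_COLS.items():
            model = fit_transfer(cells[tcol], cells[prod], "inv_logistic",
                                 trait=tname, productivity=prod,
                                 region=region_label)
            y_hat = inverse_logistic(cells[tcol].to_numpy(), **model.params)
            ev = evaluate_transfer(y_hat, cells[prod].to_numpy())
            model.se, model.se_pct = ev.se, ev.se_pct
            log.info("transfer %s~%s: excluded %d cells with x >= K",
                     prod, tname, model.n_excluded)
            rows.append({"y": prod, "x": tname, "K": model.params["K"],
                         "alpha": model.params["alpha"], "r": model.params["r"],
                         "r2": model.r2, "n_cells": model.n, "se": ev.se,
                         "se_pct": ev.se_pct, "model": model})
    return {"table": rows}


def zero_noise_round_trip(scenario: SyntheticScenario) -> pd.DataFrame:
    """Forward-generate/refit check for all six transfer rows, noise off.

    Each row's productivity is generated from that row's trait with the
    scenario's parameters and zero noise, then refitted; with no noise
    the inverse-logistic transfer is exactly recoverable, so every row
    reports R^2 = 1 and near-zero SE.
    """
    sc = dataclasses.replace(scenario, noise_frac=0.0)
    region = generate_region(sc)
    cells, _ = filter_richness(region["cells"])
    rows = []
    for (prod, tname), lp in sc.transfer.items():
        x = cells[TRAIT_COLS[tname]].to_numpy()
        y = inverse_logistic(x, *lp.as_tuple())
        ok = np.isfinite(y)
        model = fit_transfer(x[ok], y[ok], "inv_logistic", trait=tname,
                             productivity=prod)
        ev = evaluate_transfer(inverse_logistic(x[ok], **model.params), y[ok])
        rows.append({"y": prod, "x": tname, "K": model.params["K"],
                     "K_true": lp.K, "r2": model.r2, "se": ev.se,
                     "n_cells": model.n})
    return pd.DataFrame(rows)


def validate_stage(models: dict, region_b: dict, min_richness: int) -> dict:
    """Apply region-A transfer models to region B (1:1-line comparison)."""
    cells_b, _ = filter_richness(region_b["cells"], min_richness)
    out = {}
    for row in models["table"]:
        model = row["model"]
        ev, _ = cross_region_validate(model, cells_b,
                                      TRAIT_COLS[model.trait],
                                      model.productivity)
        out[f"{model.productivity}~{model.trait}"] = {
            "r2": ev.r2, "se": ev.se, "se_pct": ev.se_pct,
            "slope": ev.slope, "intercept": ev.intercept, "n": ev.n,
        }
    return out


def phylo_stage(region: dict, cfg: RunConfig) -> dict:
    """Signal in leaf size, cell mean clade age, age x size interaction."""
    sc = region["scenario"]
    tree, _ = synthetic.make_phylogeny(sc, n_tips=cfg.phylo_tips)
    scalars = region["scalars"]
    # species median length mapped onto the tree's tips (tip labels are
    # generated species ids, matching the pool's first phylo_tips species)
    trait = scalars["length"].reindex(tree.taxa).dropna()
    res = blomberg_k_test(tree, trait, n_perm=cfg.n_permutations,
                          seed=int(sc.seed % 2**31))
    depth = float(np.max(np.diag(tree.vcv)))
    cut = cfg.clade_cut_age if cfg.clade_cut_age is not None else depth / 2
    clades, ages = synthetic.clades_from_tree(tree, cut)
    pres = region["presence"]
    shared = [s for s in pres.columns if s in clades.index]
    ages_cells = cell_mean_clade_age(pres[shared], clades, ages)
    cells, _ = filter_richness(region["cells"], cfg.min_richness)
    merged = cells.join(ages_cells)
    inter = age_interaction_model(merged["GPP"], merged["mean_length"],
                                  merged["mean_clade_age"])
    return {
        "blomberg_k": res.k, "blomberg_p": res.p, "n_taxa": res.n,
        "n_permutations": res.n_perm,
        "clade_cut_age_myr": cut,
        "age_interaction": inter.loc["leaf_size:clade_age"].to_dict(),
    }


#: the three study SEM topologies (productivity sqrt-transformed)
def sem_specs(prod: str = "GPP") -> dict[str, SEMSpec]:
    t = ((prod, "sqrt"),)
    return {
        "climate_trait": SEMSpec(("AET", "mean_length", prod),
                                 (("AET", "mean_length"), ("AET", prod),
                                  ("mean_length", prod)), t),
        "trait_lai": SEMSpec(("mean_length", "LAI", prod),
                             (("mean_length", "LAI"), ("mean_length", prod),
                              ("LAI", prod)), t),
        "climate_trait_lai": SEMSpec(("AET", "mean_length", "LAI", prod),
                                     (("AET", "mean_length"), ("AET", "LAI"),
                                      ("AET", prod), ("mean_length", "LAI"),
                                      ("mean_length", prod), ("LAI", prod)), t),
    }


def sem_stage(cells: pd.DataFrame) -> dict:
    out = {}
    for prod in ("GPP", "NPP"):
        for name, spec in sem_specs(prod).items():
            fit = fit_piecewise_sem(spec, cells)
            eff = fit.effects
            aet_rows = eff[(eff["source"] == "AET") & (eff["sink"] == prod)]
            out[f"{name}_{prod}"] = {
                "paths": {f"{u}->{v}": c for (u, v), c in
                          fit.coefficients.items()},
                "component_r2": fit.component_r2,
                "aet_direct": float(aet_rows["direct"].iloc[0])
                if len(aet_rows) else None,
                "aet_indirect": float(aet_rows["indirect"].iloc[0])
                if len(aet_rows) else None,
            }
        # Venn partition of sqrt-productivity on leaf size, AET, LAI
        vp = spatial.venn_partition3(np.sqrt(cells[prod]), cells["mean_length"],
                                     cells["AET"], cells["LAI"],
                                     names=("leaf", "AET", "LAI"))
        out[f"venn_{prod}"] = {"unique": vp.unique, "pairwise": vp.pairwise,
                               "triple": vp.triple, "full_r2": vp.full_r2}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": {"seed": config.scenario.seed,
                                "min_richness": config.min_richness,
                                "bonferroni_divisor": config.bonferroni_divisor}}
    region_a = region_b = cells = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if "simulate" in config.stages or "traits" in config.stages:
            region_a = generate_region(config.scenario, label="A")
            region_b = generate_region(
                config.scenario, seed=(config.scenario.seed + 1) % 2**31,
                label="B")
            cells = _prepare_cells(region_a, config.min_richness)
            results["simulate"] = {
                "n_cells": len(region_a["cells"]), "n_species":
                config.scenario.n_species,
                "n_cells_filtered": len(cells),
                "n_removed_richness": cells.attrs["n_removed_richness"],
            }
        if "climate" in config.stages:
            results["climate"] = climate_stage(cells, config)
        models = None
        if "transfer" in config.stages:
            models = transfer_stage(cells, "A")
            results["transfer"] = {"table": [
                {k: v for k, v in row.items() if k != "model"}
                for row in models["table"]]}
        if "validate" in config.stages and models is not None:
            results["validate"] = validate_stage(models, region_b,
                                                 config.min_richness)
        if "phylo" in config.stages:
            results["phylo"] = phylo_stage(region_a, config)
        if "sem" in config.stages:
            results["sem"] = sem_stage(cells)

    (out_dir / "results.json").write_text(
        json.dumps(results, indent=2, default=_jsonable))
    (out_dir / "summary.txt").write_text(_summary(results))
    log.info("pipeline complete: %s", out_dir / "results.json")
    return results


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _summary(res: dict) -> str:
    lines = ["leafprod pipeline summary", "=" * 30]
    if "simulate" in res:
        s = res["simulate"]
        lines.append(f"cells: {s['n_cells']} simulated, "
                     f"{s['n_cells_filtered']} kept after the >=20-species "
                     f"filter ({s['n_removed_richness']} removed)")
    if "climate" in res:
        best = max((k for k in res["climate"] if "~" in k),
                   key=lambda k: res["climate"][k]["r2"])
        lines.append(f"best trait-climate model: {best} "
                     f"R2={res['climate'][best]['r2']:.3f}")
    if "transfer" in res:
        lines.append("transfer functions (y = (1/r)(alpha - ln(K/x - 1))):")
        for row in res["transfer"]["table"]:
            lines.append(
                f"  {row['y']}~{row['x']}: K={row['K']:.3f} "
                f"alpha={row['alpha']:.3f} r={row['r']:.4f} R2={row['r2']:.2f} "
                f"n={row['n_cells']} SE={row['se']:.1f} SE%={row['se_pct']:.2f}")
    if "validate" in res:
        for k, v in res["validate"].items():
            lines.append(f"  cross-region {k}: slope={v['slope']:.3f} "
                         f"R2={v['r2']:.3f} SE%={v['se_pct']:.2f}")
    if "phylo" in res:
        p = res["phylo"]
        lines.append(f"Blomberg K = {p['blomberg_k']:.3f} (p = "
                     f"{p['blomberg_p']:.3f}, {p['n_taxa']} taxa)")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose):
    """Leaf size / productivity pipeline commands."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")


def _load_config(config_path: str | None) -> RunConfig:
    return RunConfig.from_yaml(config_path) if config_path else RunConfig()


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", default="results/pipeline", show_default=True)
def run_all(config_path, out):
    """Run the full synthetic study end to end."""
    cfg = _load_config(config_path)
    cfg.out_dir = out
    run_pipeline(cfg)
    click.echo((Path(out) / "summary.txt").read_text())


def _stage_command(name: str, stages: tuple[str, ...]):
    @cli.command(name=name)
    @click.option("--config", "config_path", type=click.Path(exists=True))
    @click.option("--out", default=f"results/{name}", show_default=True)
    def _cmd(config_path, out):
        cfg = _load_config(config_path)
        cfg.out_dir = out
        cfg.stages = stages
        run_pipeline(cfg)
        click.echo((Path(out) / "summary.txt").read_text())
    _cmd.__doc__ = f"Run the {name} stage (plus its prerequisites)."
    return _cmd


simulate = _stage_command("simulate", ("simulate",))
grid = _stage_command("grid", ("simulate", "traits"))
traits_cmd = _stage_command("traits", ("simulate", "traits"))
fit_climate = _stage_command("fit-climate", ("simulate", "traits", "climate"))
fit_transfer_cmd = _stage_command("fit-transfer",
                                  ("simulate", "traits", "transfer"))
validate_transfer = _stage_command(
    "validate-transfer", ("simulate", "traits", "transfer", "validate"))
phylo_cmd = _stage_command("phylo", ("simulate", "traits", "phylo"))
sem_cmd = _stage_command("sem", ("simulate", "traits", "sem"))


if __name__ == "__main__":
    cli()
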