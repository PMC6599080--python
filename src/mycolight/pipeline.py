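"""End-to-end orchestration: simulate (or ingest), assemble, model, report.

A pipeline run sequences the full analysis: synthetic world (or user
tables) -> color aggregation -> gridding and filters -> climate PCA ->
assemblage CWM + null-model SES -> additive / mixed models -> phylogenetic
signal and regression.  The run is deterministic given the master seed;
every stage writes plain CSV/JSON/Newick artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate, color, grid, models, nulls, phylo, synthetic
from .synthetic import SimulationConfig

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline",
           "thermal_recovery_run"]

_DEFAULTS = dict(
    cell_size=50_000.0,
    min_occurrences=25,
    n_randomizations=100,
    n_swaps=1000,
    null_models=["independent_swap"],
    run_ses=True,
    run_gam=True,
    run_lmm=True,
    run_phylo=True,
    gam_spline_k=8,
    gam_spatial_k=40,
    niche_min_cells=10,
    seed=0,
    out_dir=None,
)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cell_size: float = 50_000.0
    min_occurrences: int = 25
    n_randomizations: int = 100
    n_swaps: int = 1000
    null_models: list = field(default_factory=lambda: ["independent_swap"])
    run_ses: bool = True
    run_gam: bool = True
    run_lmm: bool = True
    run_phylo: bool = True
    gam_spline_k: int = 8
    gam_spatial_k: int = 40
    niche_min_cells: int = 10
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.min_occurrences < 0 or self.n_randomizations < 1 or self.n_swaps < 0:
            raise ValueError("thresholds/counts out of range")
        bad = [m for m in self.null_models if m not in nulls.NULL_MODELS]
        if bad:
            raise ValueError(f"unknown null models {bad}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = asdict(self.simulation)
        return d


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected, defaults filled."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = set(_DEFAULTS) | {"simulation"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    sim_raw = raw.get("simulation", {}) or {}
    sim_known = set(SimulationConfig.__dataclass_fields__)
    sim_unknown = sorted(set(sim_raw) - sim_known)
    if sim_unknown:
        raise ValueError(f"unknown simulation keys: {sim_unknown}")
    if "year_range" in sim_raw:
        sim_raw["year_range"] = tuple(sim_raw["year_range"])
    sim = SimulationConfig(**sim_raw)
    kwargs = {k: raw.get(k, v) for k, v in _DEFAULTS.items()}
    return PipelineConfig(simulation=sim, **kwargs)


def dump_config(config: PipelineConfig, path) -> None:
    d = config.to_dict()
    d["simulation"]["year_range"] = list(d["simulation"]["year_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def thermal_recovery_run(seed: int, *, filtering_strength: float = 0.5,
                         n_species: int = 150, n_cells: int = 150,
                         min_occurrences: int = 25, spline_k: int = 8,
                         spatial_k: int = 25) -> dict:
    """One seeded world -> all-species assemblage GAM thermal test.

    The minimal end-to-end recovery experiment: simulate a world with the
    given filtering strength, recover species lightness from the hex
    samples, grid the occurrences, reduce climate to components, fit the
    full additive model on the all-species CWM, and report the thermal
    component 1 F test and partial slope.
    """
    sim = SimulationConfig(n_species=n_species, n_cells=n_cells,
                           filtering_strength=filtering_strength, seed=seed)
    world = synthetic.build_world(sim)
    traits = color.aggregate_color_table(world.color_samples)["lightness_mean"]
    gridded = grid.assign_to_grid(world.occurrences, sim.cell_size)
    matrices = grid.build_community_matrix(gridded, by_month=True, binary=True)
    pooled = grid.apply_filters(matrices["all"],
                                min_occurrences=min_occurrences)
    kept = set(pooled.cells)
    env = world.environment.copy()
    env["cell_id"] = grid.assign_to_grid(env, sim.cell_size)["cell_id"]
    env = env[env["cell_id"].isin(kept)]
    frames = []
    for m, cm in matrices.items():
        if m == "all":
            continue
        sub = grid.CommunityMatrix(
            cm.values.loc[[c for c in cm.cells if c in kept]], month=m,
            binary=True)
        frames.append(grid.assemblage_lightness(sub, traits))
    assemblages = pd.concat(frames)
    temp_wide = env.pivot_table(index="cell_id", columns="month",
                                values="temp_C")
    prec_wide = env.pivot_table(index="cell_id", columns="month",
                                values="precip_mm")
    thermal = climate.pca_block(pd.DataFrame({
        "temp_annual_mean": temp_wide.mean(axis=1),
        "temp_seasonality": temp_wide.std(axis=1),
        "temp_max_warmest": temp_wide.max(axis=1),
        "temp_min_coldest": temp_wide.min(axis=1)}), 2, prefix="thermal_comp")
    precip = climate.pca_block(pd.DataFrame({
        "precip_annual_sum": prec_wide.sum(axis=1),
        "precip_seasonality": prec_wide.std(axis=1),
        "precip_wettest": prec_wide.max(axis=1),
        "precip_driest": prec_wide.min(axis=1)}), 2, prefix="precip_comp")
    per_cell = env.groupby("cell_id")[
        ["lat", "lon", "uv_index", "forest_frac"]].first()
    per_cell = per_cell.join(thermal.scores).join(precip.scores).reset_index()
    fit = models.fit_lightness_gam(assemblages, per_cell,
                                   response="cwm_lightness", k=spline_k,
                                   spatial_k=spatial_k)
    F, p = fit.term_test("thermal_comp1")
    return {"seed": seed, "beta": filtering_strength, "F": F, "p": p,
            "slope": fit.partial_slope("thermal_comp1"),
            "adj_r2": fit.adj_r2, "n_obs": len(fit.data),
            "n_cells_kept": len(kept)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic world; returns the consolidated report.

    With ``config.out_dir`` set, all stage artifacts (CSV/TSV/Newick) and
    the report JSON are written there.
    """
    t0 = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(config.to_dict()), "stages": {}}

    # -- stage 1: synthetic world -----------------------------------------
    sim = config.simulation
    sim.seed = config.seed if sim.seed == 0 else sim.seed
    world = synthetic.build_world(sim)
    report["stages"]["simulate"] = {
        "n_species": len(world.trait_table), "n_cells": sim.n_cells,
        "n_occurrences": len(world.occurrences),
        "clip_fraction": world.clip_fraction, "seed": sim.seed,
    }
    if out:
        world.write(out / "world")

    # -- stage 2: color aggregation ---------------------------------------
    traits = color.aggregate_color_table(world.color_samples)
    recovered = traits["lightness_mean"]
    corr_true = float(np.corrcoef(recovered.loc[world.trait_table.index],
                                  world.trait_table)[0, 1])
    report["stages"]["colors"] = {
        "n_species": len(traits),
        "lightness_mean": float(recovered.mean()),
        "lightness_range": [float(recovered.min()), float(recovered.max())],
        "corr_with_truth": corr_true,
    }
    if out:
        color.write_species_records_csv(traits, out / "species_colors.csv")

    # -- stage 3: gridding, filters, CWM ----------------------------------
    gridded = grid.assign_to_grid(world.occurrences, config.cell_size)
    matrices = grid.build_community_matrix(gridded, by_month=True, binary=True,
                                           mode_partition=world.mode_table)
    # the cell filter applies per nutritional mode: each mode keeps its own
    # set of sufficiently sampled cells
    kept_by_mode: dict[str, set] = {}
    for mode in (synthetic.SAPROTROPH, synthetic.ECM):
        sub = matrices["all"].subset_mode(mode)
        kept_by_mode[mode] = set(grid.apply_filters(
            sub, min_occurrences=config.min_occurrences).cells)
    kept_union = sorted(set().union(*kept_by_mode.values()))
    env = world.environment.copy()
    env["cell_id"] = grid.assign_to_grid(env, config.cell_size)["cell_id"]
    env = env[env["cell_id"].isin(kept_union)]
    monthly_by_mode: dict[str, dict] = {}
    assemb_frames = []
    for mode in (synthetic.SAPROTROPH, synthetic.ECM):
        monthly_by_mode[mode] = {}
        for m, cm in matrices.items():
            if m == "all":
                continue
            sub = cm.subset_mode(mode)
            cells = [c for c in sub.cells if c in kept_by_mode[mode]]
            sub = grid.CommunityMatrix(sub.values.loc[cells], month=m,
                                       binary=True,
                                       mode_partition=sub.mode_partition)
            monthly_by_mode[mode][m] = sub
            a = grid.assemblage_lightness(sub, recovered, weighting="presence")
            a["mode"] = mode
            assemb_frames.append(a)
    assemblages = pd.concat(assemb_frames)
    pooled_union = grid.CommunityMatrix(
        matrices["all"].values.loc[kept_union], month="all", binary=True,
        mode_partition=matrices["all"].mode_partition)
    report["stages"]["assemble"] = {
        "n_cells_total": len(matrices["all"].cells),
        "n_cells_kept": {m: len(c) for m, c in kept_by_mode.items()},
        "n_cell_months": int(assemblages["cwm_lightness"].notna().sum()),
    }
    if out:
        assemblages.to_csv(out / "assemblages.csv")
        pooled_union.to_triplets().to_csv(out / "community_matrix.csv",
                                          index=False)

    # -- stage 4: climate reduction ---------------------------------------
    temp_wide = env.pivot_table(index="cell_id", columns="month",
                                values="temp_C")
    temp_block = pd.DataFrame({
        "temp_annual_mean": temp_wide.mean(axis=1),
        "temp_seasonality": temp_wide.std(axis=1),
        "temp_max_warmest": temp_wide.max(axis=1),
        "temp_min_coldest": temp_wide.min(axis=1),
    })
    prec_wide = env.pivot_table(index="cell_id", columns="month",
                                values="precip_mm")
    prec_block = pd.DataFrame({
        "precip_annual_sum": prec_wide.sum(axis=1),
        "precip_seasonality": prec_wide.std(axis=1),
        "precip_wettest": prec_wide.max(axis=1),
        "precip_driest": prec_wide.min(axis=1),
    })
    thermal = climate.pca_block(temp_block, 2, prefix="thermal_comp")
    precip = climate.pca_block(prec_block, 2, prefix="precip_comp")
    per_cell_env = env.groupby("cell_id")[
        ["lat", "lon", "uv_index", "forest_frac"]].first()
    per_cell_env = per_cell_env.join(thermal.scores).join(precip.scores)
    screen = climate.collinearity_screen(per_cell_env[
        ["thermal_comp1", "thermal_comp2", "precip_comp1", "precip_comp2",
         "uv_index", "forest_frac"]])
    report["stages"]["climate"] = {
        "thermal_labels": thermal.component_labels,
        "precip_labels": precip.component_labels,
        "thermal_variance": _jsonable(thermal.variance_explained.to_dict()),
        "flagged_pairs": [(a, b, round(r, 3)) for a, b, r in screen["flagged_pairs"]],
    }
    env_for_models = per_cell_env.reset_index()
    if out:
        per_cell_env.to_csv(out / "cell_environment.csv")

    # -- stage 5: null models / SES ---------------------------------------
    rng = np.random.default_rng(config.seed + 1)
    ses_tables = {}
    if config.run_ses:
        for nm in config.null_models:
            frames = []
            for mode in (synthetic.SAPROTROPH, synthetic.ECM):
                for m, sub in monthly_by_mode[mode].items():
                    tab = nulls.compute_ses(
                        sub, recovered, null_model=nm,
                        n_randomizations=config.n_randomizations,
                        n_swaps=config.n_swaps,
                        seed=int(rng.integers(0, 2 ** 31 - 1)))
                    tab["mode"] = mode
                    frames.append(tab)
            ses_tables[nm] = pd.concat(frames)
            if out:
                ses_tables[nm].to_csv(out / f"ses_{nm}.csv")
        report["stages"]["ses"] = {
            nm: {"ses_mean": float(t["ses"].mean()),
                 "ses_sd": float(t["ses"].std()),
                 "n": int(t["ses"].notna().sum())}
            for nm, t in ses_tables.items()}

    # -- stage 6: trait-environment models --------------------------------
    if config.run_gam:
        gam_summary = {}
        for mode in (synthetic.SAPROTROPH, synthetic.ECM):
            sub = assemblages[assemblages["mode"] == mode]
            fit = models.fit_lightness_gam(
                sub, env_for_models, response="cwm_lightness",
                k=config.gam_spline_k, spatial_k=config.gam_spatial_k)
            F, p = fit.term_test("thermal_comp1")
            gam_summary[mode] = {
                "thermal_comp1_F": F, "thermal_comp1_p": p,
                "thermal_comp1_slope": fit.partial_slope("thermal_comp1"),
                "adj_r2": fit.adj_r2,
                "terms": _jsonable(fit.terms.reset_index().to_dict("records")),
            }
            if out:
                fit.terms.to_csv(out / f"gam_terms_{mode}.csv")
                fit.partial_effect("thermal_comp1").to_csv(
                    out / f"gam_partial_thermal1_{mode}.csv", index=False)
        report["stages"]["gam"] = gam_summary

    if config.run_lmm:
        lmm = models.fit_mode_lmm(assemblages)
        report["stages"]["lmm"] = _jsonable(asdict(lmm))

    # -- stage 7: phylogenetic comparative --------------------------------
    if config.run_phylo:
        sig = phylo.phylo_signal(world.phylogeny, world.trait_table,
                                 index="lambda", n_randomizations=99,
                                 seed=config.seed + 2)
        mode_bin = (world.mode_table == synthetic.ECM).astype(float)
        reg = phylo.phylo_regression(world.phylogeny, world.trait_table,
                                     pd.DataFrame({"is_ecm": mode_bin}),
                                     evolution_model="lambda")
        niche = phylo.species_niche_positions(
            pooled_union, per_cell_env.reset_index(),
            min_cells=config.niche_min_cells)
        report["stages"]["phylo"] = {
            "lambda": sig.statistic, "lambda_p": sig.p_value,
            "mode_effect_z": float(reg.coef.loc["is_ecm", "z"]),
            "mode_effect": float(reg.coef.loc["is_ecm", "estimate"]),
            "aic": reg.aic,
            "n_niche_species": len(niche),
        }
        if out:
            niche.to_csv(out / "niche_positions.csv")

    report["elapsed_s"] = round(time.time() - t0, 2)
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
    return report
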