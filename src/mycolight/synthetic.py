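"""Synthetic worlds with the statistical structure of a thermal-filtering study.

The generator builds everything the downstream pipeline consumes: a
birth-death phylogeny, a bounded lightness trait evolved on it (BM / OU /
Pagel's lambda), phylogenetically clustered nutritional modes, a monthly
latitude-driven climate grid, occupancy records whose logit couples species
lightness to cell temperature with strength ``filtering_strength``, and raw
nine-point hex color samples per species.

The coupling model is the generative inverse of the thermal-melanism
filtering hypothesis: with logit(p) = baseline + beta * z(L) * z(T), a
positive beta favors light species in warm cells, hence darker assemblages
in cold cells.  beta = 0 switches the filter off and is the null world used
for type-I calibration.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.linalg import cholesky
from scipy.special import expit

from .color import hsl_to_hex
from .trees import Phylogeny

__all__ = [
    "SimulationConfig",
    "SyntheticWorld",
    "simulate_phylogeny",
    "simulate_trait",
    "simulate_modes",
    "simulate_climate_grid",
    "simulate_occurrences",
    "simulate_color_samples",
    "build_world",
]

SAPROTROPH = "saprotrophic"
ECM = "ectomycorrhizal"


@dataclass
class SimulationConfig:
    """All knobs of a synthetic world; defaults are the study conditions."""

    n_species: int = 300
    birth_rate: float = 1.0          # per lineage per My
    death_rate: float = 0.0
    trait_model: str = "BM"          # BM | OU | lambda
    trait_root: float = 58.0         # species lightness mean of the study system
    trait_sigma2: float = 80.0       # per-My BM rate on the 0-100 lightness scale
    trait_alpha: float = 1.0         # OU attraction strength
    trait_lambda: float = 1.0        # Pagel's lambda transform
    mode_transition_rate: float = 0.3
    n_cells: int = 300
    lat_range: float = 20.0          # degrees spanned by the grid
    lat_min: float = 45.0
    base_temp: float = 14.0          # deg C at the southern edge, July
    lapse: float = 0.7               # deg C per degree latitude
    seasonal_amplitude: float = 9.0  # deg C peak-to-mean seasonal swing
    climate_noise_sd: float = 1.0
    filtering_strength: float = 0.5  # beta in the occupancy logit
    baseline_logit: float = -1.5     # mean occupancy ~ 0.18 per species-cell-month
    n_color_points: int = 9
    color_noise_sd: float = 5.0      # lightness units per pipette sample
    cell_size: float = 50_000.0      # meters
    year_range: tuple[int, int] = (1970, 2010)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_color_points < 1:
            raise ValueError("n_color_points must be >= 1")
        for name in ("birth_rate", "death_rate", "mode_transition_rate",
                     "trait_sigma2", "trait_alpha", "color_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.trait_lambda <= 1.0:
            raise ValueError("trait_lambda must be in [0, 1]")
        if self.trait_model not in ("BM", "OU", "lambda"):
            raise ValueError(f"unknown trait_model {self.trait_model!r}")


@dataclass
class SyntheticWorld:
    """One realized world: tree, traits, modes, climate, occurrences, colors."""

    config: SimulationConfig
    phylogeny: Phylogeny
    trait_table: pd.Series        # species -> true lightness in [0, 100]
    mode_table: pd.Series         # species -> saprotrophic | ectomycorrhizal
    environment: pd.DataFrame     # long: cell_id, lat, lon, x_m, y_m, month, temp_C, ...
    occurrences: pd.DataFrame     # species_id, x_m, y_m, year, month, count
    color_samples: pd.DataFrame   # species_id, image_id, hex
    clip_fraction: float = 0.0    # share of trait values clipped into [0, 100]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.phylogeny.write_newick(out / "tree.nwk")
        self.trait_table.rename("lightness").to_csv(out / "true_traits.csv",
                                                    index_label="species_id")
        self.mode_table.rename("mode").to_csv(out / "modes.csv",
                                              index_label="species_id")
        self.environment.to_csv(out / "environment.csv", index=False)
        self.occurrences.to_csv(out / "occurrences.tsv", sep="\t", index=False)
        self.color_samples.to_csv(out / "color_samples.csv", index=False)


def _stage_seeds(master_seed: int, n: int = 6) -> list[int]:
    """Deterministically derive per-stage integer seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31 - 1) for s in ss.generate_state(n)]


def simulate_phylogeny(n_tips: int, birth_rate: float, death_rate: float,
                       seed: int, max_retries: int = 100) -> Phylogeny:
    """Ultrametric binary birth-death tree with exactly ``n_tips`` extant tips.

    The process is stopped at the birth of the n-th extant lineage; every
    terminal edge is then extended by an Exp(n_tips * birth_rate) waiting
    time so that all branch lengths are strictly positive.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > death_rate or death_rate < 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = random.Random(seed)
    tree = None
    for _ in range(max_retries):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth_rate, death_rate=death_rate,
                num_extant_tips=n_tips, rng=rng,
                is_retain_extinct_tips=False)
            break
        except Exception:
            continue
    if tree is None:
        raise RuntimeError(
            f"birth-death simulation failed after {max_retries} retries "
            f"(birth={birth_rate}, death={death_rate})")
    tail = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + tail
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:04d}"
    return Phylogeny(tree)


def _model_vcv(phy: Phylogeny, trait_model: str, sigma2: float,
               alpha: float, lam: float) -> np.ndarray:
    """Trait covariance among tips implied by the evolutionary model."""
    if trait_model == "BM":
        return sigma2 * phy.vcv()
    if trait_model == "lambda":
        v = phy.vcv().copy()
        off = ~np.eye(len(v), dtype=bool)
        v[off] *= lam
        return sigma2 * v
    if trait_model == "OU":
        # stationary OU with random root: cov = sigma2/(2 alpha) exp(-alpha d)
        d = phy.patristic_matrix()
        if alpha <= 0:
            return sigma2 * phy.vcv()
        return sigma2 / (2.0 * alpha) * np.exp(-alpha * d)
    raise ValueError(f"unknown trait model {trait_model!r}")


def simulate_trait(phylogeny: Phylogeny, trait_model: str = "BM", *,
                   root: float = 58.0, sigma2: float = 80.0, alpha: float = 1.0,
                   lam: float = 1.0, bounds: tuple[float, float] = (0.0, 100.0),
                   seed: int = 0) -> tuple[pd.Series, float]:
    """Evolve a continuous trait on the tree; returns (values, clip_fraction).

    The trait is drawn from the multivariate normal implied by the model
    (mean = root state) and clipped into ``bounds``; the fraction of tips
    that hit a bound is returned so heavy clipping can be detected.
    """
    if sigma2 < 0 or alpha < 0 or not 0 <= lam <= 1:
        raise ValueError("invalid trait parameters")
    rng = np.random.default_rng(seed)
    n = len(phylogeny)
    if sigma2 == 0:
        vals = np.full(n, float(root))
    else:
        v = _model_vcv(phylogeny, trait_model, sigma2, alpha, lam)
        # jitter for numerical PD on lambda < 1 trees with tiny branches
        L = cholesky(v + 1e-10 * np.eye(n), lower=True)
        vals = root + L @ rng.standard_normal(n)
    lo, hi = bounds
    clipped = np.clip(vals, lo, hi)
    clip_fraction = float(np.mean(clipped != vals))
    return pd.Series(clipped, index=phylogeny.tips, name="lightness"), clip_fraction


def simulate_modes(phylogeny: Phylogeny, mode_transition_rate: float,
                   seed: int = 0) -> pd.Series:
    """Two-state symmetric Markov walk (saprotroph <-> ECM) down the tree.

    The probability of ending a branch of length t in the other state is
    (1 - exp(-2 r t)) / 2; the root state is a fair coin flip.
    """
    if mode_transition_rate < 0:
        raise ValueError("mode_transition_rate must be >= 0")
    rng = np.random.default_rng(seed)
    tree = phylogeny.dendropy_tree
    states: dict[int, int] = {}
    root = tree.seed_node
    states[id(root)] = int(rng.integers(2))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        p_flip = 0.5 * (1.0 - np.exp(-2.0 * mode_transition_rate * t))
        parent_state = states[id(node.parent_node)]
        states[id(node)] = parent_state ^ int(rng.random() < p_flip)
    out = {leaf.taxon.label: (ECM if states[id(leaf)] else SAPROTROPH)
           for leaf in tree.leaf_node_iter()}
    return pd.Series(out, name="mode").loc[phylogeny.tips]


def simulate_climate_grid(n_cells: int, *, lat_range: float = 20.0,
                          lat_min: float = 45.0, base_temp: float = 14.0,
                          lapse: float = 0.7, seasonal_amplitude: float = 9.0,
                          noise_sd: float = 1.0, cell_size: float = 50_000.0,
                          seed: int = 0) -> pd.DataFrame:
    """Monthly climate over a planar grid of ``n_cells`` 50-km cells.

    temperature(cell, month) = base - lapse * (lat - lat_min)
                               + amplitude * cos(2 pi (month - 7) / 12) + noise.
    Precipitation increases with latitude and peaks in winter; UV decreases
    with latitude; forest cover is a smooth logistic field.  Cell-level
    (month-invariant) noise uses one draw per cell so monthly means stay
    interpretable.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n_col = max(1, int(np.ceil(np.sqrt(n_cells))))
    rows, cols = np.divmod(np.arange(n_cells), n_col)
    n_row = rows.max() + 1
    lat = lat_min + lat_range * (rows + 0.5) / n_row
    lon = 5.0 + 10.0 * (cols + 0.5) / n_col
    x_m = (cols + 0.5) * cell_size
    y_m = (rows + 0.5) * cell_size
    uv = 8.0 - 0.15 * (lat - lat_min) + rng.normal(0, 0.2, n_cells)
    forest = expit(rng.normal(0.5, 1.0, n_cells))
    frames = []
    for month in range(1, 13):
        season = np.cos(2.0 * np.pi * (month - 7) / 12.0)
        temp = (base_temp - lapse * (lat - lat_min) + seasonal_amplitude * season
                + (rng.normal(0, noise_sd, n_cells) if noise_sd > 0 else 0.0))
        precip = np.maximum(
            0.0, 60.0 + 2.0 * (lat - lat_min) - 15.0 * season
            + (rng.normal(0, 5.0, n_cells) if noise_sd > 0 else 0.0))
        frames.append(pd.DataFrame({
            "cell_id": [f"c{i:04d}" for i in range(n_cells)],
            "lat": lat, "lon": lon, "x_m": x_m, "y_m": y_m, "month": month,
            "temp_C": temp, "precip_mm": precip, "uv_index": uv,
            "forest_frac": forest,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_occurrences(trait_table: pd.Series, mode_table: pd.Series,
                         environment: pd.DataFrame, *,
                         filtering_strength: float = 0.5,
                         baseline_logit: float = -1.5,
                         year_range: tuple[int, int] = (1970, 2010),
                         seed: int = 0) -> pd.DataFrame:
    """Bernoulli occupancy for every species x cell x month.

    logit(p) = baseline + beta * z(lightness) * z(temperature), with z the
    standardization over species (lightness) and over cell-months
    (temperature).  Present records get a uniform year within ``year_range``
    and count 1.
    """
    missing = set(trait_table.index) ^ set(mode_table.index)
    if missing:
        raise ValueError(f"traits and modes disagree on species: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    species = trait_table.index.to_numpy()
    zl = (trait_table.to_numpy() - trait_table.mean()) / (trait_table.std(ddof=0) or 1.0)
    temp = environment["temp_C"].to_numpy()
    zt = (temp - temp.mean()) / (temp.std(ddof=0) or 1.0)
    # p matrix: cell-months x species
    logit = baseline_logit + filtering_strength * np.outer(zt, zl)
    p = expit(logit)
    present = rng.random(p.shape) < p
    cm_idx, sp_idx = np.nonzero(present)
    env = environment.reset_index(drop=True)
    years = rng.integers(year_range[0], year_range[1] + 1, size=cm_idx.size)
    return pd.DataFrame({
        "species_id": species[sp_idx],
        "x_m": env["x_m"].to_numpy()[cm_idx],
        "y_m": env["y_m"].to_numpy()[cm_idx],
        "year": years,
        "month": env["month"].to_numpy()[cm_idx],
        "count": np.ones(cm_idx.size, dtype=int),
    })


def simulate_color_samples(trait_table: pd.Series, n_points: int = 9,
                           color_noise_sd: float = 5.0,
                           seed: int = 0) -> pd.DataFrame:
    """Nine-point cap samples per species as hex strings.

    Sample lightness = true trait + N(0, noise_sd), clipped to [0, 100];
    hue uniform on [0, 360), saturation uniform on [20, 80] (chromatic
    caps), both independent of lightness.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sp, true_l in trait_table.items():
        light = np.clip(true_l + rng.normal(0, color_noise_sd, n_points), 0, 100)
        hue = rng.uniform(0, 360, n_points)
        sat = rng.uniform(20, 80, n_points)
        for k in range(n_points):
            rows.append({"species_id": sp, "image_id": f"{sp}_img1",
                         "hex": hsl_to_hex(hue[k], sat[k], light[k])})
    return pd.DataFrame(rows)


def build_world(config: SimulationConfig) -> SyntheticWorld:
    """Run every generator stage with seeds derived from the master seed."""
    s_tree, s_trait, s_mode, s_clim, s_occ, s_col = _stage_seeds(config.seed)
    phy = simulate_phylogeny(config.n_species, config.birth_rate,
                             config.death_rate, seed=s_tree)
    # rescale to unit depth so trait_sigma2 is on a fixed scale
    depth = phy.depth()
    for edge in phy.dendropy_tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    traits, clip_frac = simulate_trait(
        phy, config.trait_model, root=config.trait_root,
        sigma2=config.trait_sigma2, alpha=config.trait_alpha,
        lam=config.trait_lambda, seed=s_trait)
    modes = simulate_modes(phy, config.mode_transition_rate, seed=s_mode)
    env = simulate_climate_grid(
        config.n_cells, lat_range=config.lat_range, lat_min=config.lat_min,
        base_temp=config.base_temp, lapse=config.lapse,
        seasonal_amplitude=config.seasonal_amplitude,
        noise_sd=config.climate_noise_sd, cell_size=config.cell_size,
        seed=s_clim)
    occ = simulate_occurrences(
        traits, modes, env, filtering_strength=config.filtering_strength,
        baseline_logit=config.baseline_logit, year_range=config.year_range,
        seed=s_occ)
    colors = simulate_color_samples(traits, config.n_color_points,
                                    config.color_noise_sd, seed=s_col)
    return SyntheticWorld(config=config, phylogeny=phy, trait_table=traits,
                          mode_table=modes, environment=env, occurrences=occ,
                          color_samples=colors, clip_fraction=clip_frac)
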