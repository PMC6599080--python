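"""Synthetic-world generator: trees, traits, modes, climate, occupancy."""

import numpy as np
import pandas as pd
import pytest

from mycolight.color import hex_to_hsl
from mycolight.synthetic import (SimulationConfig, build_world,
                                 simulate_climate_grid, simulate_color_samples,
                                 simulate_modes, simulate_occurrences,
                                 simulate_phylogeny, simulate_trait)


# ---------------------------------------------------------------------------
# phylogeny simulation
# ---------------------------------------------------------------------------

def gillespie_pure_birth_depth(n_tips: int, birth: float,
                               rng: np.random.Generator) -> float:
    """Naive event-by-event Yule simulation, independent of dendropy.

    Tracks only the lineage count; returns the tree depth under the same
    convention as the implementation: the process starts from the two
    daughters of the root, stops at the birth of the n-th lineage, and adds
    an Exp(n * birth) tail.
    """
    t, k = 0.0, 2
    while k < n_tips:
        t += rng.exponential(1.0 / (k * birth))
        k += 1
    return t + rng.exponential(1.0 / (n_tips * birth))


def test_two_tip_tree_is_ultrametric():
    phy = simulate_phylogeny(2, 1.0, 0.0, seed=3)
    d = phy.root_to_tip_depths()
    assert len(phy) == 2
    assert d[0] == pytest.approx(d[1], rel=1e-9)


def test_binary_tree_node_count():
    phy = simulate_phylogeny(128, 1.0, 0.0, seed=1)
    assert len(phy) == 128
    assert phy.n_internal == 127
    assert phy.is_ultrametric()
    bl = [e.length for e in phy.dendropy_tree.preorder_edge_iter()
          if e.length is not None]
    assert min(bl) > 0


def test_mean_depth_matches_gillespie_oracle():
    n_tips, n_rep = 100, 300
    rng = np.random.default_rng(99)
    oracle = np.array([gillespie_pure_birth_depth(n_tips, 1.0, rng)
                       for _ in range(n_rep)])
    sim = np.array([simulate_phylogeny(n_tips, 1.0, 0.0, seed=10_000 + r).depth()
                    for r in range(n_rep)])
    # both estimate the same expectation; compare within joint Monte-Carlo CI
    se = np.sqrt(oracle.var() / n_rep + sim.var() / n_rep)
    assert abs(sim.mean() - oracle.mean()) < 4 * se


def test_phylogeny_rejects_bad_rates():
    with pytest.raises(ValueError):
        simulate_phylogeny(10, 0.5, 0.5, seed=1)
    with pytest.raises(ValueError):
        simulate_phylogeny(1, 1.0, 0.0, seed=1)


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def test_zero_rate_trait_is_constant(tree64):
    trait, clip = simulate_trait(tree64, "BM", root=58.0, sigma2=0.0, seed=1)
    assert (trait == 58.0).all()
    assert clip == 0.0


def test_bm_two_tip_contrast_variance():
    # var(x1 - x2) = 2 sigma^2 t on a two-tip tree of depth t
    phy = simulate_phylogeny(2, 1.0, 0.0, seed=8)
    t = phy.depth()
    sigma2 = 4.0
    contrasts = np.array([
        np.diff(simulate_trait(phy, "BM", sigma2=sigma2, seed=s,
                               bounds=(-1e9, 1e9))[0].to_numpy())[0]
        for s in range(1000)])
    expected = 2.0 * sigma2 * t
    # chi-square CI on a sampled variance with n=1000
    assert contrasts.var() == pytest.approx(expected, rel=0.2)
    assert abs(contrasts.mean()) < 4 * np.sqrt(expected / 1000)


def test_lambda_zero_trait_recovers_no_signal(tree64):
    from mycolight.phylo import phylo_signal
    trait, _ = simulate_trait(tree64, "lambda", lam=0.0,
                              sigma2=100.0 / tree64.depth(), seed=5,
                              bounds=(-1e9, 1e9))
    res = phylo_signal(tree64, trait, index="lambda", n_randomizations=0,
                       seed=0)
    assert res.statistic < 0.15


def test_trait_bounds_and_clip_logging(tree64):
    trait, clip = simulate_trait(tree64, "BM", root=95.0,
                                 sigma2=500.0 / tree64.depth(), seed=2)
    assert trait.between(0, 100).all()
    assert clip > 0


def test_trait_rejects_unknown_model(tree64):
    with pytest.raises(ValueError):
        simulate_trait(tree64, "EB", seed=1)


# ---------------------------------------------------------------------------
# mode simulation
# ---------------------------------------------------------------------------

def test_zero_transition_rate_single_mode(tree64):
    modes = simulate_modes(tree64, 0.0, seed=4)
    assert modes.nunique() == 1


def test_high_rate_modes_approach_fair_coin(tree64):
    props = [simulate_modes(tree64, 500.0, seed=s).eq("ectomycorrhizal").mean()
             for s in range(60)]
    # stationary distribution is 50/50; SE ~ sqrt(.25/ (60*64))
    assert np.mean(props) == pytest.approx(0.5, abs=0.05)


def test_low_rate_modes_are_phylogenetically_clustered():
    from mycolight.phylo import phylo_signal
    phy = simulate_phylogeny(96, 1.0, 0.0, seed=21)
    for seed in range(10):
        modes = simulate_modes(phy, 0.25 / phy.depth(), seed=seed)
        if modes.nunique() == 2 and 0.2 < modes.eq("ectomycorrhizal").mean() < 0.8:
            break
    else:
        pytest.fail("no balanced mode split found")
    binary = modes.eq("ectomycorrhizal").astype(float)
    res = phylo_signal(phy, binary, index="c_mean", n_randomizations=99, seed=0)
    assert res.p_value <= 0.05


# ---------------------------------------------------------------------------
# climate grid
# ---------------------------------------------------------------------------

def test_noise_free_temperature_decreases_with_latitude():
    env = simulate_climate_grid(100, lapse=0.7, noise_sd=0.0, seed=0)
    july = env[env.month == 7].sort_values("lat")
    assert (np.diff(july.temp_C) <= 1e-9).all()
    assert july.temp_C.is_monotonic_decreasing


def test_no_seasonality_means_flat_months():
    env = simulate_climate_grid(10, seasonal_amplitude=0.0, noise_sd=0.0, seed=0)
    per_cell = env.groupby("cell_id")["temp_C"].nunique()
    assert (per_cell == 1).all()


def test_annual_mean_equals_base_minus_lapse_term():
    env = simulate_climate_grid(30, noise_sd=0.0, base_temp=14.0, lapse=0.7,
                                lat_min=45.0, seed=0)
    per_cell = env.groupby("cell_id").agg(mean_t=("temp_C", "mean"),
                                          lat=("lat", "first"))
    expected = 14.0 - 0.7 * (per_cell.lat - 45.0)
    np.testing.assert_allclose(per_cell.mean_t, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def test_uncoupled_world_has_no_lightness_temperature_correlation():
    rng = np.random.default_rng(0)
    species = [f"s{i}" for i in range(120)]
    traits = pd.Series(rng.uniform(20, 90, 120), index=species)
    modes = pd.Series("saprotrophic", index=species)
    env = simulate_climate_grid(500, noise_sd=0.5, seed=1)
    occ = simulate_occurrences(traits, modes, env, filtering_strength=0.0,
                               seed=2)
    merged = occ.merge(traits.rename("L"), left_on="species_id",
                       right_index=True)
    envkey = env.set_index(["x_m", "y_m", "month"])["temp_C"]
    cell_month = merged.groupby(["x_m", "y_m", "month"])["L"].mean()
    temps = np.array([envkey.loc[k] for k in cell_month.index])
    r = np.corrcoef(cell_month.to_numpy(), temps)[0, 1]
    assert abs(r) < 0.05


def test_coupled_world_darker_when_cold(small_world):
    # beta > 0: assemblage lightness increases with temperature
    occ = small_world.occurrences
    env = small_world.environment
    merged = occ.merge(small_world.trait_table.rename("L"),
                       left_on="species_id", right_index=True)
    envkey = env.set_index(["x_m", "y_m", "month"])["temp_C"]
    cell_month = merged.groupby(["x_m", "y_m", "month"])["L"].mean()
    temps = np.array([envkey.loc[k] for k in cell_month.index])
    assert np.corrcoef(cell_month.to_numpy(), temps)[0, 1] > 0.3


# ---------------------------------------------------------------------------
# color samples
# ---------------------------------------------------------------------------

def test_noise_free_samples_decode_to_truth():
    traits = pd.Series([18.0, 58.0, 86.0], index=["a", "b", "c"])
    samples = simulate_color_samples(traits, n_points=9, color_noise_sd=0.0,
                                     seed=3)
    decoded = samples.assign(L=[hex_to_hsl(h)[2] for h in samples.hex])
    err = decoded.groupby("species_id")["L"].mean() - traits
    assert np.abs(err).max() <= 0.5  # 8-bit quantization bound


def test_recovered_lightness_standard_error():
    # mean |error| of a 9-sample mean with sd=5 is sqrt(2/pi) * 5/3
    rng = np.random.default_rng(1)
    traits = pd.Series(rng.uniform(30, 70, 1000),
                       index=[f"s{i}" for i in range(1000)])
    samples = simulate_color_samples(traits, n_points=9, color_noise_sd=5.0,
                                     seed=4)
    decoded = samples.assign(L=[hex_to_hsl(h)[2] for h in samples.hex])
    rec = decoded.groupby("species_id")["L"].mean()
    mae = np.abs(rec - traits).mean()
    assert mae == pytest.approx(np.sqrt(2 / np.pi) * 5.0 / 3.0, rel=0.1)


# ---------------------------------------------------------------------------
# whole-world invariants
# ---------------------------------------------------------------------------

def test_world_is_deterministic_given_seed():
    cfg = SimulationConfig(n_species=40, n_cells=25, seed=9)
    w1, w2 = build_world(cfg), build_world(cfg)
    pd.testing.assert_series_equal(w1.trait_table, w2.trait_table)
    pd.testing.assert_frame_equal(w1.occurrences, w2.occurrences)
    pd.testing.assert_frame_equal(w1.color_samples, w2.color_samples)
    assert w1.phylogeny.to_newick() == w2.phylogeny.to_newick()


def test_world_species_closed_under_tables(small_world):
    occ_species = set(small_world.occurrences.species_id)
    assert occ_species <= set(small_world.trait_table.index)
    assert occ_species <= set(small_world.mode_table.index)
    assert small_world.trait_table.between(0, 100).all()


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_species=1)
    with pytest.raises(ValueError):
        SimulationConfig(trait_lambda=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(trait_model="white-noise")
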