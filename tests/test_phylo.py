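"""Phylogenetic signal, correlogram, GLS regression, niches, tree perturbation."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

from mycolight.grid import CommunityMatrix
from mycolight.phylo import (_gls_profile, perturb_tree_set, phylo_correlogram,
                             phylo_regression, phylo_signal,
                             species_niche_positions)
from mycolight.synthetic import simulate_phylogeny, simulate_trait
from mycolight.trees import Phylogeny


# ---------------------------------------------------------------------------
# signal
# ---------------------------------------------------------------------------

def test_bm_trait_has_high_lambda_and_k_near_one(tree64, bm_trait64):
    lam = phylo_signal(tree64, bm_trait64, index="lambda",
                       n_randomizations=99, seed=1)
    k = phylo_signal(tree64, bm_trait64, index="K", n_randomizations=99, seed=1)
    assert lam.statistic > 0.8
    assert 0.4 < k.statistic < 2.5
    assert lam.p_value <= 0.05
    assert k.p_value <= 0.05


def test_shuffled_trait_loses_signal(tree64, bm_trait64, rng):
    shuffled = pd.Series(rng.permutation(bm_trait64.to_numpy()),
                         index=bm_trait64.index)
    lam = phylo_signal(tree64, shuffled, index="lambda", n_randomizations=99,
                       seed=2)
    assert lam.statistic < 0.3
    cm = phylo_signal(tree64, shuffled, index="c_mean", n_randomizations=99,
                      seed=2)
    assert cm.p_value > 0.05


def test_signal_invariant_to_tip_order(tree64, bm_trait64, rng):
    reordered = bm_trait64.sample(frac=1.0, random_state=1)
    for index in ("K", "moran_i", "c_mean"):
        a = phylo_signal(tree64, bm_trait64, index=index, n_randomizations=0)
        b = phylo_signal(tree64, reordered, index=index, n_randomizations=0)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_signal_errors(tree64):
    const = pd.Series(1.0, index=tree64.tips)
    with pytest.raises(ValueError, match="constant"):
        phylo_signal(tree64, const, index="K")
    with pytest.raises(ValueError, match="missing"):
        phylo_signal(tree64, const.iloc[:10], index="K")
    with pytest.raises(ValueError, match="unknown index"):
        phylo_signal(tree64, const, index="king")


def test_randomization_p_floor(tree64, bm_trait64):
    res = phylo_signal(tree64, bm_trait64, index="moran_i",
                       n_randomizations=99, seed=3)
    assert res.p_value >= 1.0 / 100.0
    assert res.p_value <= 1.0


# ---------------------------------------------------------------------------
# correlogram
# ---------------------------------------------------------------------------

def test_correlogram_bm_significant_at_short_distance(tree64, bm_trait64):
    res = phylo_correlogram(tree64, bm_trait64, n_classes=8, n_bootstrap=99,
                            seed=4)
    assert res.moran_i[0] > 0
    sig = res.significant_classes()
    assert sig[0]


def test_correlogram_shuffled_mostly_null(tree64, bm_trait64):
    rng = np.random.default_rng(7)
    hits = []
    for rep in range(5):
        shuffled = pd.Series(rng.permutation(bm_trait64.to_numpy()),
                             index=bm_trait64.index)
        res = phylo_correlogram(tree64, shuffled, n_classes=6,
                                n_bootstrap=99, seed=rep)
        hits.append(res.significant_classes().mean())
    assert np.mean(hits) < 0.4


def test_correlogram_two_tip_tree_degenerates_to_global():
    phy = simulate_phylogeny(2, 1.0, 0.0, seed=5)
    trait = pd.Series([1.0, 2.0], index=phy.tips)
    res = phylo_correlogram(phy, trait, n_classes=3, n_bootstrap=19, seed=0)
    assert len(res.moran_i) == 1
    assert res.moran_i[0] == pytest.approx(-1.0)  # global I of a pair


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def brute_force_bm_covariance(tree: Phylogeny) -> np.ndarray:
    """Oracle: shared path length via per-pair MRCA lookup in dendropy."""
    t = tree.dendropy_tree
    t.calc_node_root_distances()
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace}
    n = len(tree.tips)
    V = np.zeros((n, n))
    for i, a in enumerate(tree.tips):
        for j, b in enumerate(tree.tips):
            if i == j:
                leaf = t.find_node_with_taxon_label(a)
                V[i, j] = leaf.root_distance
            else:
                mrca = pdm.mrca(taxa[a], taxa[b])
                V[i, j] = mrca.root_distance
    return V


@pytest.fixture(scope="module")
def regression_data(tree64):
    rng = np.random.default_rng(50)
    x = pd.Series(rng.normal(size=64), index=tree64.tips)
    base, _ = simulate_trait(tree64, "BM", sigma2=30.0 / tree64.depth(),
                             root=0.0, seed=51, bounds=(-1e9, 1e9))
    y = base + 1.5 * x
    return y, pd.DataFrame({"x": x})


def test_bm_regression_matches_gls_oracle(tree64, regression_data):
    y, pred = regression_data
    fit = phylo_regression(tree64, y, pred, evolution_model="BM")
    V = brute_force_bm_covariance(tree64)
    X = np.column_stack([np.ones(64), pred.loc[tree64.tips, "x"]])
    yv = y.loc[tree64.tips].to_numpy()
    beta_oracle = np.linalg.solve(X.T @ np.linalg.solve(V, X),
                                  X.T @ np.linalg.solve(V, yv))
    np.testing.assert_allclose(fit.coef["estimate"].to_numpy(), beta_oracle,
                               rtol=1e-8)


def test_lambda_zero_equals_ols(tree64):
    # a trait with no phylogenetic structure drives lambda-hat to 0
    rng = np.random.default_rng(60)
    x = pd.Series(rng.normal(size=64), index=tree64.tips)
    y = 2.0 + 0.5 * x + pd.Series(rng.normal(size=64), index=tree64.tips)
    fit = phylo_regression(tree64, y, pd.DataFrame({"x": x}),
                           evolution_model="lambda")
    assert fit.model_parameter == pytest.approx(0.0, abs=1e-4)
    ols = np.polyfit(x.loc[tree64.tips], y.loc[tree64.tips], 1)
    assert fit.coef.loc["x", "estimate"] == pytest.approx(ols[0], rel=1e-6)
    assert fit.coef.loc["intercept", "estimate"] == pytest.approx(ols[1],
                                                                  rel=1e-6)


def test_lambda_one_loglik_equals_bm(tree64, regression_data):
    y, pred = regression_data
    yv = y.loc[tree64.tips].to_numpy()
    X = np.column_stack([np.ones(64), pred.loc[tree64.tips, "x"]])
    V = tree64.vcv()
    ll_bm = _gls_profile(yv, X, V)[2]
    lam1 = V.copy()  # lambda = 1 leaves the covariance untouched
    ll_lam1 = _gls_profile(yv, X, lam1)[2]
    assert ll_lam1 == pytest.approx(ll_bm, abs=1e-8)


def test_model_comparison_by_aic(tree64, regression_data):
    y, pred = regression_data
    fits = {m: phylo_regression(tree64, y, pred, evolution_model=m)
            for m in ("BM", "OU", "lambda")}
    for m, f in fits.items():
        assert f.aic == pytest.approx(
            2 * (2 + 1 + (0 if m == "BM" else 1)) - 2 * f.log_likelihood)
    # BM-generated response: BM should not be grossly disfavoured
    assert fits["BM"].aic <= min(f.aic for f in fits.values()) + 10


def test_regression_recovers_slope_and_mode_contrast(tree64):
    # binary predictor with a known shift: z should be clearly significant
    rng = np.random.default_rng(70)
    mode = pd.Series((rng.random(64) < 0.5).astype(float), index=tree64.tips)
    base, _ = simulate_trait(tree64, "BM", sigma2=20.0 / tree64.depth(),
                             root=58.0, seed=71, bounds=(-1e9, 1e9))
    y = base - 8.0 * mode
    fit = phylo_regression(tree64, y, pd.DataFrame({"is_ecm": mode}),
                           evolution_model="lambda")
    assert fit.coef.loc["is_ecm", "estimate"] == pytest.approx(-8.0, abs=2.0)
    assert abs(fit.coef.loc["is_ecm", "z"]) > 3


def test_regression_rejects_rank_deficient(tree64, regression_data):
    y, pred = regression_data
    bad = pred.assign(x2=2.0 * pred["x"])
    with pytest.raises(ValueError, match="rank"):
        phylo_regression(tree64, y, bad)


# ---------------------------------------------------------------------------
# niche positions
# ---------------------------------------------------------------------------

def test_niche_positions_mean_and_threshold():
    vals = pd.DataFrame([[1, 1], [1, 0], [1, 0]],
                        index=["c1", "c2", "c3"], columns=["wide", "narrow"])
    env = pd.DataFrame({"cell_id": ["c1", "c2", "c3"],
                        "temp_C": [5.0, 10.0, 15.0]})
    out = species_niche_positions(CommunityMatrix(vals), env, min_cells=1)
    assert out.loc["wide", "temp_C"] == pytest.approx(10.0)
    assert out.loc["narrow", "temp_C"] == pytest.approx(5.0)
    out10 = species_niche_positions(CommunityMatrix(vals), env, min_cells=3)
    assert list(out10.index) == ["wide"]


# ---------------------------------------------------------------------------
# tree perturbation
# ---------------------------------------------------------------------------

def label_supports(phy: Phylogeny, value: float) -> Phylogeny:
    t = phy.dendropy_tree.clone(depth=1)
    for node in t.preorder_node_iter():
        if not node.is_leaf() and node.parent_node is not None:
            node.label = str(value)
    return Phylogeny(t)


def rf_distance(a: Phylogeny, b: Phylogeny) -> int:
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                           taxon_namespace=tns)
    tb = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                           taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


def test_high_support_trees_are_unchanged():
    phy = simulate_phylogeny(24, 1.0, 0.0, seed=90)
    labelled = label_supports(phy, 95.0)
    out = perturb_tree_set(labelled, support_threshold=80, n_trees=5, seed=0)
    assert len(out) == 5
    for t in out:
        assert rf_distance(labelled, t) == 0


def test_low_support_trees_are_random_resolutions():
    phy = simulate_phylogeny(24, 1.0, 0.0, seed=91)
    labelled = label_supports(phy, 10.0)
    out = perturb_tree_set(labelled, support_threshold=80, n_trees=6, seed=1)
    assert len(out) == 6
    dists = []
    for t in out:
        assert sorted(t.tips) == sorted(phy.tips)
        assert t.n_internal == len(phy) - 1  # binary again
        dists.append(rf_distance(out[0], t))
    assert max(dists) > 0


def test_perturb_requires_supports():
    phy = simulate_phylogeny(8, 1.0, 0.0, seed=92)
    with pytest.raises(ValueError, match="support"):
        perturb_tree_set(phy, n_trees=2)
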