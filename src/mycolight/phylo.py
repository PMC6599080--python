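"""Phylogenetic comparative methods for the color-lightness trait.

Implements the four phylogenetic-signal indices (Pagel's lambda by maximum
likelihood, Blomberg's K, Moran's I on inverse patristic distances,
Abouheif's C_mean on oriented proximities) with tip-label randomization
tests, a Moran's I correlogram over patristic distance classes with
bootstrap confidence bands, generalized least-squares regression under BM /
stationary-OU / lambda covariances with AIC comparison, species
environmental niche positions, and support-based random resolution of
uncertain nodes into alternative tree sets.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .grid import CommunityMatrix
from .trees import Phylogeny

__all__ = [
    "SignalResult",
    "CorrelogramResult",
    "PhyloRegFit",
    "phylo_signal",
    "phylo_correlogram",
    "phylo_regression",
    "species_niche_positions",
    "perturb_tree_set",
]

SIGNAL_INDICES = ("lambda", "K", "moran_i", "c_mean")


@dataclass
class SignalResult:
    index: str
    statistic: float
    p_value: float
    n_randomizations: int
    log_likelihood: float | None = None  # lambda only


@dataclass
class CorrelogramResult:
    distance_classes: np.ndarray   # (n_classes, 2) bin edges
    moran_i: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_pairs: np.ndarray
    n_bootstrap: int
    null_expectation: float

    def significant_classes(self) -> np.ndarray:
        """Classes whose bootstrap CI excludes the null expectation."""
        return ((self.ci_low > self.null_expectation)
                | (self.ci_high < self.null_expectation))


@dataclass
class PhyloRegFit:
    evolution_model: str
    coef: pd.DataFrame             # estimate, se, z, p per predictor
    model_parameter: float | None  # lambda-hat or alpha-hat
    sigma2: float
    log_likelihood: float
    aic: float
    n: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Profile GLS fit: returns (beta, sigma2_ml, loglik, XtVinvX_inv)."""
    n, p = X.shape
    cf = cho_factor(V, lower=True)
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = cho_solve(cf, r)
    quad = float(r @ Vi_r)
    sigma2 = quad / n
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return beta, sigma2, ll, np.linalg.inv(XtViX), quad


def _lambda_vcv(V: np.ndarray, lam: float) -> np.ndarray:
    out = V * lam
    np.fill_diagonal(out, np.diag(V))
    return out


def _pagel_lambda_ml(y: np.ndarray, X: np.ndarray, V: np.ndarray,
                     lam_max: float = 1.0):
    """Maximize the GLS likelihood over the lambda branch-length transform."""

    def nll(lam):
        return -_gls_profile(y, X, _lambda_vcv(V, lam))[2]

    res = optimize.minimize_scalar(nll, bounds=(0.0, lam_max), method="bounded",
                                   options={"xatol": 1e-5})
    lam = float(res.x)
    # snap to a boundary if it is at least as good (bounded opt stays interior)
    for bound in (0.0, lam_max):
        if nll(bound) <= res.fun + 1e-9:
            lam = bound
            break
    return lam, -nll(lam)


def _blomberg_k(y: np.ndarray, V: np.ndarray) -> float:
    n = len(y)
    cf = cho_factor(V, lower=True)
    Vi_y = cho_solve(cf, y)
    Vi_1 = cho_solve(cf, np.ones(n))
    a = float(np.ones(n) @ Vi_y) / float(np.ones(n) @ Vi_1)
    r = y - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(cf, r)) / (n - 1)
    observed = mse0 / mse
    expected = (np.trace(V) - n / float(np.ones(n) @ Vi_1)) / (n - 1)
    return observed / expected


def _moran_i(z: np.ndarray, W: np.ndarray) -> float:
    """Moran's I with raw weight matrix W (diagonal ignored)."""
    n = len(z)
    zc = z - z.mean()
    s0 = W.sum()
    if s0 == 0:
        return float("nan")
    return float(n / s0 * (zc @ W @ zc) / (zc @ zc))


def _inverse_distance_weights(D: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    np.fill_diagonal(W, 0.0)
    W[~np.isfinite(W)] = 0.0
    rs = W.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return W / rs


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

def phylo_signal(tree: Phylogeny, trait, index: str = "lambda",
                 n_randomizations: int = 99, seed: int = 0) -> SignalResult:
    """One phylogenetic-signal index with a tip-randomization test.

    ``index`` is one of lambda | K | moran_i | c_mean.  The p-value is
    one-tailed in the direction of phylogenetic clustering, computed as
    (1 + #{null >= observed}) / (n_randomizations + 1).
    """
    if index not in SIGNAL_INDICES:
        raise ValueError(f"unknown index {index!r}; choose from {SIGNAL_INDICES}")
    y = tree.trait_vector(trait) if not isinstance(trait, np.ndarray) else trait
    if np.ptp(y) == 0:
        raise ValueError("signal undefined: trait is constant across tips")
    rng = np.random.default_rng(seed)
    ll = None
    if index == "lambda":
        V = tree.vcv()
        X = np.ones((len(y), 1))

        def stat_fn(vec):
            return _pagel_lambda_ml(vec, X, V)[0]

        lam, ll = _pagel_lambda_ml(y, X, V)
        obs = lam
    elif index == "K":
        V = tree.vcv()

        def stat_fn(vec):
            return _blomberg_k(vec, V)

        obs = stat_fn(y)
    elif index == "moran_i":
        W = _inverse_distance_weights(tree.patristic_matrix())

        def stat_fn(vec):
            return _moran_i(vec, W)

        obs = stat_fn(y)
    else:  # c_mean
        A = tree.abouheif_proximity()

        def stat_fn(vec):
            return _moran_i(vec, A)

        obs = stat_fn(y)
    null = np.array([stat_fn(rng.permutation(y)) for _ in range(n_randomizations)])
    p = (1.0 + np.sum(null >= obs)) / (n_randomizations + 1.0)
    return SignalResult(index=index, statistic=float(obs), p_value=float(p),
                        n_randomizations=n_randomizations, log_likelihood=ll)


def phylo_correlogram(tree: Phylogeny, trait, n_classes: int = 10,
                      n_bootstrap: int = 99, seed: int = 0) -> CorrelogramResult:
    """Moran's I across patristic-distance classes with bootstrap CI.

    Distance classes are equal-width bins over (0, max patristic distance];
    within each class weights are binary and row-standardized.  The CI per
    class comes from resampling tips with replacement; classes with fewer
    than 2 tip pairs are dropped.
    """
    y = tree.trait_vector(trait) if not isinstance(trait, np.ndarray) else trait
    if np.ptp(y) == 0:
        raise ValueError("signal undefined: trait is constant across tips")
    D = tree.patristic_matrix()
    n = len(y)
    edges = np.linspace(0.0, D.max(), n_classes + 1)
    rng = np.random.default_rng(seed)
    min_pairs = 1 if n <= 2 else 2  # a two-tip tree has one pair, one class

    def class_moran(Dm, vec):
        out = np.full(n_classes, np.nan)
        pairs = np.zeros(n_classes, dtype=int)
        m = len(vec)
        offdiag = ~np.eye(m, dtype=bool)
        for k in range(n_classes):
            lo, hi = edges[k], edges[k + 1]
            mask = (Dm > lo) & (Dm <= hi) & offdiag
            if k == 0:
                mask |= (Dm == 0) & offdiag  # duplicated bootstrap tips
            pairs[k] = int(mask.sum()) // 2
            if pairs[k] < min_pairs:
                continue
            W = mask.astype(float)
            rs = W.sum(axis=1, keepdims=True)
            rs[rs == 0] = 1.0
            out[k] = _moran_i(vec, W / rs)
        return out, pairs

    moran, n_pairs = class_moran(D, y)
    import warnings as _warnings
    boot = np.full((n_bootstrap, n_classes), np.nan)
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            boot[b], _ = class_moran(D[np.ix_(idx, idx)], y[idx])
        ci_low = np.nanpercentile(boot, 2.5, axis=0)
        ci_high = np.nanpercentile(boot, 97.5, axis=0)
    keep = n_pairs >= min_pairs
    classes = np.column_stack([edges[:-1], edges[1:]])
    return CorrelogramResult(
        distance_classes=classes[keep], moran_i=moran[keep],
        ci_low=ci_low[keep], ci_high=ci_high[keep], n_pairs=n_pairs[keep],
        n_bootstrap=n_bootstrap, null_expectation=-1.0 / (n - 1))


# ---------------------------------------------------------------------------
# phylogenetic regression
# ---------------------------------------------------------------------------

def phylo_regression(tree: Phylogeny, response, predictors,
                     evolution_model: str = "lambda") -> PhyloRegFit:
    """GLS regression with a model-implied phylogenetic covariance.

    ``predictors`` is a DataFrame (or dict of per-tip mappings) aligned by
    tip label; an intercept is added.  ``evolution_model`` is BM (fixed
    Brownian covariance), OU (stationary Ornstein-Uhlenbeck with random
    root, alpha profiled by ML) or lambda (Pagel transform, lambda profiled
    by ML).  Standard errors use the unbiased variance estimate; z tests
    are two-tailed.
    """
    if evolution_model not in ("BM", "OU", "lambda"):
        raise ValueError(f"unknown evolution model {evolution_model!r}")
    y = tree.trait_vector(response) if not isinstance(response, np.ndarray) else response
    if isinstance(predictors, pd.DataFrame):
        pred = predictors.loc[tree.tips]
    else:
        pred = pd.DataFrame(predictors).loc[tree.tips]
    X = np.column_stack([np.ones(len(y)), pred.to_numpy(dtype=float)])
    names = ["intercept"] + list(pred.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    n, p = X.shape
    V_bm = tree.vcv()
    extra_par = 0
    param = None
    if evolution_model == "BM":
        V = V_bm
    elif evolution_model == "lambda":
        param, _ = _pagel_lambda_ml(y, X, V_bm)
        V = _lambda_vcv(V_bm, param)
        extra_par = 1
    else:
        D = tree.patristic_matrix()
        depth = tree.depth()
        lo, hi = 1e-4 / depth, 50.0 / depth

        def nll(log_a):
            a = np.exp(log_a)
            Vou = np.exp(-a * D)
            try:
                return -_gls_profile(y, X, Vou)[2]
            except np.linalg.LinAlgError:
                return np.inf

        res = optimize.minimize_scalar(nll, bounds=(np.log(lo), np.log(hi)),
                                       method="bounded")
        param = float(np.exp(res.x))
        if res.x <= np.log(lo) + 1e-6 or res.x >= np.log(hi) - 1e-6:
            import warnings
            warnings.warn("OU alpha estimate at optimization boundary; "
                          "model may be unidentifiable on this tree")
        V = np.exp(-param * D)
        extra_par = 1
    beta, sigma2_ml, ll, XtViX_inv, quad = _gls_profile(y, X, V)
    sigma2_unbiased = quad / (n - p)
    se = np.sqrt(np.diag(XtViX_inv) * sigma2_unbiased)
    z = beta / se
    coef = pd.DataFrame({"estimate": beta, "se": se, "z": z,
                         "p": 2 * stats.norm.sf(np.abs(z))}, index=names)
    k = p + 1 + extra_par
    return PhyloRegFit(evolution_model=evolution_model, coef=coef,
                       model_parameter=param, sigma2=float(sigma2_ml),
                       log_likelihood=float(ll), aic=float(2 * k - 2 * ll), n=n)


# ---------------------------------------------------------------------------
# niche positions and tree perturbation
# ---------------------------------------------------------------------------

def species_niche_positions(matrix: CommunityMatrix, environment: pd.DataFrame,
                            min_cells: int = 10,
                            variables: list[str] | None = None) -> pd.DataFrame:
    """Mean environment over each species' occupied cells.

    ``environment`` is per-cell (cell_id index or column); species occupying
    fewer than ``min_cells`` cells are dropped.  Returns a species-indexed
    frame with the per-variable niche positions and ``n_cells_occupied``.
    """
    env = environment.set_index("cell_id") if "cell_id" in environment.columns \
        else environment
    if variables is None:
        variables = [c for c in env.columns
                     if np.issubdtype(env[c].dtype, np.number) and c != "month"]
    env = env.groupby(level=0)[variables].mean()
    arr = (matrix.values.to_numpy() > 0).astype(float)
    cells = matrix.cells
    aligned = env.reindex(cells)
    occ = arr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        niche = (arr.T @ aligned.to_numpy()) / occ[:, None]
    out = pd.DataFrame(niche, index=matrix.species, columns=variables)
    out["n_cells_occupied"] = occ.astype(int)
    return out[out["n_cells_occupied"] >= min_cells]


def perturb_tree_set(tree: Phylogeny, support_threshold: float = 80.0,
                     n_trees: int = 100, seed: int = 0) -> list[Phylogeny]:
    """Random resolutions of the poorly supported parts of a tree.

    Internal nodes with support below ``support_threshold`` (parsed from
    node labels) are collapsed into polytomies; each returned tree is an
    independent random binary re-resolution (new edges get zero length).
    The tip set is unchanged.
    """
    base = tree.dendropy_tree
    has_support = any(v is not None for v in tree.node_supports())
    if not has_support:
        raise ValueError("tree has no node support values")
    rng = _random.Random(seed)
    out = []
    for _ in range(n_trees):
        t = base.clone(depth=1)
        to_collapse = []
        for node in t.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            try:
                support = float(node.label) if node.label is not None else None
            except ValueError:
                support = None
            if support is not None and support < support_threshold:
                to_collapse.append(node.edge)
        for edge in to_collapse:
            edge.collapse()
        t.resolve_polytomies(rng=rng)
        for edge in t.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
        out.append(Phylogeny(t))
    return out
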