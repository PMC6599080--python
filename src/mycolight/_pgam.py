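"""Penalized additive least-squares engine (internal).

A small Gaussian additive-model fitter in the penalized-regression-spline
tradition: each smooth term contributes a basis block and a quadratic
roughness penalty; smoothing parameters are chosen by minimizing GCV over
log-lambdas; per-term Wald-type approximate F tests use the (Bayesian)
posterior covariance of the penalized coefficients.

Term types
----------
- linear:        one unpenalized column;
- spline:        cubic B-spline basis with a second-difference penalty and
                 a sum-to-zero identifiability constraint absorbed by
                 reparameterization;
- cyclic:        Fourier sine/cosine pairs with a frequency-squared ridge
                 penalty (periodic by construction, December meets January);
- spatial:       low-rank thin-plate radial basis (r^2 log r) over k-means
                 knots plus unpenalized linear coordinates, ridge penalty on
                 the radial coefficients;
- random effect: one ridge-penalized dummy column per factor level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = ["TermSpec", "AdditiveModel", "AdditiveFit"]


# ---------------------------------------------------------------------------
# basis builders
# ---------------------------------------------------------------------------

def _bspline_basis(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Evaluate the full B-spline basis at x for the given interior knots."""
    t = np.concatenate([[knots[0]] * degree, knots, [knots[-1]] * degree])
    n_basis = len(t) - degree - 1
    xc = np.clip(x, knots[0], knots[-1])
    out = np.empty((len(x), n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        out[:, j] = BSpline(t, c, degree, extrapolate=False)(xc)
    return np.nan_to_num(out)


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _sum_to_zero_reparam(colsums: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the row vector ``colsums``."""
    q, _ = np.linalg.qr(colsums[:, None], mode="complete")
    return q[:, 1:]


def _fourier_basis(x: np.ndarray, period: float, n_pairs: int) -> np.ndarray:
    cols = []
    for j in range(1, n_pairs + 1):
        w = 2.0 * np.pi * j * x / period
        cols += [np.sin(w), np.cos(w)]
    return np.column_stack(cols)


def _tps_eta(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _spatial_knots(xy: np.ndarray, k: int, random_state: int = 0) -> np.ndarray:
    uniq = np.unique(xy, axis=0)
    if len(uniq) <= k:
        return uniq
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=k, n_init=4, random_state=random_state)
    km.fit(uniq)
    return km.cluster_centers_


# ---------------------------------------------------------------------------
# term specification
# ---------------------------------------------------------------------------

@dataclass
class TermSpec:
    """One model term: design block, optional penalty, prediction closure."""

    name: str
    kind: str                      # linear | spline | cyclic | spatial | random
    X: np.ndarray                  # n x p block
    S: np.ndarray | None = None    # p x p penalty (None = unpenalized)
    predict: object = None         # callable new_x -> basis block, or None
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def linear_term(name: str, x: np.ndarray) -> TermSpec:
    x = np.asarray(x, dtype=float)
    X = x[:, None] if x.ndim == 1 else x
    return TermSpec(name, "linear", X, None,
                    predict=lambda nx: np.asarray(nx, float).reshape(len(nx), -1))


def spline_term(name: str, x: np.ndarray, k: int = 10) -> TermSpec:
    x = np.asarray(x, dtype=float)
    qs = np.linspace(0, 1, max(4, k - 2))
    knots = np.unique(np.quantile(x, qs))
    if len(knots) < 4:
        raise ValueError(f"spline term {name!r}: too few distinct values")
    B = _bspline_basis(x, knots)
    S = _diff_penalty(B.shape[1])
    Z = _sum_to_zero_reparam(B.sum(axis=0))
    Xb = B @ Z
    Sb = Z.T @ S @ Z

    def predict(nx):
        return _bspline_basis(np.asarray(nx, float), knots) @ Z

    return TermSpec(name, "spline", Xb, Sb, predict, meta={"knots": knots})


def cyclic_term(name: str, x: np.ndarray, period: float = 12.0,
                n_pairs: int = 5) -> TermSpec:
    x = np.asarray(x, dtype=float)
    X = _fourier_basis(x, period, n_pairs)
    pen = np.repeat([float(j * j) for j in range(1, n_pairs + 1)], 2)
    return TermSpec(name, "cyclic", X, np.diag(pen),
                    predict=lambda nx: _fourier_basis(np.asarray(nx, float),
                                                      period, n_pairs))


def spatial_term(name: str, xy: np.ndarray, k: int = 40) -> TermSpec:
    xy = np.asarray(xy, dtype=float)
    lo, span = xy.min(axis=0), np.ptp(xy, axis=0)
    span[span == 0] = 1.0
    scaled = (xy - lo) / span
    knots = _spatial_knots(scaled, k)

    def basis(pts_scaled):
        r = np.linalg.norm(pts_scaled[:, None, :] - knots[None, :, :], axis=2)
        return np.column_stack([pts_scaled - 0.5, _tps_eta(r)])

    X = basis(scaled)
    # the whole block is ridge-penalized, linear plane included: large-scale
    # climatic gradients should load on the named climate covariates, the
    # spatial term only absorbs residual spatial autocorrelation
    S = np.eye(X.shape[1])

    def predict(nxy):
        pts = (np.asarray(nxy, float) - lo) / span
        return basis(pts)

    return TermSpec(name, "spatial", X, S, predict,
                    meta={"knots": knots, "lo": lo, "span": span})


def random_term(name: str, levels) -> TermSpec:
    codes, uniques = pd.factorize(pd.Series(levels), sort=True)
    X = np.zeros((len(codes), len(uniques)))
    X[np.arange(len(codes)), codes] = 1.0
    return TermSpec(name, "random", X, np.eye(len(uniques)),
                    meta={"levels": list(uniques)})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class AdditiveFit:
    terms: list
    beta: np.ndarray
    cov: np.ndarray                # sigma^2 (X'X + S)^-1
    sigma2: float
    edf_total: float
    edf: dict
    fstat: dict                    # term -> (F, df1, df2, p)
    adj_r2: float
    fitted: np.ndarray
    residuals: np.ndarray
    lambdas: dict
    slices: dict
    gcv: float
    n: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            F, df1, df2, p = self.fstat[t.name]
            rows.append({"term": t.name, "kind": t.kind, "edf": self.edf[t.name],
                         "F": F, "p": p})
        return pd.DataFrame(rows).set_index("term")

    def partial_effect(self, name: str, new_x) -> pd.DataFrame:
        """Centered partial effect curve with pointwise +/- 1 SE."""
        term = next(t for t in self.terms if t.name == name)
        if term.predict is None:
            raise ValueError(f"term {name!r} has no prediction basis")
        Xn = term.predict(new_x)
        sl = self.slices[name]
        eff = Xn @ self.beta[sl]
        # center over the training data
        eff = eff - (term.X @ self.beta[sl]).mean()
        se = np.sqrt(np.maximum(0, np.einsum(
            "ij,jk,ik->i", Xn, self.cov[sl, sl], Xn)))
        return pd.DataFrame({"effect": eff, "se": se})

    def linear_coef(self, name: str) -> tuple[float, float]:
        sl = self.slices[name]
        return float(self.beta[sl][0]), float(np.sqrt(self.cov[sl, sl][0, 0]))


class AdditiveModel:
    """Assemble terms, select smoothing parameters by GCV, fit by PLS."""

    def __init__(self, terms: list[TermSpec], include_intercept: bool = True):
        self.terms = terms
        self.include_intercept = include_intercept

    def fit(self, y: np.ndarray, maxiter: int = 300) -> AdditiveFit:
        y = np.asarray(y, dtype=float)
        n = len(y)
        blocks = [np.ones((n, 1))] if self.include_intercept else []
        slices: dict[str, slice] = {}
        start = 1 if self.include_intercept else 0
        for t in self.terms:
            blocks.append(t.X)
            slices[t.name] = slice(start, start + t.p)
            start += t.p
        X = np.column_stack(blocks)
        p = X.shape[1]
        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)
        pen_terms = [t for t in self.terms if t.S is not None]

        def build_A(log_lams: np.ndarray) -> np.ndarray:
            A = XtX.copy()
            for t, ll in zip(pen_terms, log_lams):
                sl = slices[t.name]
                A[sl, sl] += np.exp(np.clip(ll, -30.0, 30.0)) * t.S
            return A

        def solve(log_lams, ridge: float = 1e-8):
            A = build_A(np.asarray(log_lams))
            scale = max(1.0, float(np.mean(np.diag(XtX))))
            for attempt in range(6):
                try:
                    cf = cho_factor(A + ridge * scale * np.eye(p), lower=True)
                    break
                except np.linalg.LinAlgError:
                    ridge *= 100.0
            else:
                raise np.linalg.LinAlgError("penalized system not PD")
            beta = cho_solve(cf, Xty)
            H = cho_solve(cf, XtX)            # A^-1 X'X; edf = trace
            edf = float(np.trace(H))
            rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 1e-12)
            return beta, cf, H, edf, rss

        def gcv(log_lams):
            try:
                _, _, _, edf, rss = solve(log_lams)
            except np.linalg.LinAlgError:
                return 1e300
            denom = max(n - edf, 1e-6)
            return n * rss / denom ** 2

        # balanced initialization: lambda ~ tr(X'X block) / tr(S)
        x0 = []
        for t in pen_terms:
            sl = slices[t.name]
            num = max(np.trace(XtX[sl, sl]), 1e-8)
            x0.append(np.log(num / max(np.trace(t.S), 1e-8)))
        x0 = np.array(x0)
        if len(x0):
            res = optimize.minimize(gcv, x0, method="Powell",
                                    options={"maxiter": maxiter, "xtol": 1e-2,
                                             "ftol": 1e-4})
            log_lams = res.x if np.ndim(res.x) else np.array([res.x])
        else:
            log_lams = np.array([])
        beta, cf, H, edf_total, rss = solve(log_lams)
        sigma2 = rss / max(n - edf_total, 1.0)
        cov = sigma2 * cho_solve(cf, np.eye(p))
        edf = {t.name: float(np.trace(H[slices[t.name], slices[t.name]]))
               for t in self.terms}
        fstat = {}
        for t in self.terms:
            sl = slices[t.name]
            b = beta[sl]
            V = cov[sl, sl]
            r = max(1, int(round(edf[t.name]))) if t.S is not None else t.p
            w, U = np.linalg.eigh(V)
            order = np.argsort(w)[::-1][:r]
            w_r, U_r = w[order], U[:, order]
            keep = w_r > max(w_r.max(), 1e-300) * 1e-10
            w_r, U_r = w_r[keep], U_r[:, keep]
            r_eff = len(w_r)
            if r_eff == 0:
                fstat[t.name] = (0.0, 0, n - edf_total, 1.0)
                continue
            stat = float(((U_r.T @ b) ** 2 / w_r).sum())
            F = stat / r_eff
            df2 = max(n - edf_total, 1.0)
            pval = float(stats.f.sf(F, r_eff, df2))
            fstat[t.name] = (F, r_eff, df2, pval)
        tss = float(((y - y.mean()) ** 2).sum())
        adj_r2 = 1.0 - (rss / max(n - edf_total, 1.0)) / (tss / (n - 1)) if tss > 0 else np.nan
        lambdas = {t.name: float(np.exp(ll)) for t, ll in zip(pen_terms, log_lams)}
        fitted = X @ beta
        return AdditiveFit(terms=self.terms, beta=beta, cov=cov, sigma2=sigma2,
                           edf_total=edf_total, edf=edf, fstat=fstat,
                           adj_r2=float(adj_r2), fitted=fitted,
                           residuals=y - fitted, lambdas=lambdas, slices=slices,
                           gcv=float(n * rss / max(n - edf_total, 1e-6) ** 2), n=n)
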