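"""Trait-environment models for assemblage color lightness.

Four model families mirror the analysis design:

1. an additive model (GAM) of assemblage lightness (CWM or SES) on the two
   thermal and two precipitation components, a cyclic month smooth, linear
   UV / forest-cover / log10-richness terms, a bivariate spatial smooth and
   a per-grid random intercept;
2. a linear mixed model of lightness on nutritional mode with a grid random
   effect;
3. a seasonal-only cyclic smooth for the local weekly-count dataset;
4. an ordinary least-squares contrast of lightness change on temperature
   change between two climate intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._pgam import (AdditiveFit, AdditiveModel, cyclic_term, linear_term,
                    random_term, spatial_term, spline_term)

__all__ = [
    "GamFit",
    "LmmFit",
    "TrendFit",
    "fit_lightness_gam",
    "fit_mode_lmm",
    "seasonal_profile_local",
    "climate_change_trend",
]

GAM_SMOOTH_PREDICTORS = ("thermal_comp1", "thermal_comp2",
                         "precip_comp1", "precip_comp2")
GAM_LINEAR_PREDICTORS = ("uv_index", "forest_frac", "log10_richness")


@dataclass
class GamFit:
    """Per-term F statistics and partial effects of one additive fit."""

    fit: AdditiveFit
    response: str
    data: pd.DataFrame

    @property
    def terms(self) -> pd.DataFrame:
        return self.fit.summary_frame()

    @property
    def adj_r2(self) -> float:
        return self.fit.adj_r2

    def term_test(self, name: str) -> tuple[float, float]:
        """(F, p) of one model term."""
        F, _, _, p = self.fit.fstat[name]
        return F, p

    def partial_effect(self, name: str, n_grid: int = 100) -> pd.DataFrame:
        x = self.data[name].to_numpy()
        grid = np.linspace(x.min(), x.max(), n_grid)
        out = self.fit.partial_effect(name, grid)
        out.insert(0, name, grid)
        return out

    def partial_slope(self, name: str) -> float:
        """Least-squares slope of the partial effect curve (sign summary)."""
        pe = self.partial_effect(name)
        x, y = pe[name].to_numpy(), pe["effect"].to_numpy()
        return float(np.polyfit(x - x.mean(), y, 1)[0])


@dataclass
class LmmFit:
    effect: float          # ECM minus saprotroph fixed effect on lightness
    se: float
    z: float
    p: float
    re_variance: float     # grid random-intercept variance
    resid_variance: float
    n_obs: int
    n_groups: int


@dataclass
class TrendFit:
    slope: float           # lightness change per deg C warming
    intercept: float
    t: float
    p: float
    adj_r2: float
    n_cells: int


def _prepare_gam_frame(assemblages: pd.DataFrame, environment: pd.DataFrame,
                       response: str) -> pd.DataFrame:
    """Join assemblage rows to per-cell environment and derived predictors."""
    env_cols = ["lat", "lon", "uv_index", "forest_frac",
                "thermal_comp1", "thermal_comp2", "precip_comp1", "precip_comp2"]
    per_cell = environment.groupby("cell_id")[
        [c for c in env_cols if c in environment.columns]].first()
    df = assemblages.reset_index().merge(per_cell, on="cell_id", how="inner")
    missing = [c for c in env_cols if c not in df.columns]
    if missing:
        raise ValueError(f"environment lacks predictors {missing}")
    df["log10_richness"] = np.log10(df["species_richness"].clip(lower=1))
    df = df.dropna(subset=[response] + env_cols + ["month"])
    return df


def fit_lightness_gam(assemblages: pd.DataFrame, environment: pd.DataFrame,
                      response: str = "cwm_lightness", *, k: int = 8,
                      spatial_k: int = 40, min_rows: int = 50) -> GamFit:
    """Additive model of assemblage lightness on climate components.

    ``assemblages`` must carry cell_id (index or column), month,
    species_richness and the response column (``cwm_lightness`` or ``ses``);
    ``environment`` the per-cell predictors including the PCA components.
    Smooths: four univariate climate splines, cyclic month, spatial
    (lon, lat); linear: UV, forest cover, log10 richness; ridge random
    intercept per grid cell.
    """
    df = _prepare_gam_frame(assemblages, environment, response)
    if len(df) < min_rows:
        raise ValueError(f"only {len(df)} usable rows; need >= {min_rows}")
    terms = []
    for name in GAM_SMOOTH_PREDICTORS:
        terms.append(spline_term(name, df[name].to_numpy(), k=k))
    terms.append(cyclic_term("month", df["month"].to_numpy()))
    for name in GAM_LINEAR_PREDICTORS:
        terms.append(linear_term(name, df[name].to_numpy()))
    terms.append(spatial_term("space", df[["lon", "lat"]].to_numpy(),
                              k=spatial_k))
    terms.append(random_term("grid", df["cell_id"]))
    fit = AdditiveModel(terms).fit(df[response].to_numpy())
    return GamFit(fit=fit, response=response, data=df)


def fit_mode_lmm(assemblages: pd.DataFrame, response: str = "cwm_lightness",
                 ) -> LmmFit:
    """Mixed model: lightness ~ nutritional mode + (1 | grid cell).

    ``assemblages`` holds rows for both modes with columns cell_id (or
    index), ``mode`` and the response.  The fixed effect is ECM relative to
    saprotroph (negative = ECM darker); inference is a large-sample Wald
    test.
    """
    df = assemblages.reset_index()
    modes = sorted(df["mode"].unique())
    if len(modes) < 2:
        raise ValueError("need both nutritional modes")
    shared = (df.groupby("cell_id")["mode"].nunique() >= 2)
    if int(shared.sum()) < 2:
        raise ValueError("need >= 2 grids holding both modes")
    df = df.dropna(subset=[response])
    df["is_ecm"] = (df["mode"] == "ectomycorrhizal").astype(float)
    model = sm.MixedLM(df[response].to_numpy(),
                       sm.add_constant(df["is_ecm"].to_numpy()),
                       groups=df["cell_id"].to_numpy())
    import warnings
    res = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                # variance components at zero are a legitimate boundary case;
                # we verify the fit ourselves below
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method=method)
            if np.isfinite(res.params).all() and np.isfinite(res.bse[1]):
                break
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
            continue
    if res is None or not np.isfinite(res.bse[1]):
        raise RuntimeError("mixed-model fit did not converge")
    eff = float(res.params[1])
    se = float(res.bse[1])
    z = eff / se
    return LmmFit(effect=eff, se=se, z=z, p=float(2 * stats.norm.sf(abs(z))),
                  re_variance=float(np.asarray(res.cov_re)[0, 0]),
                  resid_variance=float(res.scale),
                  n_obs=int(res.nobs), n_groups=df["cell_id"].nunique())


def seasonal_profile_local(monthly_cwm: pd.DataFrame,
                           response: str = "cwm_lightness") -> GamFit:
    """Cyclic month smooth of local monthly assemblage lightness.

    ``monthly_cwm`` needs columns month and the response; >= 6 distinct
    months are required for the seasonal profile to be identifiable.
    """
    df = monthly_cwm.reset_index().dropna(subset=[response, "month"])
    if df["month"].nunique() < 6:
        raise ValueError(f"only {df['month'].nunique()} distinct months; need >= 6")
    terms = [cyclic_term("month", df["month"].to_numpy())]
    fit = AdditiveModel(terms).fit(df[response].to_numpy())
    return GamFit(fit=fit, response=response, data=df)


def peak_month(seasonal: GamFit) -> int:
    """Month at which the fitted seasonal effect is maximal."""
    grid = np.arange(1, 13)
    eff = seasonal.fit.partial_effect("month", grid)["effect"].to_numpy()
    return int(grid[int(np.argmax(eff))])


def climate_change_trend(cwm_interval1: pd.Series, cwm_interval2: pd.Series,
                         temp_interval1: pd.Series, temp_interval2: pd.Series,
                         ) -> TrendFit:
    """OLS of lightness change on temperature change over common cells.

    Inputs are cell-indexed series for the two climate intervals (e.g.
    1970-1990 vs 1991-2010); only cells present in all four enter.
    """
    common = (cwm_interval1.index.intersection(cwm_interval2.index)
              .intersection(temp_interval1.index)
              .intersection(temp_interval2.index))
    d_cwm = (cwm_interval2.loc[common] - cwm_interval1.loc[common]).astype(float)
    d_temp = (temp_interval2.loc[common] - temp_interval1.loc[common]).astype(float)
    ok = d_cwm.notna() & d_temp.notna()
    d_cwm, d_temp = d_cwm[ok], d_temp[ok]
    if len(d_cwm) < 3:
        raise ValueError(f"only {len(d_cwm)} common cells; need >= 3")
    if float(np.var(d_cwm)) == 0.0:
        return TrendFit(slope=0.0, intercept=float(d_cwm.iloc[0]), t=0.0,
                        p=1.0, adj_r2=float("nan"), n_cells=len(d_cwm))
    fit = sm.OLS(d_cwm.to_numpy(), sm.add_constant(d_temp.to_numpy())).fit()
    return TrendFit(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                    t=float(fit.tvalues[1]), p=float(fit.pvalues[1]),
                    adj_r2=float(fit.rsquared_adj), n_cells=int(fit.nobs))
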