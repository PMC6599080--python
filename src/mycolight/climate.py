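"""Dimension reduction of climate variable blocks and collinearity screening.

Temperature and precipitation variables are reduced separately to two
principal components each.  Variables are standardized first (bioclim-style
blocks mix units), and component signs are fixed so the component tracking
the block's overall mean correlates positively with it — "thermal component
1" then reproducibly means "overall mean temperature", "component 2" its
variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PCAResult", "pca_block", "collinearity_screen"]


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # variable x component
    scores: pd.DataFrame            # cell x component
    variance_explained: pd.Series   # fraction per component
    component_labels: dict[str, str]


def pca_block(env_block: pd.DataFrame, n_components: int = 2,
              prefix: str = "comp") -> PCAResult:
    """Correlation-matrix PCA of one environmental block.

    Requires >= 2 variables, >= 3 rows and no missing values.  Constant
    columns are rejected by name.  Each retained component is sign-fixed to
    correlate non-negatively with the block's row mean (of standardized
    variables); the component most correlated with that mean is labelled
    "overall means", the next "variability".
    """
    if env_block.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    if env_block.shape[0] < 3:
        raise ValueError("need >= 3 rows")
    if env_block.isna().any().any():
        bad = list(env_block.columns[env_block.isna().any()])
        raise ValueError(f"missing values in variables {bad}")
    sd = env_block.std(ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        raise ValueError(f"constant variable column(s): {constant}")
    z = (env_block - env_block.mean()) / sd
    n_components = min(n_components, env_block.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T.copy()  # variable x component, unit columns
    row_mean = z.mean(axis=1).to_numpy()
    corr_with_mean = np.zeros(n_components)
    for k in range(n_components):
        c = _safe_corr(scores[:, k], row_mean)
        sign = 1.0 if (c >= 0 or np.isnan(c)) else -1.0
        if np.isnan(c) or c == 0:
            # degenerate: orient by the largest-loading variable instead
            sign = 1.0 if loadings[np.argmax(np.abs(loadings[:, k])), k] >= 0 else -1.0
        scores[:, k] *= sign
        loadings[:, k] *= sign
        corr_with_mean[k] = abs(c) if np.isfinite(c) else 0.0
    comp_names = [f"{prefix}{k + 1}" for k in range(n_components)]
    order = np.argsort(-corr_with_mean)
    labels = {}
    for rank, k in enumerate(order):
        labels[comp_names[k]] = "overall means" if rank == 0 else "variability"
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=env_block.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=env_block.index, columns=comp_names),
        variance_explained=pd.Series(pca.explained_variance_ratio_, index=comp_names),
        component_labels=labels,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def collinearity_screen(predictors: pd.DataFrame,
                        threshold: float = 0.6) -> dict:
    """Pairwise Pearson screen of model predictors.

    Flags pairs with |r| >= threshold; the retained set (all predictors not
    in any flagged pair) is advisory — the caller decides what to drop.
    Zero-variance predictors get NaN correlations and are flagged as
    undefined.
    """
    if predictors.shape[1] < 2:
        raise ValueError("need >= 2 predictors")
    r = predictors.corr()
    np.fill_diagonal(r.to_numpy(), 1.0)
    undefined = list(predictors.columns[predictors.std(ddof=0) == 0])
    flagged = []
    cols = list(predictors.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rv = r.loc[a, b]
            if np.isfinite(rv) and abs(rv) >= threshold:
                flagged.append((a, b, float(rv)))
    in_flagged = {v for pair in flagged for v in pair[:2]}
    retained = [c for c in cols if c not in in_flagged and c not in undefined]
    return {"correlations": r, "flagged_pairs": flagged,
            "undefined": undefined, "retained": retained,
            "threshold": threshold}
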