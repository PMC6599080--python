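"""Community-matrix null models and standardized effect sizes.

Three randomizations of a binary cell x species matrix:

- ``richness``: permute entries within each cell (row); keeps each cell's
  species richness but destroys species identities;
- ``frequency``: permute entries within each species (column); keeps each
  species' occurrence frequency but destroys cell structure;
- ``independent_swap``: repeated 2x2 checkerboard swaps
  ([[1,0],[0,1]] <-> [[0,1],[1,0]]), preserving both row and column sums.

The standardized effect size of assemblage color lightness is
SES = (observed CWM - null mean) / null SD, with the null moments taken
over ``n_randomizations`` independent randomized matrices.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .grid import CommunityMatrix

log = logging.getLogger(__name__)

__all__ = ["randomize_matrix", "compute_ses", "NULL_MODELS"]

NULL_MODELS = ("richness", "frequency", "independent_swap")


def _check_binary(arr: np.ndarray) -> None:
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("null models require a strictly binary matrix")


def independent_swap(arr: np.ndarray, n_swaps: int, rng: np.random.Generator,
                     max_attempt_factor: int = 100) -> tuple[np.ndarray, int]:
    """Perform ``n_swaps`` successful checkerboard swaps.

    Random 2x2 submatrices are proposed until ``n_swaps`` checkerboards have
    been flipped (both margins are conserved exactly by construction), or
    until ``max_attempt_factor * n_swaps`` proposals have been tried —
    whichever comes first.  Returns (matrix, n_successful).
    """
    out = arr.copy()
    n_rows, n_cols = out.shape
    if n_rows < 2 or n_cols < 2 or n_swaps == 0:
        return out, 0
    successes = 0
    attempts_left = max_attempt_factor * n_swaps
    batch = max(256, 4 * n_swaps)
    while successes < n_swaps and attempts_left > 0:
        m = min(batch, attempts_left)
        rows1 = rng.integers(0, n_rows, size=m)
        rows2 = rng.integers(0, n_rows - 1, size=m)
        rows2 = np.where(rows2 >= rows1, rows2 + 1, rows2)
        cols1 = rng.integers(0, n_cols, size=m)
        cols2 = rng.integers(0, n_cols - 1, size=m)
        cols2 = np.where(cols2 >= cols1, cols2 + 1, cols2)
        for r1, r2, c1, c2 in zip(rows1, rows2, cols1, cols2):
            attempts_left -= 1
            a, b = out[r1, c1], out[r1, c2]
            c, d = out[r2, c1], out[r2, c2]
            if a == d and b == c and a != b:
                out[r1, c1], out[r1, c2] = b, a
                out[r2, c1], out[r2, c2] = d, c
                successes += 1
                if successes >= n_swaps:
                    break
    return out, successes


def randomize_matrix(matrix: CommunityMatrix | np.ndarray, method: str,
                     n_swaps: int = 1000, seed: int | None = None,
                     rng: np.random.Generator | None = None):
    """One randomized copy of a binary community matrix.

    ``n_swaps`` counts attempted checkerboard proposals for
    ``independent_swap`` (successful swaps are logged); it is ignored by the
    permutation nulls.  Returns the same type as the input.
    """
    if method not in NULL_MODELS:
        raise ValueError(f"unknown null model {method!r}; choose from {NULL_MODELS}")
    as_cm = isinstance(matrix, CommunityMatrix)
    arr = matrix.values.to_numpy().copy() if as_cm else np.asarray(matrix).copy()
    _check_binary(arr)
    if rng is None:
        rng = np.random.default_rng(seed)
    if method == "richness":
        for i in range(arr.shape[0]):
            rng.shuffle(arr[i, :])
    elif method == "frequency":
        for j in range(arr.shape[1]):
            arr[:, j] = arr[rng.permutation(arr.shape[0]), j]
    else:
        arr, successes = independent_swap(arr, n_swaps, rng)
        if successes == 0:
            warnings.warn("independent_swap: no swappable checkerboard found; "
                          "matrix returned unchanged")
    if as_cm:
        out = pd.DataFrame(arr, index=matrix.values.index,
                           columns=matrix.values.columns)
        return CommunityMatrix(out, month=matrix.month, binary=True,
                               mode_partition=matrix.mode_partition)
    return arr


def compute_ses(matrix: CommunityMatrix, traits: pd.Series | pd.DataFrame,
                null_model: str = "independent_swap",
                n_randomizations: int = 100, n_swaps: int = 1000,
                seed: int = 0) -> pd.DataFrame:
    """SES of assemblage (CWM) lightness per cell of one monthly matrix.

    The observed CWM is the unweighted mean lightness of each cell's
    species; the null distribution comes from ``n_randomizations``
    independent randomizations (each from a child seed).  Cells whose null
    SD is zero get NaN SES.  Margin conservation of the swap null is
    asserted on every draw.
    """
    if isinstance(traits, pd.DataFrame):
        traits = traits["lightness_mean" if "lightness_mean" in traits else "lightness"]
    arr = matrix.values.to_numpy()
    _check_binary(arr)
    missing = [s for s in matrix.species if s not in traits.index]
    if missing:
        raise ValueError(f"species without traits: {missing[:5]}")
    t = traits.loc[matrix.species].to_numpy(dtype=float)
    row_n = arr.sum(axis=1)
    col_n = arr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = (arr @ t) / row_n
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=n_randomizations)
    null_cwm = np.empty((n_randomizations, arr.shape[0]))
    for k, cs in enumerate(child_seeds):
        rnd = randomize_matrix(arr, null_model, n_swaps=n_swaps, seed=int(cs))
        if null_model == "independent_swap":
            assert (rnd.sum(axis=1) == row_n).all() and (rnd.sum(axis=0) == col_n).all()
        elif null_model == "richness":
            assert (rnd.sum(axis=1) == row_n).all()
        else:
            assert (rnd.sum(axis=0) == col_n).all()
        rn = rnd.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_cwm[k] = (rnd @ t) / rn
    # a randomized matrix can leave a cell empty (frequency null); such
    # draws carry no CWM and are excluded from that cell's null moments
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.nanmean(null_cwm, axis=0)
        null_sd = np.nanstd(null_cwm, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = (observed - null_mean) / null_sd
    ses[~np.isfinite(ses)] = np.nan
    n_zero_sd = int((null_sd == 0).sum())
    if n_zero_sd:
        log.info("compute_ses: %d cells with zero null SD -> SES missing", n_zero_sd)
    return pd.DataFrame({
        "month": matrix.month,
        "observed_cwm": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "ses": ses,
        "n_randomizations": n_randomizations,
        "null_model": null_model,
    }, index=matrix.values.index.rename("cell_id"))
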