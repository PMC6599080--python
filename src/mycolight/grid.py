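"""Gridding of occurrence records and assemblage trait computation.

Occurrences on planar (UTM-style) coordinates are binned into half-open
50 km x 50 km cells, pooled across years into monthly presence/absence
community matrices, filtered for minimum sampling effort, and summarized
as community-weighted mean (CWM) color lightness per cell, month and
nutritional mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "assign_to_grid",
    "build_community_matrix",
    "apply_filters",
    "grid_environment_means",
    "assemblage_lightness",
]


@dataclass
class CommunityMatrix:
    """Cell x species occurrence matrix for one month slice (or pooled).

    ``values`` is a DataFrame indexed by cell_id with species columns;
    binary matrices hold {0, 1}.  ``mode_partition`` maps each species to
    its nutritional mode (saprotrophic / ectomycorrhizal) when known.
    """

    values: pd.DataFrame
    month: int | str = "all"
    binary: bool = True
    mode_partition: pd.Series | None = None

    def __post_init__(self):
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate cell or species labels")
        if self.binary:
            arr = self.values.to_numpy()
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("binary matrix contains values other than {0, 1}")

    @property
    def cells(self) -> list:
        return list(self.values.index)

    @property
    def species(self) -> list:
        return list(self.values.columns)

    def subset_mode(self, mode: str) -> "CommunityMatrix":
        if self.mode_partition is None:
            raise ValueError("no mode partition attached")
        cols = [s for s in self.species if self.mode_partition.get(s) == mode]
        return CommunityMatrix(self.values[cols], month=self.month,
                               binary=self.binary,
                               mode_partition=self.mode_partition.loc[cols])

    def to_triplets(self) -> pd.DataFrame:
        long = self.values.stack()
        long = long[long != 0].reset_index()
        long.columns = ["cell_id", "species_id", "value"]
        return long


def assign_to_grid(records: pd.DataFrame, cell_size: float = 50_000.0) -> pd.DataFrame:
    """Attach a ``cell_id`` column from floor-indexed half-open grid cells.

    cell = (floor(x / s), floor(y / s)); a point exactly on a boundary
    belongs to the higher-index cell.  Row count is preserved.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    xy = records[["x_m", "y_m"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite coordinates at rows {list(np.nonzero(bad)[0][:10])}")
    cx = np.floor(xy[:, 0] / cell_size).astype(int)
    cy = np.floor(xy[:, 1] / cell_size).astype(int)
    out = records.copy()
    out["cell_id"] = [f"{a}_{b}" for a, b in zip(cx, cy)]
    return out


def build_community_matrix(records: pd.DataFrame, *, by_month: bool = True,
                           binary: bool = True,
                           mode_partition: pd.Series | None = None,
                           ) -> dict[int | str, CommunityMatrix]:
    """Pool gridded records across years into per-month community matrices.

    Returns a dict keyed by month (1-12) plus ``"all"`` for the year- and
    month-pooled matrix.  With ``by_month=False`` only ``"all"`` is built.
    Binary matrices collapse duplicates to presence; count matrices sum the
    ``count`` column.
    """
    if records.empty:
        raise ValueError("no occurrence records")
    if "cell_id" not in records.columns:
        raise ValueError("records lack cell_id; run assign_to_grid first")

    def _pivot(rec: pd.DataFrame, month) -> CommunityMatrix:
        agg = rec.groupby(["cell_id", "species_id"])["count"].sum().unstack(fill_value=0)
        if binary:
            agg = (agg > 0).astype(int)
        return CommunityMatrix(agg, month=month, binary=binary,
                               mode_partition=mode_partition)

    out: dict[int | str, CommunityMatrix] = {"all": _pivot(records, "all")}
    if by_month:
        for month, rec in records.groupby("month"):
            out[int(month)] = _pivot(rec, int(month))
    return out


def apply_filters(matrix: CommunityMatrix, *, min_occurrences: int = 25,
                  taxa_whitelist: set[str] | None = None,
                  local_min_months: int | None = None,
                  month_counts: pd.Series | None = None) -> CommunityMatrix:
    """Apply the study's sampling-effort filters to one matrix.

    - cells with fewer than ``min_occurrences`` species presences for a
      nutritional mode are dropped from that mode's analysis set (applied
      per mode when a partition is attached, else on the full matrix);
    - ``taxa_whitelist`` restricts the species set (e.g. the four
      mushroom-forming orders);
    - species seen in fewer than ``local_min_months`` distinct months
      (supplied via ``month_counts``) are removed (local-dataset rule).

    Idempotent: filtering a filtered matrix changes nothing.
    """
    if min_occurrences < 0 or (local_min_months or 0) < 0:
        raise ValueError("thresholds must be >= 0")
    vals = matrix.values
    if taxa_whitelist is not None:
        vals = vals[[s for s in vals.columns if s in taxa_whitelist]]
    if local_min_months is not None:
        if month_counts is None:
            raise ValueError("local_min_months filter needs month_counts")
        keep = [s for s in vals.columns
                if month_counts.get(s, 0) >= local_min_months]
        vals = vals[keep]
    presences = (vals > 0).astype(int)
    if matrix.mode_partition is not None:
        modes = matrix.mode_partition
        keep_cells = pd.Series(True, index=vals.index)
        for mode in modes.dropna().unique():
            cols = [s for s in vals.columns if modes.get(s) == mode]
            keep_cells &= presences[cols].sum(axis=1) >= min_occurrences
    else:
        keep_cells = presences.sum(axis=1) >= min_occurrences
    dropped = int((~keep_cells).sum())
    if dropped:
        log.info("apply_filters: dropped %d of %d cells below %d occurrences",
                 dropped, len(keep_cells), min_occurrences)
    mp = matrix.mode_partition
    if mp is not None:
        mp = mp.loc[[s for s in vals.columns if s in mp.index]]
    return CommunityMatrix(vals.loc[keep_cells], month=matrix.month,
                           binary=matrix.binary, mode_partition=mp)


def grid_environment_means(fine_values: pd.DataFrame,
                           occupied_subgrids: set | None = None,
                           *, cell_col: str = "cell_id",
                           subgrid_col: str = "subgrid_id") -> pd.DataFrame:
    """Cell means of fine-resolution environmental values.

    ``fine_values`` is long-format with one row per subgrid and one column
    per variable.  When ``occupied_subgrids`` is given, means use only
    subgrids holding fungal records (the record-weighted variant); pass
    ``None`` for the unweighted fallback.  Cells with zero occupied
    subgrids yield NaN and are logged.
    """
    df = fine_values
    if occupied_subgrids is not None:
        df = df[df[subgrid_col].isin(occupied_subgrids)]
    value_cols = [c for c in fine_values.columns if c not in (cell_col, subgrid_col)]
    means = df.groupby(cell_col)[value_cols].mean()
    empty = set(fine_values[cell_col]) - set(means.index)
    if empty:
        log.warning("grid_environment_means: %d cells with no occupied subgrids",
                    len(empty))
        means = means.reindex(sorted(set(fine_values[cell_col])))
    return means


def assemblage_lightness(matrix: CommunityMatrix, traits: pd.Series | pd.DataFrame,
                         weighting: str = "presence") -> pd.DataFrame:
    """Community-weighted mean lightness per cell of one matrix.

    presence: unweighted mean over member species; abundance: count-weighted
    mean.  Species without a trait are dropped with a warning; empty
    assemblages give NaN.  Returns cell_id-indexed DataFrame with
    cwm_lightness, species_richness, month and weighting columns.
    """
    if weighting not in ("presence", "abundance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if isinstance(traits, pd.DataFrame):
        traits = traits["lightness_mean" if "lightness_mean" in traits else "lightness"]
    vals = matrix.values
    missing = [s for s in vals.columns if s not in traits.index or
               not np.isfinite(traits.get(s, np.nan))]
    if missing:
        warnings.warn(f"{len(missing)} species lack a color trait and were dropped")
        vals = vals.drop(columns=missing)
    t = traits.loc[vals.columns].to_numpy(dtype=float)
    w = vals.to_numpy(dtype=float)
    if weighting == "presence":
        w = (w > 0).astype(float)
    totals = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cwm = (w @ t) / totals
    cwm[totals == 0] = np.nan
    return pd.DataFrame({
        "cwm_lightness": cwm,
        "species_richness": (vals.to_numpy() > 0).sum(axis=1),
        "month": matrix.month,
        "weighting": weighting,
    }, index=vals.index.rename("cell_id"))
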