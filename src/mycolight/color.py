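"""Cap-color trait extraction in HSL space.

Species color traits are built from small sets of ``#RRGGBB`` samples taken
on a nine-point cross over each mushroom cap.  Every hex string decomposes
into hue (degrees), saturation and lightness (both on 0-100); the lightness
mean per species is the trait ``L`` used by every downstream assemblage and
phylogenetic analysis.  Hue is angular, so species means use a circular
model; achromatic samples (saturation zero) carry no hue information and are
excluded from the circular mean.
"""

from __future__ import annotations

import colorsys
import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ColorSample",
    "SpeciesColorRecord",
    "hex_to_hsl",
    "hsl_to_hex",
    "circular_mean_hue",
    "aggregate_species_color",
    "aggregate_color_table",
    "validate_against_reference",
    "read_samples_csv",
    "write_species_records_csv",
]

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")


@dataclass(frozen=True)
class ColorSample:
    """One pipette sample from one cap image."""

    species_id: str
    hex: str
    hue: float
    saturation: float
    lightness: float
    image_id: str = ""

    @classmethod
    def from_hex(cls, species_id: str, hex_string: str, image_id: str = "") -> "ColorSample":
        h, s, l = hex_to_hsl(hex_string)
        return cls(species_id=species_id, hex=hex_string.upper(), hue=h,
                   saturation=s, lightness=l, image_id=image_id)


@dataclass(frozen=True)
class SpeciesColorRecord:
    """Per-species aggregated color trait (lightness_mean is the trait L)."""

    species_id: str
    n_samples: int
    hue_mean: float  # circular mean over chromatic samples; NaN if undefined
    saturation_mean: float
    lightness_mean: float
    lightness_sd: float


def hex_to_hsl(hex_string: str) -> tuple[float, float, float]:
    """Decompose ``#RRGGBB`` into (hue deg [0,360), saturation %, lightness %).

    Standard HSL cylinder transform of the sRGB bytes.  Hue is defined as 0
    for achromatic colors (saturation 0).  Lightness is scaled 0 (black) to
    100 (white).
    """
    if not isinstance(hex_string, str) or not _HEX_RE.match(hex_string):
        raise ValueError(f"malformed hex color: {hex_string!r} (expected '#RRGGBB')")
    r, g, b = (int(hex_string[i:i + 2], 16) / 255.0 for i in (1, 3, 5))
    h, l, s = colorsys.rgb_to_hls(r, g, b)
    return (h * 360.0) % 360.0, s * 100.0, l * 100.0


def hsl_to_hex(hue: float, saturation: float, lightness: float) -> str:
    """Inverse of :func:`hex_to_hsl`, quantizing to 8-bit channels."""
    r, g, b = colorsys.hls_to_rgb((hue % 360.0) / 360.0, lightness / 100.0,
                                  saturation / 100.0)
    return "#{:02X}{:02X}{:02X}".format(*(int(round(c * 255.0)) for c in (r, g, b)))


def circular_mean_hue(hues: Sequence[float]) -> float:
    """Circular mean of hue angles in degrees, mapped to [0, 360).

    Returns NaN when the resultant vector is (numerically) zero, in which
    case the mean direction is undefined.
    """
    hues = np.asarray(list(hues), dtype=float)
    if hues.size == 0:
        raise ValueError("circular_mean_hue: empty hue list")
    rad = np.deg2rad(hues)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    if math.hypot(s, c) < 1e-12:
        return float("nan")
    deg = float(np.rad2deg(math.atan2(s, c)) % 360.0)
    return 0.0 if deg >= 360.0 - 1e-9 else deg


def aggregate_species_color(samples: Iterable[ColorSample],
                            species_id: str | None = None) -> SpeciesColorRecord:
    """Pool all samples of one species into a :class:`SpeciesColorRecord`.

    Arithmetic means for saturation and lightness, circular mean for hue
    (achromatic samples excluded).  All samples are weighted equally,
    regardless of which image they came from.
    """
    samples = list(samples)
    if not samples:
        raise ValueError(f"no color samples for species {species_id!r}")
    ids = {s.species_id for s in samples}
    if species_id is None:
        if len(ids) != 1:
            raise ValueError(f"samples mix several species: {sorted(ids)}")
        species_id = next(iter(ids))
    elif ids != {species_id}:
        raise ValueError(f"samples for {sorted(ids)} do not all match {species_id!r}")
    light = np.array([s.lightness for s in samples])
    sat = np.array([s.saturation for s in samples])
    chromatic = [s.hue for s in samples if s.saturation > 0]
    hue_mean = circular_mean_hue(chromatic) if chromatic else float("nan")
    return SpeciesColorRecord(
        species_id=species_id,
        n_samples=len(samples),
        hue_mean=hue_mean,
        saturation_mean=float(sat.mean()),
        lightness_mean=float(light.mean()),
        lightness_sd=float(light.std(ddof=1)) if len(samples) > 1 else 0.0,
    )


def aggregate_color_table(samples: pd.DataFrame, min_samples: int = 9) -> pd.DataFrame:
    """Aggregate a long sample table (species_id, image_id, hex) per species.

    Species with fewer than ``min_samples`` samples are kept but flagged in
    the ``below_min`` column (real-data protocol expects >= 9 per cap).
    """
    required = {"species_id", "hex"}
    if not required.issubset(samples.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    records = []
    for sp, grp in samples.groupby("species_id", sort=True):
        objs = [ColorSample.from_hex(sp, hx, img)
                for hx, img in zip(grp["hex"], grp.get("image_id", [""] * len(grp)))]
        rec = aggregate_species_color(objs, sp)
        records.append({
            "species_id": rec.species_id,
            "n_samples": rec.n_samples,
            "hue_mean": rec.hue_mean,
            "saturation_mean": rec.saturation_mean,
            "lightness_mean": rec.lightness_mean,
            "lightness_sd": rec.lightness_sd,
            "below_min": rec.n_samples < min_samples,
        })
    return pd.DataFrame(records).set_index("species_id")


def validate_against_reference(web_lightness: pd.Series,
                               reference_lightness: pd.Series) -> dict:
    """Regress reference (illustration) lightness on web-survey lightness.

    Returns OLS slope/intercept with confidence interval, R-squared and a
    Wald test of slope == 1 — the standard reliability check of a web-sourced
    trait against an independent reference.  Needs >= 3 shared species.
    """
    shared = web_lightness.index.intersection(reference_lightness.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared species; need >= 3")
    x = web_lightness.loc[shared].astype(float)
    y = reference_lightness.loc[shared].astype(float)
    if float(np.var(y)) == 0.0:
        return {"n": len(shared), "slope": float("nan"), "intercept": float("nan"),
                "r_squared": float("nan"), "slope_ci": (float("nan"), float("nan")),
                "p_slope_eq_1": float("nan"), "degenerate": "constant reference"}
    fit = sm.OLS(y.values, sm.add_constant(x.values)).fit()
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    ci = fit.conf_int()[1]
    # Wald test of slope == 1
    t_stat = (slope - 1.0) / float(fit.bse[1])
    from scipy import stats as sps
    p = float(2.0 * sps.t.sf(abs(t_stat), fit.df_resid))
    return {"n": int(len(shared)), "slope": slope, "intercept": intercept,
            "r_squared": float(fit.rsquared), "slope_ci": (float(ci[0]), float(ci[1])),
            "t_slope_eq_1": float(t_stat), "p_slope_eq_1": p, "degenerate": None}


def read_samples_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"species_id": str, "image_id": str})


def write_species_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path)
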