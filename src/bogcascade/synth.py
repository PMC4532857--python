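"""Synthetic inputs with the statistical structure the pipeline assumes.

Every external dataset the cascade consumes has a seeded generator here:
hilly terrain with an elevation-dependent habitat mosaic; seasonal
monthly climate along a west-east rainfall gradient (wet Mid Wales
~2,071 mm/yr, South Pennines ~1,359 mm, dry North York Moors
~1,016 mm); negative-binomial cranefly quartet counts that decline
log-linearly with the previous summer's water-table depth; bird counts
for two survey years that are log-linear in cranefly abundance and
correlated between years through a shared square effect; and noisy
dipwell observations with a systematic offset for calibration tests.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .hydro import MonthlyClimate, WTDSeries
from .landscape import DEMGrid

__all__ = [
    "SynthConfig",
    "REGION_ANNUAL_RAIN_MM",
    "make_dem",
    "make_climate",
    "make_cranefly_counts",
    "make_bird_counts",
    "make_dipwells",
]

# 1961-1990 mean annual rainfall of the three focal landscapes
REGION_ANNUAL_RAIN_MM = {
    "MidWales": 2071.0,
    "SouthPennines": 1359.0,
    "NorthYorkMoors": 1016.0,
}

HABITATS = ("heath", "rough grassland", "woodland", "improved grassland")


@dataclass(frozen=True)
class SynthConfig:
    """Defaults for every generator, mirroring the study conditions."""

    seed: int = 0

    # terrain
    dem_nx: int = 60
    dem_ny: int = 60
    dem_cell_m: float = 10.0
    dem_base_elevation_m: float = 350.0
    dem_relief_m: float = 250.0        # range 225-475 m straddles the peat cutoff

    # climate
    annual_rain_mm: float = 2071.0     # Mid Wales default
    rain_seasonality: float = 0.35     # winter-wet amplitude (fraction)
    temp_mean_c: float = 6.5           # upland UK annual mean
    temp_amplitude_c: float = 5.5      # summer-winter half-range
    precip_cv: float = 0.3
    temp_sd_c: float = 1.0

    # cranefly generating model (quartet counts, log link)
    cranefly_intercept: float = 5.203
    cranefly_wtd_slope: float = -0.333
    cranefly_region_effects: Mapping[str, float] = field(
        default_factory=lambda: {"MidWales": 0.0, "NorthYorkMoors": 0.0,
                                 "SouthPennines": 0.0})
    cranefly_theta: float = 2.0
    n_quartets: int = 128              # sample locations across 3 regions

    # bird generating models (counts, log link in cranefly abundance)
    bird_coeffs: Mapping[str, tuple] = field(
        default_factory=lambda: {
            # (intercept, slope per quartet-count unit of cranefly abundance)
            "dunlin": (-1.5, 0.020),
            "golden plover": (-0.5, 0.015),
            "red grouse": (0.5, 0.008),
        })
    bird_theta: float = 1.5
    bird_square_sd: float = 0.8        # shared square effect -> year correlation
    n_squares: int = 557

    # dipwells
    dipwell_noise_sd_cm: float = 1.5
    dipwell_offset_cm: float = -2.8
    manual_extra_sd_cm: float = 2.0    # single-day sampling penalty


DEFAULT_SYNTH = SynthConfig()


# --------------------------------------------------------------------------
# terrain
# --------------------------------------------------------------------------

def make_dem(nx: int = 60, ny: int = 60, relief: float = 250.0,
             seed: int = 0, cell_size: float = 10.0,
             base_elevation: float = 350.0,
             origin: tuple = (0.0, 0.0)) -> DEMGrid:
    """Smooth random terrain with an elevation-dependent habitat mosaic.

    Filtered Gaussian noise plus one broad hill, scaled to ``relief``
    metres of total range around ``base_elevation``.  Habitat is heath or
    rough grassland on the high ground, grading into woodland and
    improved grassland below ~250 m.
    """
    if nx < 10 or ny < 10:
        raise ValueError("DEM must be at least 10x10")
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma=4.0)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = 0.35 * ny, 0.6 * nx
    hill = np.exp(-(((yy - cy) / (0.45 * ny)) ** 2
                    + ((xx - cx) / (0.45 * nx)) ** 2))
    z = noise + 1.5 * hill
    if relief > 0 and np.ptp(z) > 0:
        # anchor the realized range exactly at [base - relief/2, base + relief/2]
        z = (z - z.min()) / np.ptp(z) * relief - relief / 2.0
    else:
        z = np.zeros_like(z)
    elevation = base_elevation + z
    # habitat probabilities shift with elevation
    u = rng.random((ny, nx))
    habitat = np.empty((ny, nx), dtype=object)
    high = elevation >= 250.0
    habitat[high & (u < 0.55)] = "heath"
    habitat[high & (u >= 0.55) & (u < 0.90)] = "rough grassland"
    habitat[high & (u >= 0.90)] = "woodland"
    habitat[~high & (u < 0.45)] = "improved grassland"
    habitat[~high & (u >= 0.45) & (u < 0.80)] = "woodland"
    habitat[~high & (u >= 0.80)] = "rough grassland"
    return DEMGrid(elevation=elevation, cell_size=cell_size, origin=origin,
                   habitat=habitat)


# --------------------------------------------------------------------------
# climate
# --------------------------------------------------------------------------

def _monthly_normals(annual_rain_mm: float, seasonality: float,
                     temp_mean: float, temp_amp: float):
    """Winter-wet rain and summer-warm temperature normals (Jan first)."""
    m = np.arange(1, 13)
    rain = annual_rain_mm / 12.0 * (1.0 + seasonality * np.cos(2 * np.pi * (m - 1) / 12.0))
    temp = temp_mean - temp_amp * np.cos(2 * np.pi * (m - 1) / 12.0)
    return rain, temp


def make_climate(annual_rain_mm: float, years: int, seed: int = 0,
                 start_year: int = 1961,
                 seasonality: float = 0.35,
                 temp_mean_c: float = 6.5,
                 temp_amplitude_c: float = 5.5,
                 precip_cv: float = 0.3,
                 temp_sd_c: float = 1.0,
                 rain_trend_per_year: float = 0.0,
                 temp_trend_per_year: float = 0.0) -> MonthlyClimate:
    """Seeded monthly climate: seasonal sinusoid plus gamma rain noise
    and normal temperature noise; expected annual total equals the
    target.  Optional linear trends emulate scenario forcing."""
    if annual_rain_mm <= 0:
        raise ValueError("annual rainfall target must be positive")
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    rain_n, temp_n = _monthly_normals(annual_rain_mm, seasonality,
                                      temp_mean_c, temp_amplitude_c)
    year = np.repeat(np.arange(start_year, start_year + years), 12)
    month = np.tile(np.arange(1, 13), years)
    elapsed = year - start_year
    # rain trend is in mm of annual total per year, spread evenly over months
    p_mean = np.maximum(rain_n[month - 1] + rain_trend_per_year * elapsed / 12.0,
                        0.01)
    t_mean = temp_n[month - 1] + temp_trend_per_year * elapsed
    if precip_cv > 0:
        shape = 1.0 / precip_cv ** 2
        precip = rng.gamma(shape, p_mean / shape)
    else:
        precip = p_mean.copy()
    temp = rng.normal(t_mean, temp_sd_c) if temp_sd_c > 0 else t_mean.copy()
    return MonthlyClimate(year, month, precip, temp)


# --------------------------------------------------------------------------
# counts
# --------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 sample with mean mu and dispersion theta (gamma-Poisson mix)."""
    lam = rng.gamma(theta, mu / theta)
    return rng.poisson(lam)


def make_cranefly_counts(wtd_cm: Sequence[float], regions: Sequence[str],
                         intercept: float = 5.203, wtd_slope: float = -0.333,
                         region_effects: Mapping[str, float] | None = None,
                         theta: float = 2.0, seed: int = 0) -> np.ndarray:
    """Quartet counts ~ NB(exp(intercept + region + slope*wtd), theta)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    wtd = np.asarray(wtd_cm, float)
    regions = np.asarray(regions, dtype=object)
    if region_effects is None:
        region_effects = {}
    eff = np.array([float(region_effects.get(r, 0.0)) for r in regions])
    mu = np.exp(intercept + eff + wtd_slope * wtd)
    rng = np.random.default_rng(seed)
    return _nb_draw(rng, mu, theta)


def make_bird_counts(cranefly_1990: Sequence[float],
                     cranefly_2004: Sequence[float],
                     intercept: float, slope: float,
                     theta: float = 1.5, square_sd: float = 0.8,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Counts for the two survey years, log-linear in cranefly abundance.

    A shared square-level normal effect on the linear predictor couples
    the years, producing the moderate between-year rank correlations
    seen in repeat surveys.
    """
    if theta <= 0 or square_sd < 0:
        raise ValueError("invalid dispersion parameters")
    c90 = np.asarray(cranefly_1990, float)
    c04 = np.asarray(cranefly_2004, float)
    if c90.shape != c04.shape:
        raise ValueError("year vectors must align")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, square_sd, size=c90.shape)
    y90 = _nb_draw(rng, np.exp(intercept + slope * c90 + b), theta)
    y04 = _nb_draw(rng, np.exp(intercept + slope * c04 + b), theta)
    return y90, y04


# --------------------------------------------------------------------------
# dipwells
# --------------------------------------------------------------------------

def make_dipwells(true_series: WTDSeries, noise_sd: float = 1.5,
                  offset_cm: float = -2.8, scheme: str = "automatic-monthly-mean",
                  seed: int = 0, manual_extra_sd: float = 2.0) -> WTDSeries:
    """Observed dipwell series: truth + systematic offset + noise.

    ``automatic-monthly-mean`` adds only instrument noise; ``manual-
    monthly`` emulates a single manual reading per month, which carries
    extra within-month sampling variance.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if scheme not in ("automatic-monthly-mean", "manual-monthly"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    sd = noise_sd if scheme == "automatic-monthly-mean" else math.hypot(
        noise_sd, manual_extra_sd)
    noise = rng.normal(0.0, sd, size=len(true_series)) if sd > 0 else 0.0
    return WTDSeries(true_series.year, true_series.month,
                     true_series.wtd_cm + offset_cm + noise)
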