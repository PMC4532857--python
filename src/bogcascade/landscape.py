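"""Landscape-scale projection of water tables and cranefly abundance.

A 10 m DEM is reduced to slope/aspect/elevation per cell (Horn's
third-order finite differences), cells are masked to deep-peat habitat
(heath or rough grassland at >= 250 m), and the remaining cells are
grouped into topographic bins so that one column simulation per unique
bin covers the whole landscape.  Cells inherit the water-table series of
their bin's midpoint, and value grids are averaged landscape-wide or
within 1 x 1 km survey squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .hydro import (DEFAULT_PARAMS, HydroParams, MonthlyClimate,
                    TopographicCell, WTDSeries, simulate, summer_mean_wtd)

logger = logging.getLogger(__name__)

__all__ = [
    "DEMGrid",
    "BinScheme",
    "TopoBin",
    "LandscapeProjection",
    "derive_slope_aspect",
    "bin_topography",
    "apply_mask",
    "project_landscape",
    "aggregate_cells",
    "aggregate_to_square",
]

PEAT_HABITATS = frozenset({"heath", "rough grassland"})
MIN_PEAT_ELEVATION_M = 250.0


@dataclass
class DEMGrid:
    """Rectangular elevation raster with optional habitat layer.

    ``origin`` is the (x, y) of the grid's south-west corner in projected
    metres; row 0 of ``elevation`` is the NORTHERN edge (image order).
    """

    elevation: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    habitat: Optional[np.ndarray] = None
    nodata: float = -9999.0

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.habitat is not None:
            self.habitat = np.asarray(self.habitat, dtype=object)
            if self.habitat.shape != self.elevation.shape:
                raise ValueError("habitat layer shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) of every cell centre, matching array layout."""
        ny, nx = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 + (ny - np.arange(ny) - 0.5) * self.cell_size  # row 0 = north
        return np.meshgrid(xs, ys)


# --------------------------------------------------------------------------
# terrain derivatives
# --------------------------------------------------------------------------

def _pad_linear(z: np.ndarray) -> np.ndarray:
    """Pad by linear extrapolation so border cells get one-sided slopes."""
    p = np.pad(z, 1, mode="edge")
    p[0, 1:-1] = 2 * z[0] - z[1]
    p[-1, 1:-1] = 2 * z[-1] - z[-2]
    p[1:-1, 0] = 2 * z[:, 0] - z[:, 1]
    p[1:-1, -1] = 2 * z[:, -1] - z[:, -2]
    # corners from the two adjacent edges
    p[0, 0] = p[0, 1] + p[1, 0] - p[1, 1]
    p[0, -1] = p[0, -2] + p[1, -1] - p[1, -2]
    p[-1, 0] = p[-1, 1] + p[-2, 0] - p[-2, 1]
    p[-1, -1] = p[-1, -2] + p[-2, -1] - p[-2, -2]
    return p


def derive_slope_aspect(dem: DEMGrid) -> tuple[np.ndarray, np.ndarray]:
    """Slope (deg) and aspect (deg, 0 = north, clockwise, downslope
    direction) by Horn's 8-neighbour finite differences.

    Flat cells get slope 0 and the sentinel aspect 0.
    """
    ny, nx = dem.shape
    if ny < 3 or nx < 3:
        raise ValueError("DEM must be at least 3x3")
    z = _pad_linear(dem.elevation)
    c = dem.cell_size
    # Horn kernel; row 0 is north, columns increase eastward
    a, b_, cc = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dz_dx = ((cc + 2 * f + i) - (a + 2 * d + g)) / (8.0 * c)       # east
    dz_dy = ((a + 2 * b_ + cc) - (g + 2 * h + i)) / (8.0 * c)      # north
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    # downslope compass bearing: direction of -gradient
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    flat = slope == 0.0
    aspect[flat] = 0.0
    return slope, aspect


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Interval widths for topographic aggregation.

    ``landscape``: 50 m elevation / 10 deg aspect / 1 deg slope.
    ``birds``: 50 m / 15 deg / 2 deg for slopes <= 20 deg, 5 deg above.
    ``exact`` keeps every distinct (slope, aspect, elevation) tuple as its
    own bin (used for convergence checks).
    """

    name: str = "landscape"
    elev_width: float = 50.0
    aspect_width: float = 10.0
    slope_width: float = 1.0
    slope_width_steep: Optional[float] = None  # used above slope_break
    slope_break: float = 20.0

    @classmethod
    def landscape(cls) -> "BinScheme":
        return cls("landscape", 50.0, 10.0, 1.0)

    @classmethod
    def birds(cls) -> "BinScheme":
        return cls("birds", 50.0, 15.0, 2.0, slope_width_steep=5.0, slope_break=20.0)

    @classmethod
    def exact(cls) -> "BinScheme":
        return cls("exact", 0.0, 0.0, 0.0)

    def _interval(self, value: float, width: float) -> tuple[float, float]:
        if width <= 0:  # identity binning
            return (value, value)
        left = math.floor(value / width) * width
        return (left, left + width)

    def slope_interval(self, slope: float) -> tuple[float, float]:
        if self.slope_width <= 0:
            return (slope, slope)
        if self.slope_width_steep is not None and slope > self.slope_break:
            w = self.slope_width_steep
            left = self.slope_break + math.floor((slope - self.slope_break) / w) * w
            return (left, left + w)
        return self._interval(slope, self.slope_width)

    def aspect_interval(self, aspect: float) -> tuple[float, float]:
        return self._interval(aspect % 360.0, self.aspect_width)

    def elev_interval(self, elev: float) -> tuple[float, float]:
        return self._interval(elev, self.elev_width)


@dataclass(frozen=True)
class TopoBin:
    """One aggregation class: three intervals plus the midpoint cell."""

    elev_interval: tuple[float, float]
    aspect_interval: tuple[float, float]
    slope_interval: tuple[float, float]

    @property
    def midpoint(self) -> TopographicCell:
        def mid(iv):
            return 0.5 * (iv[0] + iv[1])
        return TopographicCell(slope_deg=mid(self.slope_interval),
                               aspect_deg=mid(self.aspect_interval) % 360.0,
                               elevation_m=mid(self.elev_interval))


def bin_topography(slope: np.ndarray, aspect: np.ndarray, elevation: np.ndarray,
                   scheme: BinScheme) -> tuple[list[TopoBin], np.ndarray]:
    """Group cells into bins; returns (unique bins, flat cell->bin index).

    Intervals are left-closed right-open, anchored at 0.  NaN cells map
    to index -1.
    """
    slope = np.asarray(slope, float).ravel()
    aspect = np.asarray(aspect, float).ravel()
    elevation = np.asarray(elevation, float).ravel()
    bins: list[TopoBin] = []
    lookup: dict[TopoBin, int] = {}
    idx = np.full(slope.shape, -1, dtype=int)
    for i in range(len(slope)):
        if not (np.isfinite(slope[i]) and np.isfinite(aspect[i])
                and np.isfinite(elevation[i])):
            continue
        b = TopoBin(scheme.elev_interval(elevation[i]),
                    scheme.aspect_interval(aspect[i]),
                    scheme.slope_interval(slope[i]))
        j = lookup.get(b)
        if j is None:
            j = len(bins)
            lookup[b] = j
            bins.append(b)
        idx[i] = j
    return bins, idx


# --------------------------------------------------------------------------
# masking and projection
# --------------------------------------------------------------------------

def apply_mask(dem: DEMGrid,
               habitats: frozenset[str] = PEAT_HABITATS,
               min_elevation_m: float = MIN_PEAT_ELEVATION_M) -> np.ndarray:
    """Boolean grid of cells retained for blanket-peat modelling.

    Retained iff habitat is heath or rough grassland (case-insensitive)
    AND elevation >= 250 m.
    """
    if dem.habitat is None:
        raise ValueError("DEM has no habitat layer")
    hab = np.char.lower(np.char.strip(dem.habitat.astype(str)))
    known = np.isin(hab, sorted(habitats | {"woodland", "improved grassland"}))
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("excluding %d cells with unrecognised habitat codes", n_unknown)
    keep = np.isin(hab, sorted(habitats)) & (dem.elevation >= min_elevation_m)
    return keep


@dataclass
class LandscapeProjection:
    """Per-bin WTD series plus the cell->bin mapping."""

    dem: DEMGrid
    mask: np.ndarray
    bins: list[TopoBin]
    bin_index: np.ndarray       # flat, -1 for masked cells
    bin_series: list[WTDSeries]
    n_runs: int

    def grid_from_bins(self, per_bin: Sequence[float]) -> np.ndarray:
        """Spread per-bin scalars to a cell grid (NaN outside the mask)."""
        out = np.full(self.dem.shape[0] * self.dem.shape[1], np.nan)
        ok = self.bin_index >= 0
        out[ok] = np.asarray(per_bin, float)[self.bin_index[ok]]
        return out.reshape(self.dem.shape)

    def summer_wtd_grid(self, sampling_year: int) -> np.ndarray:
        """Mean Jul-Sep WTD (of sampling_year - 1) per cell."""
        vals = [summer_mean_wtd(s, sampling_year) for s in self.bin_series]
        return self.grid_from_bins(vals)

    def abundance_grid(self, sampling_year: int,
                       predict: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
        """Cranefly abundance per cell for ``sampling_year`` via ``predict``."""
        wtd = np.array([summer_mean_wtd(s, sampling_year) for s in self.bin_series])
        return self.grid_from_bins(np.asarray(predict(wtd), float))


def project_landscape(dem: DEMGrid, scheme: BinScheme, climate: MonthlyClimate,
                      params: HydroParams = DEFAULT_PARAMS,
                      spinup_climate: MonthlyClimate | None = None,
                      mask: np.ndarray | None = None) -> LandscapeProjection:
    """One column simulation per unique topographic bin; cells inherit
    their bin's series.  Masked cells carry no data."""
    slope, aspect = derive_slope_aspect(dem)
    if mask is None:
        mask = (apply_mask(dem) if dem.habitat is not None
                else np.ones(dem.shape, dtype=bool))
    s = np.where(mask, slope, np.nan)
    a = np.where(mask, aspect, np.nan)
    e = np.where(mask, dem.elevation, np.nan)
    bins, idx = bin_topography(s, a, e, scheme)
    series: list[WTDSeries] = []
    for b in bins:
        try:
            series.append(simulate(climate, b.midpoint, spinup_climate, params))
        except Exception:  # pragma: no cover - continue other bins
            logger.exception("simulation failed for bin %s", b)
            series.append(WTDSeries(climate.year, climate.month,
                                    np.full(len(climate), np.nan)))
    return LandscapeProjection(dem=dem, mask=mask, bins=bins, bin_index=idx,
                               bin_series=series, n_runs=len(bins))


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def aggregate_cells(values: np.ndarray) -> float:
    """Landscape mean over retained (non-NaN) cells."""
    v = np.asarray(values, float)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("no retained cells to aggregate")
    return float(v[ok].mean())


def aggregate_to_square(values: np.ndarray, dem: DEMGrid,
                        square_sw: tuple[float, float],
                        square_size: float = 1000.0) -> float:
    """Mean over cells whose centres fall in the half-open square
    [x0, x0+size) x [y0, y0+size).  NaN if the square holds no data."""
    xs, ys = dem.cell_centres()
    x0, y0 = square_sw
    inside = ((xs >= x0) & (xs < x0 + square_size)
              & (ys >= y0) & (ys < y0 + square_size))
    v = np.asarray(values, float)[inside]
    v = v[np.isfinite(v)]
    if v.size == 0:
        logger.warning("square at (%s, %s) holds no retained cells", x0, y0)
        return float("nan")
    return float(v.mean())
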