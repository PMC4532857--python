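"""Future climate forcing and trend summaries.

The climate-change workflow mirrors how stochastic weather-generator
output is turned into one continuous forcing series: for each
overlapping 30-year period (2010-2039, 2020-2049, ..., 2070-2099) an
ensemble of monthly realizations is drawn around the period's climatic
normals, the realizations are ranked by mean summer (Jul-Sep) rainfall
and the 50th driest of 100 is taken as the period's representative
(approximate median) run, and the middle decade of each representative
run is spliced into a continuous 70-year sequence.  Downstream, annual
landscape-mean abundances are aggregated to decadal means, regressed on
time, and expressed as 30-year-window changes.

The generator here is a transparent gamma (precipitation) / normal
(temperature) monthly sampler around user-supplied normals; it does not
emulate any particular weather generator's internal structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hydro import MonthlyClimate, SUMMER_MONTHS

logger = logging.getLogger(__name__)

__all__ = [
    "ClimatePeriod",
    "Realization",
    "generate_realizations",
    "select_median_run",
    "splice_middle_decades",
    "decadal_means",
    "trend_regression",
    "thirty_year_change",
    "project_70yr",
]

PERIOD_YEARS = 30
PERIOD_STEP = 10


@dataclass(frozen=True)
class ClimatePeriod:
    """A 30-year climate period defined by monthly normals.

    ``precip_normals_mm`` and ``temp_normals_c`` have 12 entries
    (January first).  ``precip_cv`` is the coefficient of variation of a
    monthly precipitation total; ``temp_sd_c`` the s.d. of a monthly
    mean temperature.
    """

    start_year: int
    precip_normals_mm: tuple
    temp_normals_c: tuple
    precip_cv: float = 0.3
    temp_sd_c: float = 1.0

    def __post_init__(self):
        if len(self.precip_normals_mm) != 12 or len(self.temp_normals_c) != 12:
            raise ValueError("normals must have 12 monthly entries")
        if self.precip_cv <= 0 or self.temp_sd_c < 0:
            raise ValueError("invalid variability parameters")

    @property
    def end_year(self) -> int:
        return self.start_year + PERIOD_YEARS - 1

    @property
    def middle_decade(self) -> tuple[int, int]:
        return (self.start_year + 10, self.start_year + 19)


@dataclass(frozen=True)
class Realization:
    """One stochastic 30-year monthly series from a period's normals."""

    seed: int
    climate: MonthlyClimate
    mean_summer_rain_mm: float

    def __post_init__(self):
        if len(self.climate) != PERIOD_YEARS * 12:
            raise ValueError("realization must span 360 months")


def generate_realizations(period: ClimatePeriod, n: int,
                          seed: int) -> list[Realization]:
    """Draw ``n`` seeded monthly realizations around the period normals.

    Monthly precipitation is gamma-distributed with the normal as mean
    and the configured CV; temperature is normal.  Reproducible: each
    realization uses a child seed derived from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    years = np.repeat(np.arange(period.start_year, period.end_year + 1), 12)
    months = np.tile(np.arange(1, 13), PERIOD_YEARS)
    p_mean = np.tile(np.asarray(period.precip_normals_mm, float), PERIOD_YEARS)
    t_mean = np.tile(np.asarray(period.temp_normals_c, float), PERIOD_YEARS)
    shape = 1.0 / period.precip_cv ** 2  # gamma: CV depends on shape only
    out = []
    for k in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        precip = rng.gamma(shape, p_mean / shape)
        temp = rng.normal(t_mean, period.temp_sd_c)
        clim = MonthlyClimate(years, months, precip, temp)
        summer = np.isin(months, SUMMER_MONTHS)
        out.append(Realization(seed=k, climate=clim,
                               mean_summer_rain_mm=float(precip[summer].mean())))
    return out


def select_median_run(realizations: Sequence[Realization]) -> Realization:
    """The approximate-median run: rank by mean summer rainfall
    (ascending, ties broken by seed) and take the ceil(n/2)-th driest —
    the 50th of 100."""
    if not realizations:
        raise ValueError("no realizations supplied")
    ordered = sorted(realizations,
                     key=lambda r: (r.mean_summer_rain_mm, r.seed))
    return ordered[math.ceil(len(ordered) / 2) - 1]


def splice_middle_decades(periods: Sequence[ClimatePeriod],
                          selected: Sequence[Realization]) -> MonthlyClimate:
    """Concatenate the middle decade of each period's selected run.

    Periods must be ordered, step by 10 years and span 30; the output is
    a contiguous, duplicate-free monthly series (70 years for the seven
    standard periods), every month bit-identical to its source run.
    """
    if len(periods) != len(selected):
        raise ValueError("periods and selected runs must align")
    for a, b in zip(periods, periods[1:]):
        if b.start_year - a.start_year != PERIOD_STEP:
            raise ValueError("periods must step by 10 years")
    parts = []
    for period, run in zip(periods, selected):
        y0, y1 = period.middle_decade
        clim = run.climate
        keep = (clim.year >= y0) & (clim.year <= y1)
        if keep.sum() != 120:
            raise ValueError(f"run for period {period.start_year} does not "
                             f"cover its middle decade {y0}-{y1}")
        parts.append((clim.year[keep], clim.month[keep],
                      clim.precip_mm[keep], clim.temp_c[keep]))
    year = np.concatenate([p[0] for p in parts])
    month = np.concatenate([p[1] for p in parts])
    precip = np.concatenate([p[2] for p in parts])
    temp = np.concatenate([p[3] for p in parts])
    return MonthlyClimate(year, month, precip, temp)  # validates contiguity


def decadal_means(annual: Mapping[int, float],
                  anchor_year: int | None = None) -> pd.DataFrame:
    """Aggregate annual landscape means to decadal means.

    Decades are anchored at ``anchor_year`` (default: the first year
    present); incomplete decades are averaged over the available years,
    empty ones omitted.
    """
    if not annual:
        raise ValueError("no annual values")
    years = sorted(annual)
    if anchor_year is None:
        anchor_year = years[0]
    rows = {}
    for y in years:
        d0 = anchor_year + ((y - anchor_year) // 10) * 10
        rows.setdefault(d0, []).append(annual[y])
    table = pd.DataFrame({
        "decade_start": list(rows),
        "decade_mid": [d + 4.5 for d in rows],
        "mean": [float(np.mean(v)) for v in rows.values()],
        "n_years": [len(v) for v in rows.values()],
    }).sort_values("decade_start", ignore_index=True)
    return table


def trend_regression(decadal: pd.DataFrame) -> dict:
    """OLS of decadal mean abundance on decade midpoint year.

    Slope is per calendar year (as decade midpoints are in years).
    """
    if len(decadal) < 3:
        raise ValueError("need at least 3 decades")
    x = decadal["decade_mid"].to_numpy(float)
    y = decadal["mean"].to_numpy(float)
    res = stats.linregress(x, y)
    n = len(x)
    r2 = float(res.rvalue ** 2)
    f = r2 / (1 - r2) * (n - 2) if r2 < 1 else float("inf")
    return {"slope": float(res.slope), "se": float(res.stderr),
            "intercept": float(res.intercept), "r_squared": r2,
            "f_stat": float(f), "p_value": float(res.pvalue), "n": n}


def thirty_year_change(abundance_by_year: Mapping[int, np.ndarray],
                       baseline_years: tuple[int, int],
                       future_years: tuple[int, int]
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cell 30-year mean abundance maps and the landscape change.

    ``abundance_by_year`` maps abundance year (already offset: summer
    WTD of year t drives abundance in year t+1) to a cell grid.  The
    landscape percent change compares the aggregate means of the two
    windows, 100 * (baseline - future) / baseline; note this is the
    change OF the landscape mean, not the mean of per-cell changes.
    """
    def window_mean(years):
        y0, y1 = years
        grids = [abundance_by_year[y] for y in range(y0, y1 + 1)
                 if y in abundance_by_year]
        if len(grids) != y1 - y0 + 1:
            raise ValueError(f"window {y0}-{y1} not fully covered")
        return np.nanmean(np.stack(grids), axis=0)

    base = window_mean(baseline_years)
    fut = window_mean(future_years)
    base_mean = float(np.nanmean(base))
    fut_mean = float(np.nanmean(fut))
    pct = 100.0 * (base_mean - fut_mean) / base_mean
    return base, fut, pct


def project_70yr(abundance: float, slope_per_year: float) -> float:
    """Abundance 70 years on from the survey midpoint, floored at 0."""
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    return max(abundance + 70.0 * slope_per_year, 0.0)
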