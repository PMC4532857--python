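"""Monthly blanket-bog water-table simulator.

A one-dimensional peat column is driven by monthly precipitation and
temperature.  Each month the column gains water from precipitation and
loses it through runoff (steeper or drier-surfaced columns shed more or
less of the incoming rain) and evapotranspiration (limited by vegetation
rooting depth once the water table falls below the root zone).  The
running water *deficit* — millimetres of water missing relative to a
saturated column — is converted to a water-table depth (WTD, cm; positive
below the surface, negative for ponding) through a depth-dependent
specific-yield profile: the loose upper acrotelm drains easily, the dense
catotelm barely at all.

Long-term mean WTD sets the plant-functional-type (PFT) mix, which feeds
back on evapotranspiration through rooting depth.  A spin-up under
repeated baseline climate equilibrates water storage and the PFT mix
before any scenario run.

All tunable constants live in :class:`HydroParams`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HydroParams",
    "MonthlyClimate",
    "TopographicCell",
    "PeatColumnState",
    "WTDSeries",
    "ValidationStats",
    "specific_yield",
    "deficit_from_wtd",
    "wtd_from_deficit",
    "runoff",
    "potential_et",
    "actual_et",
    "update_pft",
    "step_month",
    "run_spinup",
    "simulate",
    "summer_mean_wtd",
    "summer_min_wtd",
    "calibrate_offset",
    "validate",
]

SUMMER_MONTHS = (7, 8, 9)  # Jul-Sep: the cranefly desiccation window


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HydroParams:
    """All constants of the water-balance model, in one place.

    Units: depths in cm, water fluxes in mm/month, temperatures in degC.
    """

    # specific yield s(z) = max(s_min, s0 * exp(-z / z_s))
    s0: float = 0.5          # drainable porosity at the surface
    s_min: float = 0.05      # catotelm floor
    z_s: float = 20.0        # e-folding depth (cm)

    # runoff coefficient c = clip(c0 + a*tan(slope), 0, c_max) * exp(-max(wtd,0)/w0)
    c0: float = 0.1
    a: float = 1.0
    c_max: float = 0.95
    w0: float = 15.0         # wetness e-folding (cm)

    # potential evapotranspiration (temperature index)
    pet_coeff: float = 6.0   # mm per degC of adjusted temperature per month
    lapse_per_m: float = 0.006      # degC lost per metre climbed
    aspect_amp_c: float = 0.5       # south-facing bonus (degC)
    ref_elevation_m: float = 400.0  # elevation of the driving climate grid square
    latitude_deg: float = 54.0      # daylength modifier latitude

    # actual ET limiter
    z_root_wet: float = 5.0   # rooting depth of wet-adapted PFTs (cm)
    z_root_dry: float = 30.0  # rooting depth of shrubby PFTs (cm)
    z_e: float = 20.0         # decay scale below the root zone (cm)

    # PFT rule: pft_wet = 1 / (1 + exp((mean_wtd - pft_mid)/pft_scale))
    pft_mid: float = 10.0
    pft_scale: float = 5.0
    pft_memory_months: int = 60  # trailing-mean window for PFT updates

    # column geometry
    ponding_cap_cm: float = 5.0   # max surface ponding before spill
    column_depth_cm: float = 200.0  # static peat column (peat growth out of scope)

    # spin-up
    spinup_tol_cm: float = 0.1
    spinup_max_cycles: int = 200

    # sub-steps per month (quasi-daily): keeps the explicit update inside
    # the monotone (comparison-principle) regime of the water balance
    substeps: int = 30

    @property
    def ponding_floor_mm(self) -> float:
        """Deficit floor: ponded water uses storage coefficient 1."""
        return -10.0 * self.ponding_cap_cm

    @property
    def z_break_cm(self) -> float:
        """Depth where the exponential profile hits ``s_min``."""
        return self.z_s * math.log(self.s0 / self.s_min)


DEFAULT_PARAMS = HydroParams()


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MonthlyClimate:
    """A contiguous monthly climate series.

    ``year``/``month`` are integer arrays, ``precip_mm`` total monthly
    precipitation, ``temp_c`` mean monthly temperature.
    """

    year: np.ndarray
    month: np.ndarray
    precip_mm: np.ndarray
    temp_c: np.ndarray

    def __post_init__(self):
        for name in ("year", "month", "precip_mm", "temp_c"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.year)
        if not (len(self.month) == len(self.precip_mm) == len(self.temp_c) == n):
            raise ValueError("climate fields must have equal length")
        if n == 0:
            raise ValueError("empty climate series")
        if np.any(self.precip_mm < 0):
            raise ValueError("negative precipitation")
        if np.any((self.month < 1) | (self.month > 12)):
            raise ValueError("month outside 1..12")
        idx = self.year * 12 + (self.month - 1)
        if np.any(np.diff(idx) != 1):
            gap = int(np.argmax(np.diff(idx) != 1))
            raise ValueError(
                f"gap in climate series after {int(self.year[gap])}-{int(self.month[gap]):02d}"
            )

    def __len__(self) -> int:
        return len(self.year)

    def __iter__(self):
        for i in range(len(self)):
            yield (int(self.year[i]), int(self.month[i]),
                   float(self.precip_mm[i]), float(self.temp_c[i]))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "MonthlyClimate":
        rec = list(records)
        y, m, p, t = zip(*rec)
        return cls(np.array(y), np.array(m), np.array(p, float), np.array(t, float))

    def slice_years(self, first: int, last: int) -> "MonthlyClimate":
        keep = (self.year >= first) & (self.year <= last)
        return MonthlyClimate(self.year[keep], self.month[keep],
                              self.precip_mm[keep], self.temp_c[keep])


@dataclass(frozen=True)
class TopographicCell:
    """Slope (deg), aspect (deg clockwise from north) and elevation (m)."""

    slope_deg: float = 0.0
    aspect_deg: float = 0.0
    elevation_m: float = 400.0

    def __post_init__(self):
        if self.slope_deg < 0 or self.slope_deg >= 90:
            raise ValueError("slope_deg must be in [0, 90)")
        object.__setattr__(self, "aspect_deg",
                           0.0 if self.slope_deg == 0 else self.aspect_deg % 360.0)


@dataclass(frozen=True)
class PeatColumnState:
    """Hydrological state of the column at the end of a month."""

    deficit_mm: float
    wtd_cm: float
    pft_wet_frac: float
    mean_wtd_cm: float

    def __post_init__(self):
        if not 0.0 <= self.pft_wet_frac <= 1.0:
            raise ValueError("pft_wet_frac outside [0, 1]")


@dataclass(frozen=True)
class WTDSeries:
    """Monthly WTD aligned 1:1 with the driving climate."""

    year: np.ndarray
    month: np.ndarray
    wtd_cm: np.ndarray

    def __post_init__(self):
        for name in ("year", "month", "wtd_cm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not len(self.year) == len(self.month) == len(self.wtd_cm):
            raise ValueError("series fields must have equal length")

    def __len__(self) -> int:
        return len(self.year)

    def value(self, year: int, month: int) -> float:
        hit = (self.year == year) & (self.month == month)
        if not hit.any():
            raise ValueError(f"month {year}-{month:02d} not in series")
        return float(self.wtd_cm[hit][0])

    def shifted(self, offset_cm: float) -> "WTDSeries":
        return WTDSeries(self.year, self.month, self.wtd_cm + offset_cm)


@dataclass(frozen=True)
class ValidationStats:
    mean_obs_cm: float
    mean_pred_cm: float
    slope: float
    intercept: float
    r_squared: float
    n_months: int


# --------------------------------------------------------------------------
# water-balance pieces
# --------------------------------------------------------------------------

def specific_yield(depth_cm, params: HydroParams = DEFAULT_PARAMS):
    """Drainable pore fraction s(z) at depth ``depth_cm`` below the surface.

    Non-increasing in depth: ``max(s_min, s0 * exp(-z/z_s))``.
    """
    z = np.asarray(depth_cm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth_cm must be non-negative")
    s = np.maximum(params.s_min, params.s0 * np.exp(-z / params.z_s))
    return float(s) if np.isscalar(depth_cm) else s


def deficit_from_wtd(wtd_cm: float, params: HydroParams = DEFAULT_PARAMS) -> float:
    """Water deficit (mm) holding the table at ``wtd_cm``.

    Integrates the specific-yield profile analytically; ponded water
    (wtd < 0) has unit storage coefficient.
    """
    w = float(wtd_cm)
    if w < 0:
        return 10.0 * w
    zb = params.z_break_cm
    s0, zs, smin = params.s0, params.z_s, params.s_min
    if w <= zb:
        return 10.0 * s0 * zs * (1.0 - math.exp(-w / zs))
    d_break = s0 * zs * (1.0 - math.exp(-zb / zs))
    return 10.0 * (d_break + smin * (w - zb))


def wtd_from_deficit(deficit_mm: float, params: HydroParams = DEFAULT_PARAMS) -> float:
    """Invert :func:`deficit_from_wtd` (exact analytic inverse)."""
    d = float(deficit_mm)
    floor = params.ponding_floor_mm
    if d < floor:
        logger.warning("deficit %.2f mm below ponding floor %.2f mm; clamped", d, floor)
        d = floor
    if d < 0:
        return d / 10.0
    s0, zs, smin = params.s0, params.z_s, params.s_min
    zb = params.z_break_cm
    d_break = 10.0 * s0 * zs * (1.0 - math.exp(-zb / zs))
    if d <= d_break:
        return -zs * math.log(1.0 - d / (10.0 * s0 * zs))
    return zb + (d - d_break) / (10.0 * smin)


def runoff(precip_mm: float, slope_deg: float, antecedent_wtd_cm: float,
           params: HydroParams = DEFAULT_PARAMS) -> float:
    """Runoff (mm) from this month's rain.

    The runoff coefficient grows with slope and shrinks as the antecedent
    water table deepens (a dry column absorbs more of the rain).
    """
    if precip_mm < 0:
        raise ValueError("precip_mm must be non-negative")
    c_topo = min(max(params.c0 + params.a * math.tan(math.radians(slope_deg)), 0.0),
                 params.c_max)
    c = c_topo * math.exp(-max(antecedent_wtd_cm, 0.0) / params.w0)
    return c * precip_mm


def _daylength_factor(month: int, latitude_deg: float) -> float:
    """Relative daylight hours for the month, normalised to annual mean 1."""
    # mid-month solar declination (degrees)
    day_of_year = 30.4 * (month - 0.5)
    decl = math.radians(-23.44 * math.cos(2.0 * math.pi * (day_of_year + 10.0) / 365.0))
    lat = math.radians(latitude_deg)
    x = max(-1.0, min(1.0, -math.tan(lat) * math.tan(decl)))
    return math.degrees(math.acos(x)) / 90.0  # annual mean is 1 at any latitude


def potential_et(temp_c: float, month: int, elevation_m: float, aspect_deg: float,
                 latitude_deg: float | None = None,
                 params: HydroParams = DEFAULT_PARAMS,
                 slope_deg: float | None = None) -> float:
    """Monthly potential evapotranspiration (mm) from a temperature index.

    Temperature is first adjusted for the cell: a lapse of 0.6 degC per
    100 m relative to the climate grid square, and a cosine aspect term
    making south-facing slopes warmer (northern hemisphere).  Flat cells
    (``slope_deg == 0``) take no aspect modifier.  PET is zero in frozen
    months (adjusted T <= 0).
    """
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    if latitude_deg is None:
        latitude_deg = params.latitude_deg
    aspect_term = params.aspect_amp_c * math.cos(math.radians(aspect_deg - 180.0))
    if slope_deg is not None and slope_deg == 0.0:
        aspect_term = 0.0
    t_adj = (temp_c - params.lapse_per_m * (elevation_m - params.ref_elevation_m)
             + aspect_term)
    if t_adj <= 0.0:
        return 0.0
    return params.pet_coeff * t_adj * _daylength_factor(month, latitude_deg)


def actual_et(pet_mm: float, wtd_cm: float, pft_wet_frac: float,
              params: HydroParams = DEFAULT_PARAMS) -> float:
    """Actual ET (mm): PET throttled once the table drops below the roots."""
    if pet_mm < 0:
        raise ValueError("pet_mm must be non-negative")
    z_root = (pft_wet_frac * params.z_root_wet
              + (1.0 - pft_wet_frac) * params.z_root_dry)
    if wtd_cm <= z_root:
        g = 1.0
    else:
        g = math.exp(-(wtd_cm - z_root) / params.z_e)
    return pet_mm * g


def update_pft(mean_wtd_cm: float, params: HydroParams = DEFAULT_PARAMS) -> float:
    """Wet-adapted PFT fraction from the long-term mean WTD (logistic)."""
    x = (mean_wtd_cm - params.pft_mid) / params.pft_scale
    # guard overflow for extreme means
    if x > 500:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


# --------------------------------------------------------------------------
# stepping
# --------------------------------------------------------------------------

def step_month(state: PeatColumnState, clim: tuple, topo: TopographicCell,
               params: HydroParams = DEFAULT_PARAMS,
               return_fluxes: bool = False):
    """Advance the column one month.

    ``clim`` is a ``(year, month, precip_mm, temp_c)`` record.  Mass
    balance ``precip = delta_storage + runoff + AET + spill`` closes
    exactly (storage increase = deficit decrease).

    The monthly fluxes are applied in ``params.substeps`` equal
    sub-steps, re-evaluating the runoff coefficient and the ET throttle
    at the evolving water-table depth, so the discrete update stays
    within the monotone regime of the underlying (cooperative)
    continuous-time balance.
    """
    _, month, precip, temp = clim
    pet = potential_et(temp, int(month), topo.elevation_m, topo.aspect_deg,
                       params=params, slope_deg=topo.slope_deg)
    nsub = max(1, params.substeps)
    p_sub = precip / nsub
    pet_sub = pet / nsub
    deficit = state.deficit_mm
    wtd = state.wtd_cm
    r_total = 0.0
    aet_total = 0.0
    spill = 0.0
    floor = params.ponding_floor_mm
    for _k in range(nsub):
        r = runoff(p_sub, topo.slope_deg, wtd, params)
        aet = actual_et(pet_sub, wtd, state.pft_wet_frac, params)
        deficit = deficit - p_sub + r + aet
        if deficit < floor:
            spill += floor - deficit
            deficit = floor
        wtd = wtd_from_deficit(deficit, params)
        r_total += r
        aet_total += aet
    r, aet = r_total, aet_total
    # trailing mean drives the PFT mix with a multi-year memory
    alpha = 1.0 / params.pft_memory_months
    mean_wtd = (1.0 - alpha) * state.mean_wtd_cm + alpha * wtd
    new = PeatColumnState(deficit_mm=deficit, wtd_cm=wtd,
                          pft_wet_frac=update_pft(mean_wtd, params),
                          mean_wtd_cm=mean_wtd)
    if return_fluxes:
        fluxes = {"precip": precip, "runoff": r, "aet": aet, "spill": spill,
                  "dstorage": state.deficit_mm - deficit}
        return new, wtd, fluxes
    return new, wtd


def _initial_state(params: HydroParams) -> PeatColumnState:
    return PeatColumnState(deficit_mm=0.0, wtd_cm=0.0, pft_wet_frac=1.0,
                           mean_wtd_cm=0.0)


def run_spinup(baseline_climate: MonthlyClimate, topo: TopographicCell,
               params: HydroParams = DEFAULT_PARAMS,
               max_cycles: int | None = None) -> PeatColumnState:
    """Equilibrate water storage and PFTs under repeated baseline climate.

    The baseline is cycled until the annual-mean WTD moves less than
    ``spinup_tol_cm`` between cycles (or ``max_cycles`` is hit, with a
    warning).  Deterministic.
    """
    if len(baseline_climate) < 12:
        raise ValueError("spin-up climate must cover at least one full year")
    if max_cycles is None:
        max_cycles = params.spinup_max_cycles
    state = _initial_state(params)
    prev_mean = math.inf
    for cycle in range(max_cycles):
        wtds = []
        for rec in baseline_climate:
            state, w = step_month(state, rec, topo, params)
            wtds.append(w)
        cycle_mean = float(np.mean(wtds))
        # PFTs re-set from this cycle's mean (long-term average rule)
        state = replace(state, mean_wtd_cm=cycle_mean,
                        pft_wet_frac=update_pft(cycle_mean, params))
        if abs(cycle_mean - prev_mean) < params.spinup_tol_cm:
            return state
        prev_mean = cycle_mean
    logger.warning("spin-up did not converge within %d cycles (last mean %.2f cm)",
                   max_cycles, prev_mean)
    return state


def simulate(climate: MonthlyClimate, topo: TopographicCell,
             spinup_climate: MonthlyClimate | None = None,
             params: HydroParams = DEFAULT_PARAMS,
             initial_state: PeatColumnState | None = None) -> WTDSeries:
    """Spin up, then produce one WTD per month of ``climate``.

    ``spinup_climate`` defaults to the first full years of ``climate``
    (at most five).  Pass ``initial_state`` to skip the spin-up, e.g. to
    stream a long run in chunks.
    """
    if initial_state is None:
        if spinup_climate is None:
            n_years = min(5, len(climate) // 12)
            if n_years < 1:
                raise ValueError("climate too short to derive a spin-up baseline")
            spinup_climate = MonthlyClimate(
                climate.year[: 12 * n_years], climate.month[: 12 * n_years],
                climate.precip_mm[: 12 * n_years], climate.temp_c[: 12 * n_years])
        state = run_spinup(spinup_climate, topo, params)
    else:
        state = initial_state
    out = np.empty(len(climate))
    for i, rec in enumerate(climate):
        state, out[i] = step_month(state, rec, topo, params)
    series = WTDSeries(climate.year.copy(), climate.month.copy(), out)
    object.__setattr__(series, "final_state", state)
    return series


# --------------------------------------------------------------------------
# summaries, calibration, validation
# --------------------------------------------------------------------------

def _summer_values(series: WTDSeries, sampling_year: int) -> np.ndarray:
    """Jul-Sep WTDs of the year preceding sampling."""
    year = sampling_year - 1
    vals = []
    for m in SUMMER_MONTHS:
        hit = (series.year == year) & (series.month == m)
        if not hit.any():
            raise ValueError(f"series lacks {year}-{m:02d} (needed for "
                             f"sampling year {sampling_year})")
        vals.append(series.wtd_cm[hit][0])
    return np.array(vals, dtype=float)


def summer_mean_wtd(series: WTDSeries, sampling_year: int) -> float:
    """Mean Jul-Sep WTD of the year before ``sampling_year``."""
    return float(np.mean(_summer_values(series, sampling_year)))


def summer_min_wtd(series: WTDSeries, sampling_year: int) -> float:
    """Shallowest (numerically smallest) Jul-Sep WTD of the preceding year."""
    return float(np.min(_summer_values(series, sampling_year)))


def calibrate_offset(auto_series: WTDSeries, manual_series: WTDSeries) -> float:
    """Constant bias correction (cm) for an automatic dipwell.

    ``mean(manual) - mean(auto)`` over the overlapping months; e.g. an
    automatic logger reading 2.8 cm too deep yields -2.8 (apply by adding
    the offset to every automatic reading).
    """
    akey = set(zip(auto_series.year.tolist(), auto_series.month.tolist()))
    mkey = set(zip(manual_series.year.tolist(), manual_series.month.tolist()))
    overlap = akey & mkey
    if not overlap:
        raise ValueError("no overlapping months between series")
    a = np.array([auto_series.value(y, m) for (y, m) in sorted(overlap)])
    b = np.array([manual_series.value(y, m) for (y, m) in sorted(overlap)])
    return float(b.mean() - a.mean())


def validate(observed: WTDSeries, predicted: WTDSeries) -> ValidationStats:
    """Regress observed on predicted WTD over paired months."""
    key_obs = list(zip(observed.year.tolist(), observed.month.tolist()))
    key_pred = list(zip(predicted.year.tolist(), predicted.month.tolist()))
    common = sorted(set(key_obs) & set(key_pred))
    if len(common) < 3:
        raise ValueError("need at least 3 paired months")
    obs = np.array([observed.value(y, m) for (y, m) in common])
    pred = np.array([predicted.value(y, m) for (y, m) in common])
    if np.ptp(pred) == 0:
        raise ValueError("predictions have zero variance; regression undefined")
    from scipy import stats

    res = stats.linregress(pred, obs)
    return ValidationStats(
        mean_obs_cm=float(obs.mean()), mean_pred_cm=float(pred.mean()),
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), n_months=len(common))
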