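"""Readers, writers, configuration and the pipeline orchestrator.

CSV dialect: comma separated, '.' decimal, UTF-8 headers.  Rasters are
Esri ASCII grids (NODATA_value honoured bit-exactly) or GeoTIFFs
(ModelPixelScale / ModelTiepoint / GDAL nodata tags, read and written
via tifffile).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hydro import HydroParams, MonthlyClimate, WTDSeries
from .landscape import DEMGrid

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_climate_csv",
    "write_climate_csv",
    "read_dipwell_csv",
    "read_cranefly_csv",
    "read_bird_csv",
    "read_raster",
    "write_raster",
    "run_pipeline",
]

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


# --------------------------------------------------------------------------
# tabular I/O
# --------------------------------------------------------------------------

def read_climate_csv(path) -> MonthlyClimate:
    """Read a year,month,precip_mm,temp_c series; gaps are an error."""
    df = pd.read_csv(path)
    required = {"year", "month", "precip_mm", "temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric {col!r} at row {row}")
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 2
            raise ValueError(f"{path}: missing {col!r} at row {row}")
    try:
        return MonthlyClimate(df["year"].to_numpy(int), df["month"].to_numpy(int),
                              df["precip_mm"].to_numpy(float),
                              df["temp_c"].to_numpy(float))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_climate_csv(climate: MonthlyClimate, path) -> None:
    pd.DataFrame({"year": climate.year, "month": climate.month,
                  "precip_mm": climate.precip_mm,
                  "temp_c": climate.temp_c}).to_csv(path, index=False)


def read_dipwell_csv(path, well_id: str | None = None) -> WTDSeries:
    """Read dipwell observations (year, month, wtd_cm[, well_id])."""
    df = pd.read_csv(path)
    if "date" in df.columns and "year" not in df.columns:
        dt = pd.to_datetime(df["date"])
        df["year"], df["month"] = dt.dt.year, dt.dt.month
    required = {"year", "month", "wtd_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if well_id is not None and "well_id" in df.columns:
        df = df[df["well_id"].astype(str) == str(well_id)]
    df = df.sort_values(["year", "month"])
    return WTDSeries(df["year"].to_numpy(int), df["month"].to_numpy(int),
                     df["wtd_cm"].to_numpy(float))


def read_cranefly_csv(path) -> pd.DataFrame:
    """Quartet table: site, region, year, count, wtd_cm[, moisture, drained]."""
    df = pd.read_csv(path)
    required = {"site", "region", "year", "count", "wtd_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_bird_csv(path) -> pd.DataFrame:
    """Bird table: square_id, easting, northing, species, count_1990, count_2004."""
    df = pd.read_csv(path)
    required = {"square_id", "easting", "northing", "species",
                "count_1990", "count_2004"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# raster I/O
# --------------------------------------------------------------------------

def _read_ascii_grid(path: Path) -> DEMGrid:
    header: dict = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(rows, dtype=float)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    grid = DEMGrid(elevation=data, cell_size=header["cellsize"],
                   origin=(header.get("xllcorner", 0.0),
                           header.get("yllcorner", 0.0)),
                   nodata=nodata)
    return grid


def _write_ascii_grid(grid: DEMGrid, path: Path, values: np.ndarray | None = None) -> None:
    data = grid.elevation if values is None else np.asarray(values, float)
    data = np.where(np.isfinite(data), data, grid.nodata)
    ny, nx = data.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\nyllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: Path) -> DEMGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    scale = tags.get(_TAG_PIXEL_SCALE, (1.0, 1.0, 0.0))
    tie = tags.get(_TAG_TIEPOINT, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
    nodata = float(tags.get(_TAG_GDAL_NODATA, -9999.0))
    cell = float(scale[0])
    ny = data.shape[0]
    # tiepoint anchors the top-left corner; DEMGrid origin is the SW corner
    x0 = float(tie[3])
    y0 = float(tie[4]) - ny * cell
    return DEMGrid(elevation=data, cell_size=cell, origin=(x0, y0), nodata=nodata)


def write_raster(grid: DEMGrid, path, values: np.ndarray | None = None) -> None:
    """Write elevation (or ``values``) as ASCII grid or GeoTIFF by suffix."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt", ".grd"):
        _write_ascii_grid(grid, path, values)
        return
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = grid.elevation if values is None else np.asarray(values, float)
        data = np.where(np.isfinite(data), data, grid.nodata).astype(np.float64)
        ny = data.shape[0]
        top = grid.origin[1] + ny * grid.cell_size
        extratags = [
            (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], top, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
        ]
        tifffile.imwrite(path, data, extratags=extratags)
        return
    raise ValueError(f"unknown raster format: {path.suffix}")


def read_raster(path) -> DEMGrid:
    """Read an Esri ASCII grid or GeoTIFF into a :class:`DEMGrid`."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt", ".grd"):
        return _read_ascii_grid(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format: {path.suffix}")


# --------------------------------------------------------------------------
# configuration and manifest
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run settings; unknown YAML keys are rejected."""

    seed: int = 0
    out_dir: str = "bogcascade_out"
    log_level: str = "INFO"
    bin_scheme: str = "landscape"
    dem_nx: int = 40
    dem_ny: int = 40
    climate_years: int = 15
    annual_rain_mm: float = 2071.0
    rain_trend_per_year: float = 0.0
    temp_trend_per_year: float = 0.0
    hydro: dict = field(default_factory=dict)   # HydroParams overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hydro_params(self) -> HydroParams:
        known = {f.name for f in fields(HydroParams)}
        unknown = set(self.hydro) - known
        if unknown:
            raise ValueError(f"unknown hydro constants: {sorted(unknown)}")
        return HydroParams(**self.hydro)


@dataclass
class RunManifest:
    """Provenance record written alongside every output set."""

    config_hash: str
    version: str
    seed: int
    inputs: dict
    timestamp: str

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def create(cls, config: PipelineConfig, inputs: dict | None = None) -> "RunManifest":
        blob = json.dumps(asdict(config), sort_keys=True).encode()
        digests = {}
        for name, p in (inputs or {}).items():
            digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        return cls(config_hash=hashlib.sha256(blob).hexdigest()[:16],
                   version=__version__, seed=config.seed, inputs=digests,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full synthetic cascade and write outputs + manifest.

    Stages: synthetic inputs -> per-bin water-table simulation ->
    cranefly GLM fit on synthetic quartets -> landscape abundance ->
    bird GLM and projection summary.  Deterministic for a fixed config.
    """
    import pandas as pd

    from . import synth, trophic
    from .landscape import BinScheme, aggregate_cells, project_landscape

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.hydro_params()
    rng = np.random.default_rng(config.seed)

    stage = "synth"
    try:
        dem = synth.make_dem(config.dem_nx, config.dem_ny, seed=config.seed)
        climate = synth.make_climate(config.annual_rain_mm,
                                     years=config.climate_years,
                                     seed=config.seed + 1,
                                     rain_trend_per_year=config.rain_trend_per_year,
                                     temp_trend_per_year=config.temp_trend_per_year)
        write_raster(dem, out / "dem.asc")
        write_climate_csv(climate, out / "climate.csv")

        stage = "landscape"
        scheme = (BinScheme.birds() if config.bin_scheme == "birds"
                  else BinScheme.landscape())
        proj = project_landscape(dem, scheme, climate, params)
        sampling_year = int(climate.year[-1])
        wtd_grid = proj.summer_wtd_grid(sampling_year)
        write_raster(dem, out / "wtd_summer.asc", values=wtd_grid)

        stage = "cranefly"
        wtd_samples = rng.uniform(0.0, 15.0, 128)
        region_pool = np.array(sorted(trophic.REGIONS), dtype=object)
        regions = region_pool[np.arange(128) % 3]
        counts = synth.make_cranefly_counts(wtd_samples, regions,
                                            seed=config.seed + 2)
        fit = trophic.fit_negbin_glm(
            counts, pd.DataFrame({"wtd_cm": wtd_samples, "region": regions}))
        fit.coef.to_csv(out / "cranefly_glm.csv")

        stage = "abundance"
        abund = proj.abundance_grid(sampling_year,
                                    lambda w: trophic.predict_cranefly(w, fit))
        write_raster(dem, out / "cranefly_abundance.asc", values=abund)
        landscape_mean = aggregate_cells(abund)

        stage = "birds"
        c90 = rng.uniform(0, landscape_mean * 2, 200)
        c04 = c90 * rng.uniform(0.8, 1.2, 200)
        y90, y04 = synth.make_bird_counts(c90, c04, -1.5, 0.02,
                                          seed=config.seed + 3)
        birds = pd.DataFrame({"species": "dunlin", "count_1990": y90,
                              "count_2004": y04, "cranefly_1990": c90,
                              "cranefly_2004": c04})
        bird_fit = trophic.fit_bird_glm(birds, "dunlin", scope="pooled")
        base, fut, pct = trophic.project_birds(bird_fit, landscape_mean,
                                               0.7 * landscape_mean)
        summary = pd.DataFrame([{"landscape_cranefly_mean": landscape_mean,
                                 "bird_baseline": base, "bird_future": fut,
                                 "bird_pct_change": pct}])
        summary.to_csv(out / "summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest.create(config)
    manifest.write(out / "manifest.json")
    return manifest
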