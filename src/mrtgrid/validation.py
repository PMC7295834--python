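"""Validation of model-based MRT against station radiation observations.

Radiation monitoring stations (e.g. the Baseline Surface Radiation Network)
measure the observed counterparts of the model inputs: direct-normal
irradiance, diffuse and upwelling solar flux, and down- and upwelling
thermal flux.  MRT is computed on both sides with the same body model, both
series are averaged in synoptic 3-h windows (model/observation agreement is
markedly better for time-averaged radiation), and three metrics summarize
the comparison:

    R²   = cov(m, o)² / (var(m) · var(o))     — correlation strength
    bias = Σ(mᵢ − oᵢ)/n                       — systematic offset
    RMSE = sqrt(Σ(mᵢ − oᵢ)²/n)                — typical deviation

Station files use a plain TSV dialect defined by this package (see
:func:`read_station_tsv`); native archive formats are out of scope.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import solar
from .mrt import HumanConfig, compute_mrt, projection_factor

__all__ = [
    "STATION_COLUMNS",
    "MISSING_SENTINEL",
    "StationSeries",
    "read_station_tsv",
    "write_station_tsv",
    "window_average",
    "station_mrt",
    "compare",
    "extract_model_cell",
    "validate_stations",
    "summarize_report",
]

#: Flux columns of the station TSV dialect, W m⁻².
STATION_COLUMNS = ("dni", "s_diffuse", "s_up", "l_dn", "l_up")

#: Sentinel written/read for missing values.
MISSING_SENTINEL = -999.0


@dataclass
class StationSeries:
    """A station's metadata plus its timestamped flux observations.

    ``data`` is indexed by strictly increasing UTC timestamps with the five
    columns of :data:`STATION_COLUMNS`; missing values are NaN.
    """

    station_id: str
    latitude: float
    longitude: float
    elevation: float = 0.0
    data: pd.DataFrame = dc_field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError("station latitude outside [-90, 90]")
        if len(self.data):
            if not self.data.index.is_monotonic_increasing \
                    or self.data.index.has_duplicates:
                raise ValueError("timestamps must be strictly increasing")
            vals = self.data[list(STATION_COLUMNS)].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValueError("fluxes must be >= 0 or missing")


def read_station_tsv(path) -> StationSeries:
    """Read the station TSV dialect.

    Format: ``#``-prefixed header lines ``# key: value`` for station_id,
    latitude, longitude, elevation, then a tab-separated table with a
    ``time`` column (ISO-8601 UTC) and the five flux columns; −999 marks
    missing values.
    """
    meta = {}
    body = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t",
                     parse_dates=["time"], index_col="time")
    if df.index.tz is not None:  # timestamps are UTC; keep the index naive
        df.index = df.index.tz_localize(None)
    df = df.replace(MISSING_SENTINEL, np.nan)
    return StationSeries(
        station_id=meta.get("station_id", Path(path).stem),
        latitude=float(meta.get("latitude", "nan")),
        longitude=float(meta.get("longitude", "0")),
        elevation=float(meta.get("elevation", "0")),
        data=df[list(STATION_COLUMNS)],
    )


def write_station_tsv(station: StationSeries, path) -> None:
    """Write a :class:`StationSeries` in the TSV dialect."""
    lines = [
        f"# station_id: {station.station_id}",
        f"# latitude: {station.latitude}",
        f"# longitude: {station.longitude}",
        f"# elevation: {station.elevation}",
    ]
    df = station.data[list(STATION_COLUMNS)].fillna(MISSING_SENTINEL)
    out = df.copy()
    out.insert(0, "time", df.index.strftime("%Y-%m-%dT%H:%M:%SZ"))
    lines.append("\t".join(out.columns))
    for row in out.itertuples(index=False):
        lines.append("\t".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def window_average(series: pd.DataFrame | pd.Series, width_h: int = 3,
                   min_valid_fraction: float = 0.5):
    """Average a series in synoptic windows aligned at 00 UTC.

    ``width_h`` must divide 24.  A window's mean is reported only if at
    least ``min_valid_fraction`` of its expected samples (inferred from the
    median time step) are valid; otherwise it is missing.  The output is
    indexed by window start.
    """
    if 24 % width_h != 0:
        raise ValueError("width_h must divide 24")
    df = series.to_frame() if isinstance(series, pd.Series) else series
    if len(df) < 2:
        raise ValueError("need at least two samples to infer the time step")
    step_s = pd.Series(df.index).diff().median().total_seconds()
    expected = int(round(width_h * 3600.0 / step_s))
    resampler = df.resample(f"{width_h}h", origin="start_day", label="left")
    means = resampler.mean()
    counts = resampler.count()
    means = means.where(counts >= min_valid_fraction * expected)
    if isinstance(series, pd.Series):
        return means.iloc[:, 0]
    return means


def station_mrt(station: StationSeries,
                config: HumanConfig | None = None) -> pd.DataFrame:
    """MRT and MRF series from observed radiation components.

    Applies the same body model as the gridded pipeline with observed fluxes:
    the measured direct-normal irradiance is used as I* directly (no zenith
    projection needed), and the projection factor comes from the
    instantaneous solar elevation at the station location and timestamp.
    Rows with any missing component yield missing MRT.

    Returns a DataFrame with ``mrt_C`` (degC) and ``mrf`` (W m⁻²).
    """
    config = config or HumanConfig()
    df = station.data
    times = df.index
    doy = (times.dayofyear - 1).to_numpy(dtype=float)
    hours = (times.hour + times.minute / 60.0
             + times.second / 3600.0).to_numpy(dtype=float)
    g = solar._g(doy, hours)
    tc = solar.time_correction(g)
    h = solar.solar_hour_angle(hours, station.longitude, tc)
    cz = solar.cos_solar_zenith(solar.solar_declination(g), station.latitude, h)
    fp = projection_factor(solar.solar_elevation(cz))

    valid = df[list(STATION_COLUMNS)].notna().all(axis=1).to_numpy()
    comp = {
        "l_dn": np.nan_to_num(df["l_dn"].to_numpy(dtype=float)),
        "l_up": np.nan_to_num(df["l_up"].to_numpy(dtype=float)),
        "s_diffuse": np.nan_to_num(df["s_diffuse"].to_numpy(dtype=float)),
        "s_up": np.nan_to_num(df["s_up"].to_numpy(dtype=float)),
        "i_star": np.nan_to_num(df["dni"].to_numpy(dtype=float)),
    }
    res = compute_mrt(comp, fp, config)
    mrt_c = np.where(valid, np.asarray(res.mrt_C), np.nan)
    mrf = np.where(valid, np.asarray(res.mrf_Wm2), np.nan)
    return pd.DataFrame({"mrt_C": mrt_c, "mrf": mrf}, index=times)


def compare(model: pd.Series, obs: pd.Series) -> dict:
    """R², bias and RMSE between paired model and observed series.

    Pairwise-complete over the two missing masks; bias and RMSE are in the
    series' units (model minus observation).  R² is reported as NaN when
    either series has zero variance (undefined correlation).
    """
    joined = pd.concat({"m": model, "o": obs}, axis=1, join="inner").dropna()
    n = len(joined)
    if n < 2:
        raise ValueError("need at least two paired valid values")
    m = joined["m"].to_numpy(dtype=float)
    o = joined["o"].to_numpy(dtype=float)
    err = m - o
    bias = float(err.mean())
    rmse = float(math.sqrt((err ** 2).mean()))
    var_m = float(((m - m.mean()) ** 2).mean())
    var_o = float(((o - o.mean()) ** 2).mean())
    if var_m == 0.0 or var_o == 0.0:
        r2 = float("nan")
    else:
        cov = float(((m - m.mean()) * (o - o.mean())).mean())
        r2 = cov * cov / (var_m * var_o)
    return {"r_squared": r2, "bias": bias, "rmse": rmse, "n_pairs": n}


def extract_model_cell(model_ds: xr.Dataset, latitude: float,
                       longitude: float, var: str = "mrt") -> pd.Series:
    """Series of ``var`` at the grid cell nearest a station.

    Plain nearest-neighbour in latitude/longitude index space; exact
    midpoints break toward the lower index.  Stations outside the coordinate
    bounds are rejected.
    """
    latname = "latitude" if "latitude" in model_ds.coords else "lat"
    lonname = "longitude" if "longitude" in model_ds.coords else "lon"
    lats = np.asarray(model_ds[latname].values, dtype=float)
    lons = np.asarray(model_ds[lonname].values, dtype=float)
    if not (min(lats) <= latitude <= max(lats)):
        raise ValueError("station latitude outside grid bounds")
    lon_n = float(np.where(np.mod(longitude, 360.0) > 180.0,
                           np.mod(longitude, 360.0) - 360.0,
                           np.mod(longitude, 360.0)))
    lons_n = np.where(np.mod(lons, 360.0) > 180.0,
                      np.mod(lons, 360.0) - 360.0, np.mod(lons, 360.0))
    dlon = np.abs((lons_n - lon_n + 180.0) % 360.0 - 180.0)
    i_lat = int(np.argmin(np.abs(lats - latitude)))   # argmin: first = lower index
    i_lon = int(np.argmin(dlon))
    cell = model_ds[var].isel({latname: i_lat, lonname: i_lon})
    tname = "time" if "time" in model_ds.coords else "valid_time"
    return pd.Series(np.asarray(cell.values, dtype=float),
                     index=pd.DatetimeIndex(model_ds[tname].values))


def validate_stations(model_ds: xr.Dataset, stations: list[StationSeries],
                      width_h: int = 3,
                      config: HumanConfig | None = None) -> pd.DataFrame:
    """Per-station validation of model MRT (and MRF) against observations.

    For each station: compute observed MRT/MRF from the measured components,
    extract the model series at the nearest grid cell, window-average both
    sides, and evaluate the three metrics.  Returns one row per
    station × variable with columns r_squared, bias, rmse, n_pairs.
    """
    config = config or HumanConfig()
    # model timestamps label accumulation-interval ends; move them to the
    # interval midpoint so the synoptic windows cover the same physical time
    # as the instantaneous station samples
    half_dt = pd.Timedelta(
        seconds=float(model_ds.attrs.get("accumulation_seconds", 0.0)) / 2.0)
    rows = []
    for st in stations:
        obs = station_mrt(st, config)
        pairs = [("mrt", "mrt_C")]
        if "mrf" in model_ds.data_vars:
            pairs.append(("mrf", "mrf"))
        for model_var, obs_var in pairs:
            cell = extract_model_cell(model_ds, st.latitude, st.longitude,
                                      var=model_var)
            cell.index = cell.index - half_dt
            m = window_average(cell, width_h)
            o = window_average(obs[obs_var], width_h)
            metrics = compare(m, o)
            rows.append({"station": st.station_id, "variable": model_var,
                         **metrics})
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame, variable: str = "mrt") -> dict:
    """Headline summaries of a validation report for one variable.

    Emits both plausible definitions of the network-average bias: the mean
    of per-station biases (stations weighted equally) and the pair-count
    weighted pool of all windows.
    """
    sub = report[report["variable"] == variable]
    if not len(sub):
        raise ValueError(f"no rows for variable {variable!r}")
    w = sub["n_pairs"].to_numpy(dtype=float)
    return {
        "mean_station_bias": float(sub["bias"].mean()),
        "pooled_bias": float(np.average(sub["bias"], weights=w)),
        "mean_station_rmse": float(sub["rmse"].mean()),
        "min_r_squared": float(sub["r_squared"].min()),
        "n_stations": int(sub["station"].nunique()),
    }
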