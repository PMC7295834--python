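"""Gridded MRT pipeline: apply the scalar flux→MRT chain per time step.

Reads the five archived radiation fields on a regular latitude–longitude
grid, builds the mean-daytime zenith-cosine map for each accumulation
interval, derives the radiant components and evaluates the MRT equation
cell-wise.  The grid path is the scalar chain broadcast over arrays — it is
required (and tested) to agree with the pointwise scalar computation.

Conventions
-----------
* A timestamp labels the *end* of its accumulation interval: the cosine map
  for time t uses [t − Δt, t].  Set ``time_labels_start=True`` if your
  archive labels the start instead.
* ``flux_mode``: ``"accumulated"`` — each step holds energy (J m⁻²)
  accumulated over the preceding Δt (the per-step convention of hourly
  reanalysis archives); ``"cumulative"`` — energy since forecast start,
  de-accumulated by pairwise differencing (the first step is dropped);
  ``"mean"`` — already W m⁻².
* Longitudes are accepted in [0, 360) or (−180, 180] and normalized
  internally for the solar geometry; output coordinates are left untouched.
* Output is CF-flavoured NetCDF: MRT in degC, diagnostics optional.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from . import fluxes, solar
from .mrt import HumanConfig, compute_mrt, compute_mrt_shade, projection_factor

__all__ = [
    "SchemaError",
    "compute_mrt_field",
    "aggregate_daily_extremes",
    "climatological_mean",
    "read_fluxes",
    "write_dataset",
]

logger = logging.getLogger(__name__)

_FLUX_MODES = ("accumulated", "cumulative", "mean")


class SchemaError(ValueError):
    """Input dataset is missing variables/coordinates or is inconsistent."""


def _get_coord(ds: xr.Dataset, names: tuple) -> str:
    for n in names:
        if n in ds.coords or n in ds.dims:
            return n
    raise SchemaError(f"dataset lacks a coordinate among {names}")


def _normalize_lon(lon: np.ndarray) -> np.ndarray:
    lon = np.mod(np.asarray(lon, dtype=float), 360.0)
    return np.where(lon > 180.0, lon - 360.0, lon)


def _time_components(ts: pd.Timestamp) -> tuple[float, float]:
    """(0-based fractional day-of-year, fractional UTC hour) of a timestamp."""
    doy = float(ts.dayofyear - 1)
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0 \
        + ts.microsecond / 3.6e9
    return doy, hour


def compute_mrt_field(flux_ds: xr.Dataset,
                      accumulation_seconds: float,
                      config: HumanConfig | None = None,
                      flux_mode: str = "accumulated",
                      shade: bool = False,
                      cap_direct_normal: bool = True,
                      time_labels_start: bool = False,
                      var_map: dict | None = None,
                      diagnostics: bool = True) -> xr.Dataset:
    """Compute the MRT field from gridded archived fluxes.

    Parameters
    ----------
    flux_ds
        Dataset with the variables ``ssrd, ssr, fdir, strd, str`` (rename
        via ``var_map``: {canonical: actual}) on (time, latitude, longitude).
    accumulation_seconds
        Width Δt of the accumulation interval, seconds.
    config
        Human-body constants; defaults to the standard standing person.
    shade
        Compute the shaded MRT (direct beam removed) instead.
    cap_direct_normal
        Cap the direct-normal irradiance at the solar constant (default on).
    diagnostics
        Include ``mrf``, ``cos_zenith_bar`` and ``fp`` layers in the output.

    Returns
    -------
    xr.Dataset with ``mrt`` in degC on the input coordinates.
    """
    if flux_mode not in _FLUX_MODES:
        raise SchemaError(f"flux_mode must be one of {_FLUX_MODES}")
    if accumulation_seconds <= 0:
        raise SchemaError("accumulation_seconds must be positive")
    config = config or HumanConfig()
    var_map = var_map or {}

    names = {canon: var_map.get(canon, canon) for canon in fluxes.FLUX_NAMES}
    missing = [v for v in names.values() if v not in flux_ds.data_vars]
    if missing:
        raise SchemaError(f"dataset lacks flux variables: {missing}")

    tname = _get_coord(flux_ds, ("time", "valid_time"))
    latname = _get_coord(flux_ds, ("latitude", "lat"))
    lonname = _get_coord(flux_ds, ("longitude", "lon"))
    times = pd.DatetimeIndex(flux_ds[tname].values)
    lats = np.asarray(flux_ds[latname].values, dtype=float)
    lons_raw = np.asarray(flux_ds[lonname].values, dtype=float)
    lons = _normalize_lon(lons_raw)
    if np.any(np.abs(lats) > 90):
        raise SchemaError("latitude values outside [-90, 90]")

    if len(times) > 1:
        steps = np.diff(times.values).astype("timedelta64[s]").astype(float)
        if flux_mode != "mean" and not np.allclose(steps, accumulation_seconds):
            raise SchemaError(
                "time step does not match accumulation_seconds; "
                "Δt must be uniform within a file")

    dt_h = accumulation_seconds / 3600.0

    # De-accumulate to mean W m⁻² along time.
    field = {}
    if flux_mode == "cumulative":
        out_times = times[1:]
        for canon, actual in names.items():
            arr = np.asarray(flux_ds[actual].transpose(
                tname, latname, lonname).values, dtype=float)
            diff = np.diff(arr, axis=0)
            if canon in fluxes.SIGNED_FLUXES:
                field[canon] = diff / accumulation_seconds
                continue
            n_neg = int(np.count_nonzero(diff < 0))
            if n_neg:
                logger.warning("clipped %d negative de-accumulated values "
                               "in %s", n_neg, canon)
            field[canon] = np.clip(diff, 0.0, None) / accumulation_seconds
    else:
        out_times = times
        scale = 1.0 if flux_mode == "mean" else accumulation_seconds
        for canon, actual in names.items():
            arr = np.asarray(flux_ds[actual].transpose(
                tname, latname, lonname).values, dtype=float)
            if canon not in fluxes.SIGNED_FLUXES:
                arr = np.clip(arr, 0.0, None)
            field[canon] = arr / scale
    if len(out_times) == 0:
        raise SchemaError("no usable time steps after de-accumulation")

    lat2 = lats[:, None]
    lon2 = lons[None, :]
    shape = (len(out_times), len(lats), len(lons))
    mrt_c = np.empty(shape)
    mrf = np.empty(shape)
    czbar = np.empty(shape)
    fp_map = np.empty(shape)

    # Chunked streaming over time steps: one (lat, lon) slab in memory at a
    # time, so long series stay cheap.
    for it, ts in enumerate(out_times):
        end = ts + pd.Timedelta(seconds=accumulation_seconds) \
            if time_labels_start else ts
        doy, hour_end = _time_components(end)
        cz = np.asarray(solar.mean_daytime_cos_zenith(
            lat2, lon2, doy, hour_end - dt_h, hour_end), dtype=float)

        mean = {canon: field[canon][it] for canon in names}
        derived = fluxes.derive_components(mean)
        i_star = fluxes.direct_normal(
            derived["fdir"], cz,
            cap=fluxes.SOLAR_CONSTANT if cap_direct_normal else None)
        comp = {
            "l_dn": derived["strd"], "l_up": derived["l_up"],
            "s_diffuse": derived["s_diffuse"], "s_up": derived["s_up"],
            "i_star": i_star,
        }
        if config.fp_from_interval_mean:
            fp = projection_factor(solar.solar_elevation(cz))
        else:
            doy_i, hour_i = _time_components(end)
            g = solar._g(doy_i, hour_i)
            h = solar.solar_hour_angle(hour_i, lon2,
                                       solar.time_correction(g))
            cz_inst = solar.cos_solar_zenith(solar.solar_declination(g),
                                             lat2, h)
            fp = projection_factor(solar.solar_elevation(cz_inst))
        if shade:
            res = compute_mrt_shade(comp, config)
        else:
            res = compute_mrt(comp, fp, config)
        mrt_c[it] = res.mrt_C
        mrf[it] = res.mrf_Wm2
        czbar[it] = cz
        fp_map[it] = np.broadcast_to(np.asarray(res.fp), cz.shape)

    coords = {tname: out_times, latname: lats, lonname: lons_raw}
    dims = (tname, latname, lonname)
    out = xr.Dataset({"mrt": (dims, mrt_c)}, coords=coords)
    out["mrt"].attrs.update(units="degC", long_name="mean radiant temperature")
    if diagnostics:
        out["mrf"] = (dims, mrf)
        out["mrf"].attrs.update(units="W m**-2", long_name="mean radiant flux")
        out["cos_zenith_bar"] = (dims, czbar)
        out["cos_zenith_bar"].attrs.update(
            units="1", long_name="mean daytime cosine of solar zenith angle")
        out["fp"] = (dims, fp_map)
        out["fp"].attrs.update(units="1", long_name="surface projection factor")
    out.attrs.update(
        accumulation_seconds=float(accumulation_seconds),
        flux_mode=flux_mode,
        shade=int(shade),
        direct_normal_cap="solar_constant" if cap_direct_normal else "none",
        emissivity_body=config.emissivity_body,
        absorption_solar=config.absorption_solar,
        angle_factor=config.angle_factor,
        posture=config.posture,
    )
    out[latname].attrs.update(units="degrees_north", standard_name="latitude")
    out[lonname].attrs.update(units="degrees_east", standard_name="longitude")
    return out


def aggregate_daily_extremes(mrt_ds: xr.Dataset, var: str = "mrt") -> xr.Dataset:
    """Per-cell daily minimum and maximum over each UTC day.

    Each step is assigned to the UTC day containing its interval *midpoint*
    (timestamps label interval ends, so the 00:00 step belongs to the
    previous day).  Returns ``<var>_min``, ``<var>_max`` indexed by date,
    plus ``n_steps`` (steps contributing to each day) and ``complete_day``
    flagging days with the modal step count — partial days at series edges
    are flagged, not silently dropped.
    """
    tname = _get_coord(mrt_ds, ("time", "valid_time"))
    if mrt_ds.sizes.get(tname, 0) < 1:
        raise SchemaError("need at least one time step")
    times = pd.DatetimeIndex(mrt_ds[tname].values)
    dt_s = mrt_ds.attrs.get("accumulation_seconds")
    if dt_s is None:
        dt_s = (float(np.median(np.diff(times.values)
                                .astype("timedelta64[s]").astype(float)))
                if len(times) > 1 else 0.0)
    shifted = mrt_ds.assign_coords(
        {tname: times - pd.Timedelta(seconds=dt_s / 2.0)})
    grouped = shifted[var].groupby(tname + ".date")
    mins = grouped.min()
    maxs = grouped.max()
    counts = grouped.count()
    spatial = [d for d in counts.dims if d != "date"]
    n_steps = counts.max(dim=spatial) if spatial else counts
    if dt_s > 0:
        expected = int(round(86400.0 / dt_s))
    else:
        expected = int(n_steps.max())
    complete = n_steps == expected
    out = xr.Dataset({
        f"{var}_min": mins,
        f"{var}_max": maxs,
        "n_steps": n_steps,
        "complete_day": complete.astype("int8"),  # NetCDF3-safe flag
    })
    out["date"] = pd.DatetimeIndex([pd.Timestamp(d) for d in out["date"].values])
    incomplete = int((~complete).sum())
    if incomplete:
        logger.warning("%d partial day(s) flagged in daily extremes", incomplete)
    return out


def climatological_mean(daily_ds: xr.Dataset, months=None) -> xr.Dataset:
    """Arithmetic mean over selected days per cell.

    ``months`` is an iterable of month numbers (1–12) or None for all days.
    Cells missing on any selected day are missing in the mean (strict
    propagation).  An empty selection is an error.
    """
    sel = daily_ds
    if months is not None:
        months = list(months)
        mask = daily_ds["date"].dt.month.isin(months)
        sel = daily_ds.sel(date=mask)
    if sel.sizes.get("date", 0) == 0:
        raise ValueError("no days match the requested month selection")
    data_vars = [v for v in sel.data_vars
                 if v not in ("n_steps", "complete_day")]
    return sel[data_vars].mean(dim="date", skipna=False)


def read_fluxes(path, var_map: dict | None = None) -> xr.Dataset:
    """Open a NetCDF flux file (returns it unchanged except eager loading)."""
    ds = xr.open_dataset(path).load()
    if var_map:
        ds = ds.rename({v: k for k, v in var_map.items() if v in ds})
    return ds


def write_dataset(ds: xr.Dataset, path) -> None:
    """Write NetCDF (classic format, self-contained, round-trips exactly)."""
    ds.to_netcdf(path)
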