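"""Physically consistent synthetic radiation inputs for tests and demos.

A single-layer Beer–Lambert clear-sky model with a fixed diffuse fraction,
grey-body thermal emission from air and surface, and a constant surface
albedo.  It is not a radiative-transfer model: its job is to produce flux
sets that satisfy the archive flux identities exactly (downward solar =
direct + diffuse; net = downward − upward) with a realistic diurnal shape,
so every pipeline stage can be exercised without downloading reanalysis
data.  Cloud fields, aerosols and weather variability are out of scope.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import solar
from .fluxes import SOLAR_CONSTANT
from .mrt import STEFAN_BOLTZMANN

__all__ = [
    "ClearSkyScene",
    "clearsky_instantaneous",
    "accumulate_series",
    "make_flux_dataset",
    "synthetic_station",
]


@dataclass(frozen=True)
class ClearSkyScene:
    """Parameters of the synthetic clear-sky radiant environment.

    ``transmittance`` is the broadband zenith transmittance of the
    atmosphere (Beer–Lambert, air-mass scaled as 1/cos θ₀);
    ``diffuse_fraction`` is the fraction of the extinguished beam that
    reappears as isotropic diffuse sky radiation.  Temperatures in kelvin.
    """

    solar_constant: float = SOLAR_CONSTANT
    transmittance: float = 0.75
    albedo: float = 0.2
    diffuse_fraction: float = 0.4
    t_surface_K: float = 288.0
    t_air_K: float = 283.0
    emissivity_surface: float = 0.98
    emissivity_air: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.transmittance <= 1.0:
            raise ValueError("transmittance must lie in (0, 1]")
        for name in ("albedo", "diffuse_fraction",
                     "emissivity_surface", "emissivity_air"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.t_surface_K < 0 or self.t_air_K < 0:
            raise ValueError("temperatures must be >= 0 K")


def clearsky_instantaneous(scene: ClearSkyScene, latitude_deg, longitude_deg,
                           day_of_year, hour_utc) -> dict:
    """Instantaneous surface fluxes (W m⁻²) of the clear-sky scene.

    Solar: the sun-normal beam is S₀ τ^(1/cos θ₀); its horizontal component
    is the direct flux, a fixed fraction of the extinguished horizontal beam
    is diffuse, and the surface reflects albedo × downward.  Thermal: grey
    Stefan–Boltzmann emission from air (down) and surface (up).  At night all
    solar fluxes are zero.  Broadcasts over arrays; returns the archive
    fields (ssrd, ssr, fdir, strd, str) so the identities hold by
    construction.
    """
    g = solar._g(day_of_year, hour_utc)
    decl = solar.solar_declination(g)
    tc = solar.time_correction(g)
    h = solar.solar_hour_angle(hour_utc, longitude_deg, tc)
    cz = np.asarray(solar.cos_solar_zenith(decl, latitude_deg, h), dtype=float)

    day = cz > 0.0
    safe_cz = np.where(day, cz, 1.0)
    beam_normal = np.where(
        day, scene.solar_constant * scene.transmittance ** (1.0 / safe_cz), 0.0)
    fdir = beam_normal * cz
    extinguished = np.where(day, scene.solar_constant * cz - fdir, 0.0)
    s_diffuse = scene.diffuse_fraction * extinguished
    ssrd = fdir + s_diffuse
    ssr = ssrd * (1.0 - scene.albedo)

    strd = scene.emissivity_air * STEFAN_BOLTZMANN * scene.t_air_K ** 4
    l_up = scene.emissivity_surface * STEFAN_BOLTZMANN * scene.t_surface_K ** 4
    return {
        "ssrd": ssrd[()],
        "ssr": ssr[()],
        "fdir": fdir[()],
        "strd": np.full_like(ssrd, strd)[()],
        "str": np.full_like(ssrd, strd - l_up)[()],
    }


def accumulate_series(scene: ClearSkyScene, latitude_deg: float,
                      longitude_deg: float, day_of_year: float,
                      n_steps: int, dt_seconds: float,
                      sampling_seconds: float = 1.0) -> pd.DataFrame:
    """Trapezoidal accumulation of the clear-sky fluxes into archive records.

    Emulates how a forecast model archives radiation: cumulative energy
    since start (J m⁻²), sampled every ``dt_seconds`` starting from hour 0 of
    ``day_of_year``.  Row 0 is the forecast start (all zeros).  The
    sub-sampling step controls the quadrature accuracy and must divide
    ``dt_seconds``.
    """
    if dt_seconds <= 0 or sampling_seconds <= 0:
        raise ValueError("dt_seconds and sampling_seconds must be positive")
    n_sub = dt_seconds / sampling_seconds
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError("dt_seconds must be a multiple of sampling_seconds")

    total_s = n_steps * dt_seconds
    t = np.arange(0.0, total_s + sampling_seconds / 2, sampling_seconds)
    inst = clearsky_instantaneous(
        scene, latitude_deg, longitude_deg, day_of_year, t / 3600.0)

    rows = {}
    idx_out = np.round(np.arange(n_steps + 1) * dt_seconds
                       / sampling_seconds).astype(int)
    for name, values in inst.items():
        v = np.broadcast_to(np.asarray(values, dtype=float), t.shape)
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (v[1:] + v[:-1]) * sampling_seconds)])
        rows[name] = cum[idx_out]
    hours = np.arange(n_steps + 1) * dt_seconds / 3600.0
    return pd.DataFrame(rows, index=pd.Index(hours, name="hour_utc"))


def make_flux_dataset(scene: ClearSkyScene, latitudes, longitudes, times,
                      accumulation_seconds: float,
                      sampling_seconds: float = 60.0) -> xr.Dataset:
    """Gridded per-step accumulated fluxes (J m⁻²) as an xarray Dataset.

    Each timestamp labels the *end* of its accumulation interval and holds
    the energy accumulated over the preceding ``accumulation_seconds``
    (the per-step convention of hourly reanalysis archives).  Quadrature is
    trapezoidal at ``sampling_seconds`` resolution.
    """
    lats = np.asarray(latitudes, dtype=float)
    lons = np.asarray(longitudes, dtype=float)
    times = pd.DatetimeIndex(times)
    n_sub = int(round(accumulation_seconds / sampling_seconds))
    if abs(n_sub * sampling_seconds - accumulation_seconds) > 1e-9 or n_sub < 1:
        raise ValueError("accumulation_seconds must be a multiple of "
                         "sampling_seconds")

    lat3 = lats[:, None]
    lon3 = lons[None, :]
    data = {name: np.zeros((len(times), len(lats), len(lons)))
            for name in ("ssrd", "ssr", "fdir", "strd", "str")}
    for it, ts in enumerate(times):
        doy = float(ts.dayofyear - 1)
        hour_end = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
        offsets = np.linspace(-accumulation_seconds, 0.0, n_sub + 1) / 3600.0
        acc = {name: 0.0 for name in data}
        prev = None
        for off in offsets:
            inst = clearsky_instantaneous(scene, lat3, lon3, doy, hour_end + off)
            if prev is not None:
                for name in data:
                    acc[name] = acc[name] + 0.5 * (prev[name] + inst[name]) \
                        * sampling_seconds
            prev = inst
        for name in data:
            data[name][it] = acc[name]

    ds = xr.Dataset(
        {name: (("time", "latitude", "longitude"), arr)
         for name, arr in data.items()},
        coords={"time": times, "latitude": lats, "longitude": lons},
    )
    for name in ds.data_vars:
        ds[name].attrs["units"] = "J m**-2"
    ds.attrs["accumulation_seconds"] = accumulation_seconds
    ds.attrs["source"] = "mrtgrid synthetic clear-sky scene"
    return ds


def synthetic_station(scene: ClearSkyScene, latitude_deg: float,
                      longitude_deg: float, start, n_samples: int,
                      step_seconds: float = 600.0,
                      noise_sd: float | dict = 0.0,
                      missing_rate: float = 0.0,
                      seed: int = 0) -> pd.DataFrame:
    """Synthetic station observations of the five MRT input components.

    Clear-sky instantaneous fluxes — direct-normal (dni), diffuse and
    upwelling solar, down- and upwelling thermal — plus independent Gaussian
    noise per component and random missing values at ``missing_rate``.
    ``noise_sd`` is a scalar applied to every component or a per-column dict.
    Deterministic for a fixed seed.
    """
    if missing_rate < 0 or missing_rate >= 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    times = pd.date_range(start, periods=n_samples,
                          freq=pd.Timedelta(seconds=step_seconds), tz=None)
    doy = (times.dayofyear - 1).to_numpy(dtype=float)
    hours = (times.hour + times.minute / 60.0 + times.second / 3600.0).to_numpy()

    g = solar._g(doy, hours)
    decl = solar.solar_declination(g)
    tc = solar.time_correction(g)
    h = solar.solar_hour_angle(hours, longitude_deg, tc)
    cz = np.asarray(solar.cos_solar_zenith(decl, latitude_deg, h), dtype=float)
    inst = clearsky_instantaneous(scene, latitude_deg, longitude_deg, doy, hours)

    day = cz > 0.0
    dni = np.where(day, scene.solar_constant
                   * scene.transmittance ** (1.0 / np.where(day, cz, 1.0)), 0.0)
    df = pd.DataFrame({
        "dni": dni,
        "s_diffuse": np.asarray(inst["ssrd"]) - np.asarray(inst["fdir"]),
        "s_up": np.asarray(inst["ssrd"]) - np.asarray(inst["ssr"]),
        "l_dn": np.broadcast_to(np.asarray(inst["strd"], dtype=float), cz.shape),
        "l_up": np.broadcast_to(np.asarray(inst["strd"], dtype=float)
                                - np.asarray(inst["str"], dtype=float), cz.shape),
    }, index=pd.Index(times, name="time"))

    for col in df.columns:
        sd = noise_sd.get(col, 0.0) if isinstance(noise_sd, dict) else noise_sd
        if sd > 0:
            df[col] = np.clip(df[col] + rng.normal(0.0, sd, len(df)), 0.0, None)
        if missing_rate > 0:
            mask = rng.random(len(df)) < missing_rate
            df.loc[mask, col] = np.nan
    return df
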