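"""Solar ephemeris and interval-averaged daytime cosine of the solar zenith angle.

The radiation fluxes this package consumes are archived as means over an
accumulation interval (typically 1 or 3 h).  Projecting the horizontal direct
flux onto a sun-normal plane therefore needs the cosine of the solar zenith
angle averaged over the *sunlit part* of that interval, not the instantaneous
value: when the interval straddles sunrise or sunset, averaging over the full
interval dilutes the cosine and inflates the direct-normal irradiance.

All public angles are in degrees.  The ephemeris is a deliberately truncated
trigonometric series (Spencer-style declination and equation of time); it is
accurate to a few tenths of a degree, which is ample for broadband flux
projection, and it is the series this package treats as its specification —
no refraction, nutation, or higher-order terms.

Every function broadcasts over numpy arrays so the grid pipeline can evaluate
a full latitude-longitude field per time step in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeoTimePoint",
    "AveragingInterval",
    "SunlitInterval",
    "SolarAngles",
    "REGIME_NORMAL",
    "REGIME_POLAR_DAY",
    "REGIME_POLAR_NIGHT",
    "angular_year_fraction",
    "solar_declination",
    "time_correction",
    "solar_hour_angle",
    "cos_solar_zenith",
    "sunrise_hour_angle",
    "interval_mean_cos_zenith",
    "mean_daytime_cos_zenith",
    "solar_elevation",
    "solar_angles",
]

REGIME_NORMAL = "normal"
REGIME_POLAR_DAY = "polar_day"
REGIME_POLAR_NIGHT = "polar_night"

#: Degrees per radian, the prefactor of the declination series.
_DEG = 180.0 / np.pi

#: Sunlit spans narrower than this (degrees of hour angle) are treated as
#: degenerate and fall back to the instantaneous cosine.
_DEGENERATE_SPAN_DEG = 1e-9


@dataclass(frozen=True)
class GeoTimePoint:
    """A location and UTC instant at which solar geometry is evaluated.

    ``day_of_year`` counts fractional days from 1 January 00 UTC (0-based),
    matching the day-of-year convention of the declination series.
    """

    latitude_deg: float
    longitude_deg: float
    day_of_year: float
    hour_utc: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError(f"latitude {self.latitude_deg} outside [-90, 90]")
        if not -180.0 < self.longitude_deg <= 180.0:
            raise ValueError(f"longitude {self.longitude_deg} outside (-180, 180]")
        if self.day_of_year < 0:
            raise ValueError("day_of_year must be >= 0")
        if not 0.0 <= self.hour_utc < 24.0:
            raise ValueError("hour_utc must lie in [0, 24)")


@dataclass(frozen=True)
class AveragingInterval:
    """A flux-accumulation interval [start, end] in UTC hours.

    ``end_hour_utc`` smaller than ``start_hour_utc`` means the interval wraps
    past midnight into the next day.  Hours outside [0, 24) are accepted and
    simply reference the adjacent day.
    """

    start_hour_utc: float
    end_hour_utc: float

    @property
    def width_hours(self) -> float:
        span = self.end_hour_utc - self.start_hour_utc
        return span + 24.0 if span < 0 else span

    @property
    def width_s(self) -> float:
        return 3600.0 * self.width_hours


@dataclass(frozen=True)
class SunlitInterval:
    """Half-width of the sunlit hour-angle span and its polar regime."""

    h0_deg: float
    regime: str

    @property
    def h_min_deg(self) -> float:
        return -self.h0_deg

    @property
    def h_max_deg(self) -> float:
        return self.h0_deg


@dataclass(frozen=True)
class SolarAngles:
    """Instantaneous solar coordinates at a :class:`GeoTimePoint`."""

    year_fraction_deg: float
    declination_deg: float
    time_correction_deg: float
    hour_angle_deg: float
    cos_zenith: float
    elevation_deg: float


def _g(day_of_year, hour_utc):
    """Angular fraction of the year, degrees; no range validation."""
    return (360.0 / 365.25) * (np.asarray(day_of_year, dtype=float)
                               + np.asarray(hour_utc, dtype=float) / 24.0)


def angular_year_fraction(day_of_year, hour_utc):
    """Angular fraction of the year in degrees: g = (360/365.25)(d + hr/24).

    ``day_of_year`` is 0-based fractional days from 1 January 00 UTC.
    """
    day_of_year = np.asarray(day_of_year, dtype=float)
    hour_utc = np.asarray(hour_utc, dtype=float)
    if np.any(day_of_year < 0):
        raise ValueError("day_of_year must be >= 0")
    if np.any((hour_utc < 0) | (hour_utc >= 24)):
        raise ValueError("hour_utc must lie in [0, 24)")
    return _g(day_of_year, hour_utc)[()]


def solar_declination(g_deg):
    """Solar declination in degrees from the 7-term truncated Fourier series.

    Arguments g, 2g, 3g are taken in degrees; amplitude is bounded by ~23.5°.
    """
    g = np.deg2rad(np.asarray(g_deg, dtype=float))
    return (_DEG * (0.006918
                    - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
                    - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
                    - 0.002697 * np.cos(3 * g) + 0.001480 * np.sin(3 * g)))[()]


def time_correction(g_deg):
    """Equation of time expressed as an hour-angle offset in degrees.

    The coefficients are the classic equation-of-time series in minutes
    multiplied by 0.25° per minute; |TC| stays below ~4.3°.
    """
    g = np.deg2rad(np.asarray(g_deg, dtype=float))
    return (0.004297
            + 0.107029 * np.cos(g) - 1.837877 * np.sin(g)
            - 0.837378 * np.cos(2 * g) - 2.340475 * np.sin(2 * g))[()]


def _normalize_hour_angle(h_deg):
    """Wrap an hour angle into (-180, 180]."""
    h = np.mod(np.asarray(h_deg, dtype=float), 360.0)
    return np.where(h > 180.0, h - 360.0, h)[()]


def solar_hour_angle(hour_utc, longitude_deg, tc_deg):
    """Solar hour angle h = (hr − 12)·15 + λ + TC, normalized to (−180, 180]."""
    h = (np.asarray(hour_utc, dtype=float) - 12.0) * 15.0 \
        + np.asarray(longitude_deg, dtype=float) + np.asarray(tc_deg, dtype=float)
    return _normalize_hour_angle(h)


def cos_solar_zenith(declination_deg, latitude_deg, hour_angle_deg):
    """Cosine of the solar zenith angle, clipped to 0 below the horizon."""
    d = np.deg2rad(np.asarray(declination_deg, dtype=float))
    p = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    if np.any(np.abs(np.asarray(latitude_deg)) > 90.0):
        raise ValueError("latitude must lie in [-90, 90]")
    h = np.deg2rad(np.asarray(hour_angle_deg, dtype=float))
    c = np.sin(d) * np.sin(p) + np.cos(d) * np.cos(p) * np.cos(h)
    # clip: 0 below the horizon; 1 guards the 1-ulp overshoot at δ = φ, h = 0
    return np.clip(c, 0.0, 1.0)[()]


def sunrise_hour_angle(declination_deg, latitude_deg):
    """Sunrise/sunset hour-angle half-width h₀ and polar regime.

    Solves the sunrise equation cos h₀ = −tan δ tan φ.  When the cosine falls
    outside [−1, 1] there is no sunrise: the Sun stays below the horizon
    (polar night, h₀ = 0) or above it (polar day, h₀ = 180°).  The cosine is
    clamped before the arccos; the regime is reported explicitly rather than
    encoded in the number.

    Returns ``(h0_deg, regime)`` as scalars or broadcast arrays.
    """
    if np.any(np.abs(np.asarray(latitude_deg)) > 90.0):
        raise ValueError("latitude must lie in [-90, 90]")
    cos_h0 = (-np.tan(np.deg2rad(np.asarray(declination_deg, dtype=float)))
              * np.tan(np.deg2rad(np.asarray(latitude_deg, dtype=float))))
    regime = np.where(cos_h0 > 1.0, REGIME_POLAR_NIGHT,
                      np.where(cos_h0 < -1.0, REGIME_POLAR_DAY, REGIME_NORMAL))
    h0 = np.rad2deg(np.arccos(np.clip(cos_h0, -1.0, 1.0)))
    if h0.ndim == 0:
        return float(h0), str(regime)
    return h0, regime


def sunlit_interval(declination_deg, latitude_deg) -> SunlitInterval:
    """Scalar convenience wrapper around :func:`sunrise_hour_angle`."""
    h0, regime = sunrise_hour_angle(declination_deg, latitude_deg)
    return SunlitInterval(h0_deg=float(h0), regime=str(regime))


def interval_mean_cos_zenith(declination_deg, latitude_deg, h_start_deg, h_end_deg):
    """Mean daytime cos θ₀ over the hour-angle interval [h_start, h_end].

    Intersects the interval with the sunlit span [−h₀, +h₀] (repeated every
    360° so that intervals already unwrapped past ±180° are handled without a
    seam) and evaluates the closed-form integral of the zenith cosine,

        sin δ sin φ + cos δ cos φ (sin h_max − sin h_min) / (h_max − h_min),

    with the denominator in radians.  The average is duration-weighted across
    disjoint sunlit pieces, returns 0 when the interval is entirely dark, and
    falls back to the instantaneous clipped cosine at the interval midpoint
    when the sunlit intersection is degenerate (zero width).  Result is
    clipped to [0, 1].

    ``h_end_deg`` must be ≥ ``h_start_deg`` in unwrapped (monotone) hour-angle
    coordinates; spans up to a full day (360° plus equation-of-time drift)
    are supported.
    """
    d, p, a, b = np.broadcast_arrays(
        np.asarray(declination_deg, dtype=float),
        np.asarray(latitude_deg, dtype=float),
        np.asarray(h_start_deg, dtype=float),
        np.asarray(h_end_deg, dtype=float),
    )
    if np.any(b < a):
        raise ValueError("h_end_deg must be >= h_start_deg (unwrapped)")
    h0 = sunrise_hour_angle(d, p)[0]
    h0 = np.asarray(h0, dtype=float)

    sin_term = np.sin(np.deg2rad(d)) * np.sin(np.deg2rad(p))
    cos_term = np.cos(np.deg2rad(d)) * np.cos(np.deg2rad(p))

    integral = np.zeros(np.broadcast(d, p, a, b).shape)
    width = np.zeros_like(integral)
    # a is expected in (-180, 180] and b - a <= ~365 deg, so the sunlit span
    # replicated at k = -1..2 covers every possible overlap.
    for k in (-1, 0, 1, 2):
        lo = np.maximum(a, -h0 + 360.0 * k)
        hi = np.minimum(b, h0 + 360.0 * k)
        w = np.clip(hi - lo, 0.0, None)
        seg = np.where(
            w > 0.0,
            sin_term * np.deg2rad(w)
            + cos_term * (np.sin(np.deg2rad(hi)) - np.sin(np.deg2rad(lo))),
            0.0,
        )
        integral += seg
        width += w

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = integral / np.deg2rad(width)
    h_mid = _normalize_hour_angle(0.5 * (a + b))
    instantaneous = cos_solar_zenith(d, p, h_mid)
    mean = np.where(width > _DEGENERATE_SPAN_DEG, mean, instantaneous)
    return np.clip(mean, 0.0, 1.0)[()]


def mean_daytime_cos_zenith(latitude_deg, longitude_deg, day_of_year,
                            start_hour_utc, end_hour_utc):
    """Average daytime cos θ₀ over a UTC accumulation interval.

    The interval endpoints are mapped to hour angles with the equation of
    time evaluated at each endpoint; the declination is evaluated at the
    interval midpoint (it drifts by well under 0.1° over a 3-h window).  An
    end hour numerically below the start hour is unwrapped across midnight.
    Broadcasts over all arguments.
    """
    lat, lon, doy, t1, t2 = np.broadcast_arrays(
        np.asarray(latitude_deg, dtype=float),
        np.asarray(longitude_deg, dtype=float),
        np.asarray(day_of_year, dtype=float),
        np.asarray(start_hour_utc, dtype=float),
        np.asarray(end_hour_utc, dtype=float),
    )
    span = t2 - t1
    span = np.where(span < 0, span + 24.0, span)

    tc1 = time_correction(_g(doy, t1))
    tc2 = time_correction(_g(doy, t1 + span))
    decl = solar_declination(_g(doy, t1 + 0.5 * span))

    # Unwrapped hour-angle interval: normalize the start, keep the end
    # monotone so sunrise/sunset and midnight crossings need no special case.
    h1_raw = (t1 - 12.0) * 15.0 + lon + tc1
    h1 = np.asarray(_normalize_hour_angle(h1_raw), dtype=float)
    h2 = h1 + span * 15.0 + (tc2 - tc1)
    return interval_mean_cos_zenith(decl, lat, h1, h2)


def solar_elevation(cos_zenith):
    """Solar elevation γ = 90° − θ₀ in degrees, for cos θ₀ ∈ [0, 1]."""
    c = np.asarray(cos_zenith, dtype=float)
    if np.any((c < 0.0) | (c > 1.0)):
        raise ValueError("cos_zenith must lie in [0, 1]")
    return (90.0 - np.rad2deg(np.arccos(c)))[()]


def solar_angles(point: GeoTimePoint) -> SolarAngles:
    """All instantaneous solar coordinates at one location and time."""
    g = angular_year_fraction(point.day_of_year, point.hour_utc)
    decl = solar_declination(g)
    tc = time_correction(g)
    h = solar_hour_angle(point.hour_utc, point.longitude_deg, tc)
    cz = cos_solar_zenith(decl, point.latitude_deg, h)
    return SolarAngles(
        year_fraction_deg=float(g),
        declination_deg=float(decl),
        time_correction_deg=float(tc),
        hour_angle_deg=float(h),
        cos_zenith=float(cz),
        elevation_deg=float(solar_elevation(cz)),
    )
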