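"""Independent low-precision solar ephemeris used only as a test oracle.

Implements the NOAA solar-calculator algorithm (after Meeus), which derives
declination and the equation of time from the Sun's mean anomaly, the
equation of center and the true obliquity — a formulation entirely
independent of the truncated Fourier series in ``mrtgrid.solar``.  Accuracy
is a few hundredths of a degree, more than an order of magnitude better
than the series under test.

Note: the package's equation-of-time series is itself truncated with an
intrinsic error of ≈ 0.15° hour angle against any accurate ephemeris, so
oracle comparisons for it are meaningful only at the 0.2° level.
"""

from __future__ import annotations

import numpy as np

#: Julian date of 2000-01-01 00:00 UT, the epoch day-of-year 0 maps to.
_JD_EPOCH = 2451544.5


def noaa_declination_eot(day_of_year, hour_utc=0.0):
    """(declination deg, equation of time as hour-angle deg) for a UT instant."""
    jd = _JD_EPOCH + np.asarray(day_of_year, dtype=float) \
        + np.asarray(hour_utc, dtype=float) / 24.0
    T = (jd - 2451545.0) / 36525.0
    L0 = np.mod(280.46646 + 36000.76983 * T + 0.0003032 * T * T, 360.0)
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T * T
    e = 0.016708634 - 0.000042037 * T - 0.0000001267 * T * T
    Mr = np.deg2rad(M)
    C = (np.sin(Mr) * (1.914602 - 0.004817 * T - 0.000014 * T * T)
         + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
         + np.sin(3 * Mr) * 0.000289)
    omega = np.deg2rad(125.04 - 1934.136 * T)
    lam = np.deg2rad(L0 + C - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + 21.448 / 60.0) / 60.0 \
        - (46.8150 * T + 0.00059 * T * T - 0.001813 * T ** 3) / 3600.0
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))
    declination = np.rad2deg(np.arcsin(np.sin(eps) * np.sin(lam)))
    y = np.tan(eps / 2.0) ** 2
    L0r = np.deg2rad(L0)
    eot_minutes = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r) - 2 * e * np.sin(Mr)
        + 4 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r) - 1.25 * e * e * np.sin(2 * Mr))
    return declination, eot_minutes / 4.0


def brute_force_daytime_mean_cos_zenith(latitude_deg, longitude_deg,
                                        day_of_year, start_hour_utc,
                                        end_hour_utc, sampling_s=1.0):
    """Time average of the clipped zenith cosine over the sunlit seconds.

    Samples the full instantaneous solar geometry (declination, equation of
    time and hour angle all re-evaluated at every step) at ``sampling_s``
    resolution and averages the clipped cosine over the samples where the
    Sun is up; 0 if it never rises within the interval.  This is the
    integral the closed-form interval average approximates.
    """
    from mrtgrid import solar

    t2 = end_hour_utc if end_hour_utc >= start_hour_utc else end_hour_utc + 24
    hours = np.arange(start_hour_utc * 3600.0, t2 * 3600.0 + sampling_s / 2,
                      sampling_s) / 3600.0
    g = solar._g(day_of_year, hours)
    decl = solar.solar_declination(g)
    tc = solar.time_correction(g)
    h = solar.solar_hour_angle(hours, longitude_deg, tc)
    cz = np.asarray(solar.cos_solar_zenith(decl, latitude_deg, h))
    sunlit = cz > 0.0
    if not np.any(sunlit):
        return 0.0
    return float(cz[sunlit].mean())
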