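"""De-accumulation of archived radiation fluxes and derived MRT components.

NWP archives store surface radiation as energy accumulated since forecast
start (J m⁻²).  Differencing two archive times and dividing by the interval
length gives the *accumulated mean* flux (W m⁻²).  From the five archived
fields — surface solar radiation downwards (ssrd), surface net solar
radiation (ssr), direct solar radiation at the surface (fdir), surface
thermal radiation downwards (strd) and surface net thermal radiation (str) —
the components entering the radiant-temperature equation follow by flux
algebra: net fluxes are downward minus upward, and downward solar splits
into direct plus diffuse.

Field dictionaries use the ECMWF short names above; derived components use
``l_up``, ``s_diffuse``, ``s_up``, ``i_star``.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np

__all__ = [
    "FLUX_NAMES",
    "DERIVED_NAMES",
    "SOLAR_CONSTANT",
    "COS_ZENITH_EPSILON",
    "AccumulationResetError",
    "deaccumulate",
    "derive_components",
    "direct_normal",
]

logger = logging.getLogger(__name__)

#: Archived flux fields, ECMWF short names.
FLUX_NAMES = ("ssrd", "ssr", "fdir", "strd", "str")

#: Components derived from the archived means.
DERIVED_NAMES = ("l_up", "s_diffuse", "s_up")

#: Archived fields whose mean may legitimately be negative: the net thermal
#: flux is downward minus upward and the surface usually emits more than the
#: sky returns, so its accumulation *decreases* with time.  Monotonicity
#: checks and zero-clipping do not apply to these.
SIGNED_FLUXES = ("str",)

#: Total solar irradiance, W m⁻²; cap for the direct-normal projection.
SOLAR_CONSTANT = 1361.0

#: Mean daytime cosines at or below this are treated as "sun effectively at
#: or below the horizon": no direct-normal projection is attempted.
COS_ZENITH_EPSILON = 1e-3


class AccumulationResetError(ValueError):
    """Accumulated energy decreased beyond noise: a new forecast segment."""


def deaccumulate(accumulated_t1: Mapping[str, np.ndarray],
                 accumulated_t2: Mapping[str, np.ndarray],
                 dt_seconds: float,
                 noise_tolerance: float = 1.0) -> dict:
    """Convert two accumulated-energy records into mean fluxes.

    Parameters
    ----------
    accumulated_t1, accumulated_t2
        Accumulated energies (J m⁻²) at the interval start and end, keyed by
        field name; both must come from the same forecast segment.
    dt_seconds
        Interval length in seconds (> 0).
    noise_tolerance
        Largest tolerated accumulation *decrease* in J m⁻² before the pair is
        rejected as straddling a forecast reset.  Small negative differences
        within tolerance (packing noise) are clipped to zero.  Fields in
        :data:`SIGNED_FLUXES` are exempt from both the check and the clip.

    Returns
    -------
    dict
        Mean fluxes in W m⁻² for the keys common to both records.

    Raises
    ------
    AccumulationResetError
        If any field's accumulation drops by more than ``noise_tolerance``.
    """
    if dt_seconds <= 0:
        raise ValueError("dt_seconds must be positive")
    means = {}
    clipped = 0
    for name in accumulated_t1:
        if name not in accumulated_t2:
            continue
        a1 = np.asarray(accumulated_t1[name], dtype=float)
        a2 = np.asarray(accumulated_t2[name], dtype=float)
        diff = a2 - a1
        if name in SIGNED_FLUXES:
            means[name] = diff[()] / dt_seconds
            continue
        if np.any(diff < -noise_tolerance):
            raise AccumulationResetError(
                f"accumulated field {name!r} decreased by more than "
                f"{noise_tolerance} J m-2; records straddle a forecast reset"
            )
        clipped += int(np.count_nonzero(diff < 0))
        means[name] = np.clip(diff, 0.0, None)[()] / dt_seconds
    if clipped:
        logger.debug("deaccumulate clipped %d small negative differences", clipped)
    return means


def derive_components(mean_fluxes: Mapping[str, np.ndarray]) -> dict:
    """Derive upwelling thermal, diffuse solar and upwelling solar fluxes.

    Implements the flux algebra

        L_up      = strd − str
        S_diffuse = ssrd − fdir
        S_up      = ssrd − ssr

    each clipped at zero (numerical noise can leave tiny negatives).  The
    input mean fluxes are passed through unchanged alongside the derived
    keys, so the result is a complete component set.
    """
    ssrd = np.asarray(mean_fluxes["ssrd"], dtype=float)
    out = dict(mean_fluxes)
    out["l_up"] = np.clip(
        np.asarray(mean_fluxes["strd"], dtype=float)
        - np.asarray(mean_fluxes["str"], dtype=float), 0.0, None)[()]
    out["s_diffuse"] = np.clip(
        ssrd - np.asarray(mean_fluxes["fdir"], dtype=float), 0.0, None)[()]
    out["s_up"] = np.clip(
        ssrd - np.asarray(mean_fluxes["ssr"], dtype=float), 0.0, None)[()]
    return out


def direct_normal(s_dn_direct, cos_zenith_bar,
                  epsilon: float = COS_ZENITH_EPSILON,
                  cap: float | None = SOLAR_CONSTANT):
    """Project the horizontal direct flux onto a sun-normal plane.

    I* = S_direct / mean-daytime-cos θ₀ wherever the cosine exceeds
    ``epsilon``; zero otherwise (the division-by-zero guard near the
    terminator).  By default the quotient is capped at the solar constant
    (1361 W m⁻²): a residual direct flux divided by a vanishing cosine would
    otherwise produce irradiances no atmosphere can deliver.  Pass
    ``cap=None`` to disable the cap and recover the bare quotient.
    """
    s = np.asarray(s_dn_direct, dtype=float)
    c = np.asarray(cos_zenith_bar, dtype=float)
    if np.any(s < 0):
        raise ValueError("direct flux must be >= 0")
    if np.any((c < 0) | (c > 1)):
        raise ValueError("cos_zenith_bar must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        i_star = np.where(c > epsilon, s / np.where(c > epsilon, c, 1.0), 0.0)
    if cap is not None:
        n_capped = int(np.count_nonzero(i_star > cap))
        if n_capped:
            logger.debug("direct_normal capped %d values at %.0f W m-2",
                         n_capped, cap)
        i_star = np.clip(i_star, None, cap)
    return i_star[()]
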