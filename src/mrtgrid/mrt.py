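"""Human-body radiation model: projection factor, MRT and mean radiant flux.

The mean radiant temperature (MRT) is the uniform temperature of a fictive
black-body enclosure that would exchange the same net radiant energy with a
person as the real environment.  For an unobstructed flat site the
surroundings reduce to two hemispheres — sky and ground — each weighted by
an angle factor fa = 0.5.  Thermal fluxes enter directly; solar fluxes are
scaled by the body's short-wave absorptivity over its long-wave emissivity;
the direct beam is additionally weighted by the surface projection factor
fp, the fraction of body area the beam actually strikes, which for an
upright person falls from 0.308 with the sun at the horizon to about 0.08
with the sun overhead.

    MRT = { (1/σ) [ fa·L_dn + fa·L_up
                    + (α_ir/ε_p)(fa·S_diffuse + fa·S_up + fp·I*) ] }^(1/4)

Inputs are W m⁻², the result kelvin (Celsius at the presentation boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "STEFAN_BOLTZMANN",
    "HumanConfig",
    "MRTResult",
    "projection_factor",
    "compute_mrt",
    "compute_mrt_shade",
    "mrf_from_mrt",
    "mrt_from_mrf",
]

#: Stefan–Boltzmann constant, W m⁻² K⁻⁴.
STEFAN_BOLTZMANN = 5.67e-8

_POSTURES = ("standing", "walking")


@dataclass(frozen=True)
class HumanConfig:
    """Radiative constants of the clothed human body.

    Attributes
    ----------
    emissivity_body : float
        Long-wave emissivity ε_p of the clothed body (standard value 0.97).
    absorption_solar : float
        Short-wave absorptivity α_ir of the irradiated body surface
        (standard value 0.7).
    angle_factor : float
        Solid-angle weight fa of each of the two hemispheres (sky, ground).
        The default 0.5 makes the two factors close the full solid angle.
    posture : str
        ``"standing"`` or ``"walking"``; both are covered by the same
        rotationally-symmetric projection-factor regression.
    fp_from_interval_mean : bool
        If True (default) the projection factor is evaluated at the elevation
        derived from the interval-averaged zenith cosine, keeping the solar
        position treatment consistent with the direct-normal projection; if
        False the instantaneous cosine at the interval end is used instead.
    """

    emissivity_body: float = 0.97
    absorption_solar: float = 0.7
    angle_factor: float = 0.5
    posture: str = "standing"
    fp_from_interval_mean: bool = True
    stefan_boltzmann: float = field(default=STEFAN_BOLTZMANN, repr=False)

    def __post_init__(self) -> None:
        for name in ("emissivity_body", "absorption_solar", "angle_factor"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.posture not in _POSTURES:
            raise ValueError(f"posture must be one of {_POSTURES}")
        if self.stefan_boltzmann != STEFAN_BOLTZMANN:
            raise ValueError("stefan_boltzmann is a physical constant")

    @property
    def hemisphere_closure(self) -> float:
        """Sum of the two angle factors; 1.0 for the default fa = 0.5."""
        return 2.0 * self.angle_factor


@dataclass(frozen=True)
class MRTResult:
    """MRT in kelvin and Celsius with the matching mean radiant flux."""

    mrt_K: np.ndarray | float
    mrt_C: np.ndarray | float
    mrf_Wm2: np.ndarray | float
    fp: np.ndarray | float

    @classmethod
    def from_kelvin(cls, mrt_K, fp, config: "HumanConfig") -> "MRTResult":
        return cls(mrt_K=mrt_K, mrt_C=mrt_K - 273.15,
                   mrf_Wm2=mrf_from_mrt(mrt_K, config), fp=fp)


def projection_factor(elevation_deg):
    """Surface projection factor fp(γ) for an upright person.

    Regression against photographs of a rotationally symmetric standing or
    walking person,

        fp = 0.308 · cos( γ (0.998 − γ²/50000) ),

    with the solar elevation γ and the cosine argument both in degrees.
    Monotonically decreasing from 0.308 at the horizon to ≈ 0.0785 overhead.
    """
    g = np.asarray(elevation_deg, dtype=float)
    if np.any((g < 0.0) | (g > 90.0)):
        raise ValueError("elevation must lie in [0, 90] degrees")
    return (0.308 * np.cos(np.deg2rad(g * (0.998 - g * g / 50000.0))))[()]


def _radicand(derived: Mapping, fp, config: HumanConfig, i_star):
    fa = config.angle_factor
    solar = (fa * np.asarray(derived["s_diffuse"], dtype=float)
             + fa * np.asarray(derived["s_up"], dtype=float)
             + np.asarray(fp, dtype=float) * np.asarray(i_star, dtype=float))
    return (fa * np.asarray(derived["l_dn"], dtype=float)
            + fa * np.asarray(derived["l_up"], dtype=float)
            + (config.absorption_solar / config.emissivity_body) * solar)


def compute_mrt(derived: Mapping, fp, config: HumanConfig | None = None) -> MRTResult:
    """Mean radiant temperature from derived flux components.

    ``derived`` maps ``l_dn``, ``l_up``, ``s_diffuse``, ``s_up``, ``i_star``
    (W m⁻², scalars or broadcastable arrays); ``fp`` is the projection factor
    in [0, 0.308].  All components must be non-negative — this guarantees a
    non-negative radicand, so the quartic root is always defined.
    """
    config = config or HumanConfig()
    fp_arr = np.asarray(fp, dtype=float)
    if np.any((fp_arr < 0.0) | (fp_arr > 0.308)):
        raise ValueError("fp must lie in [0, 0.308]")
    for key in ("l_dn", "l_up", "s_diffuse", "s_up", "i_star"):
        if np.any(np.asarray(derived[key], dtype=float) < 0):
            raise ValueError(f"flux component {key!r} must be >= 0")
    rad = _radicand(derived, fp_arr, config, derived["i_star"])
    mrt_K = (np.asarray(rad) / config.stefan_boltzmann) ** 0.25
    return MRTResult.from_kelvin(mrt_K[()], fp_arr[()], config)


def compute_mrt_shade(derived: Mapping, config: HumanConfig | None = None) -> MRTResult:
    """MRT for a fully shaded person: identical but with the direct beam removed."""
    shaded = dict(derived)
    shaded["i_star"] = np.zeros_like(np.asarray(derived["i_star"], dtype=float))[()]
    return compute_mrt(shaded, 0.0, config)


def mrf_from_mrt(mrt_K, config: HumanConfig | None = None):
    """Mean radiant flux MRF = ε_p σ MRT⁴ (W m⁻²)."""
    config = config or HumanConfig()
    t = np.asarray(mrt_K, dtype=float)
    if np.any(t < 0):
        raise ValueError("mrt_K must be >= 0")
    return (config.emissivity_body * config.stefan_boltzmann * t ** 4)[()]


def mrt_from_mrf(mrf_Wm2, config: HumanConfig | None = None):
    """Invert the mean radiant flux back to kelvin (quartic root)."""
    config = config or HumanConfig()
    f = np.asarray(mrf_Wm2, dtype=float)
    if np.any(f < 0):
        raise ValueError("mrf_Wm2 must be >= 0")
    return ((f / (config.emissivity_body * config.stefan_boltzmann)) ** 0.25)[()]
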