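# mrtgrid

Mean radiant temperature (MRT) of a standing person computed from the
surface radiation fluxes of a global numerical weather prediction (NWP)
model, with correct handling of the accumulated-flux storage convention and
of the Sun's movement across each accumulation interval.

## Who this is for

Human-biometeorology and environmental-health researchers who need gridded,
globe-wide MRT — the radiation input of thermal-stress indices such as UTCI,
PET and WBGT — from reanalysis or forecast archives (e.g. ERA5) instead of
sparse station measurements.

## The model

MRT is the uniform temperature of a fictive black-body enclosure that would
exchange the same net radiant energy with a person as the real environment.
For an unobstructed flat site the surroundings are a sky hemisphere and a
ground hemisphere, each with angle factor *f*<sub>a</sub> = 0.5:

```
MRT = { (1/σ) [ fa·L↓ + fa·L↑ + (αir/εp)(fa·S_diff + fa·S↑ + fp·I*) ] }^(1/4)
```

with σ the Stefan–Boltzmann constant, ε<sub>p</sub> = 0.97 the long-wave
emissivity of the clothed body, α<sub>ir</sub> = 0.7 its short-wave
absorptivity, and *f*<sub>p</sub>(γ) = 0.308 cos(γ(0.998 − γ²/50000)) the
surface projection factor of an upright person at solar elevation γ
(degrees).

The five inputs come from the archived model fields (ECMWF short names):

| field | meaning | derived component |
|-------|---------|-------------------|
| `ssrd` | surface solar radiation downwards | S_diff = ssrd − fdir |
| `ssr`  | surface net solar radiation | S↑ = ssrd − ssr |
| `fdir` | direct solar radiation at the surface | I* = fdir / cos̄θ₀ |
| `strd` | surface thermal radiation downwards | L↓ |
| `str`  | surface net thermal radiation | L↑ = strd − str |

Archives store these as energy accumulated over an interval Δt (J m⁻²);
differencing and dividing by Δt gives mean fluxes (W m⁻²).  Because the Sun
moves during Δt — and may rise or set inside it — the horizontal direct flux
is projected onto a sun-normal plane with the **mean daytime cosine of the
solar zenith angle**: the closed-form average of cos θ₀ over the sunlit part
of the interval, obtained by intersecting the interval's hour-angle span
with the sunrise-equation span and integrating.  Near the terminator the
projection is guarded (no division below cos̄θ₀ = 10⁻³) and capped at the
solar constant 1361 W m⁻².

## Worked example

One grid cell, 20° N 0° E, interval 11–12 UTC in mid-June, archived means
ssrd = 820, ssr = 656, fdir = 640, strd = 350, str = −70 W m⁻²:

```python
from mrtgrid import (HumanConfig, compute_mrt, compute_mrt_shade,
                     mean_daytime_cos_zenith, projection_factor,
                     solar_elevation)
from mrtgrid.fluxes import derive_components, direct_normal

mean = {"ssrd": 820.0, "ssr": 656.0, "fdir": 640.0,
        "strd": 350.0, "str": -70.0}
cz = float(mean_daytime_cos_zenith(20.0, 0.0, 166.0, 11.0, 12.0))
d = derive_components(mean)
i_star = float(direct_normal(d["fdir"], cz))
fp = float(projection_factor(solar_elevation(cz)))
comp = {"l_dn": d["strd"], "l_up": d["l_up"], "s_diffuse": d["s_diffuse"],
        "s_up": d["s_up"], "i_star": i_star}
res, shade = compute_mrt(comp, fp), compute_mrt_shade(comp)
print(f"mean daytime cos zenith : {cz:.4f}")
print(f"direct normal I*        : {i_star:.1f} W m-2")
print(f"projection factor fp    : {fp:.4f}")
print(f"MRT (sun)               : {float(res.mrt_C):.2f} degC")
print(f"MRT (shade)             : {float(shade.mrt_C):.2f} degC")
print(f"MRF                     : {float(res.mrf_Wm2):.1f} W m-2")
```

prints:

```
mean daytime cos zenith : 0.9883
direct normal I*        : 647.6 W m-2
projection factor fp    : 0.1036
MRT (sun)               : 41.75 degC
MRT (shade)             : 34.68 degC
MRF                     : 540.8 W m-2
```

The Sun is 81° high, so only ~10 % of the body intercepts the beam, yet the
direct term still lifts MRT seven degrees above the shaded value — the
radiant load a person escapes by stepping into shade.

## Command line

```
mrtgrid simulate --days 1 --dt 3600 --out fluxes.nc        # synthetic input
mrtgrid compute  --input fluxes.nc --accumulation-seconds 3600 \
                 --output mrt.nc [--shade] [--no-cap]
mrtgrid aggregate --input mrt.nc --daily-extremes --output daily.nc
mrtgrid validate --model mrt.nc --stations stations/ --window-hours 3 \
                 --report report.tsv
```

`compute` accepts accumulated-per-step (default), cumulative-since-start
(`--flux-mode cumulative`) or already-mean (`--flux-mode mean`) inputs;
timestamps label the *end* of each accumulation interval.  Station files
are a plain TSV dialect (`# key: value` header lines, ISO-8601 `time`
column, five flux columns `dni  s_diffuse  s_up  l_dn  l_up`, −999 for
missing).

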