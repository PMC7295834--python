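# Methods

## Scope and model

`mrtgrid` computes the mean radiant temperature (MRT) of a rotationally
symmetric standing (or walking) person on an unobstructed flat site from
the five surface radiation fields a global NWP archive provides: downward
and net solar, horizontal direct solar, downward and net thermal.  The
radiant surroundings are reduced to two hemispheres — sky and ground — each
weighted by an angle factor f_a = 0.5, so the two factors close the full
solid angle.  Thermal fluxes enter the radiant budget directly; solar
fluxes are weighted by the ratio of the body's short-wave absorptivity
(α_ir = 0.7) to its long-wave emissivity (ε_p = 0.97); the direct beam is
additionally weighted by the projection factor f_p(γ), the fraction of the
body surface the beam strikes.  The budget is converted to a temperature
through the Stefan–Boltzmann law (quartic root), and to a mean radiant flux
by MRF = ε_p σ MRT⁴.

Out of scope, deliberately: urban canopy and six-direction angle factors,
seated postures, orography-aware sky-view fractions, microclimate
downscaling, and anything upstream of the archived fluxes (cloud, aerosol,
radiative transfer).

## Solar geometry

Declination and the equation of time come from truncated trigonometric
series in the angular year fraction g = (360/365.25)(d + hr/24), with d the
0-based fractional day of year.  All trigonometric arguments are taken in
degrees; the equation of time is expressed directly as an hour-angle offset
(degrees, i.e. minutes × 0.25).  These series are the package's
specification of the ephemeris: their intrinsic accuracy is ~0.3° in
declination and ~0.15° in the equation of time against a precise ephemeris,
which translates to well under 1 W m⁻² in projected flux — refraction,
nutation and higher-order terms are knowingly omitted.

The hour angle is h = (hr − 12)·15 + λ + TC, normalized to (−180°, 180°];
the zenith cosine sin δ sin φ + cos δ cos φ cos h is clipped to [0, 1]
(zero below the horizon; the upper clip guards a 1-ulp overshoot at δ = φ,
h = 0).

### Mean daytime cosine over an accumulation interval

Archived fluxes are means over an interval Δt during which the Sun moves
and may rise or set.  Dividing the direct flux by the plain interval
average of the clipped cosine overestimates the beam near sunrise/sunset;
the correct weight is the average cosine over the *sunlit part* of the
interval.  The implementation:

1. maps the interval endpoints t₁, t₂ to hour angles using the equation of
   time at each endpoint, keeping the end monotone (no wrap seam — an
   interval spanning midnight or the ±180° meridian needs no special case
   because the sunlit span is intersected as a 360°-periodic family);
2. computes the sunrise half-width h₀ from cos h₀ = −tan δ tan φ with the
   cosine clamped to [−1, 1]; polar day (h₀ = 180°) and polar night
   (h₀ = 0) are explicit regimes, not silent numbers;
3. intersects the interval with the sunlit spans and evaluates
   sin δ sin φ + cos δ cos φ (sin h_max − sin h_min)/(h_max − h_min), the
   denominator in radians (the only dimensionally consistent reading of
   the integral ∫cos h dh = sin h), duration-weighted across disjoint
   pieces;
4. returns 0 for an entirely dark interval, and falls back to the
   instantaneous clipped cosine at the interval midpoint when the sunlit
   intersection is degenerate (width < 10⁻⁹ degrees), avoiding 0/0.

Declination is evaluated at the interval midpoint; it drifts < 0.1° over
3 h, which is why the closed form tracks a 1-second brute-force average of
the instantaneous cosine to better than 2×10⁻³ (property-tested over
randomized locations, dates, straddling and polar intervals).

A consequence worth noting: averaging over the sunlit part extends the
*nonzero* band of the cosine map at the terminator — a cell dark at the
nominal time but lit earlier in the interval gets a positive average — by
up to Δt beyond the instantaneous day, so a 3-h map is nonzero over more
cells than a 1-h map ending at the same time, and its fully-dark zero set
is a strict subset of the 1-h one (the two windows are nested).  The test
suite asserts exactly this nesting.

## Flux handling

* De-accumulation is (A(t₂) − A(t₁))/Δt.  Monotonicity checks, forecast
  reset detection (drop > 1 J m⁻² by default) and zero-clipping of packing
  noise apply to the inherently non-negative fields (ssrd, ssr, fdir,
  strd) only; the net thermal flux `str` is signed — the surface normally
  outradiates the sky — and is passed through untouched.
* Derived components: L↑ = strd − str, S_diff = ssrd − fdir,
  S↑ = ssrd − ssr, each clipped at zero.
* Direct-normal projection I* = fdir / cos̄θ₀ only where cos̄θ₀ > 10⁻³
  (bounding the amplification at 1000×), and capped at the solar constant
  1361 W m⁻²: a residual direct flux divided by a vanishing cosine would
  otherwise produce irradiances no atmosphere delivers and spike the MRT at
  the terminator.  The cap is a switch (`cap=None`, CLI `--no-cap`) so the
  uncapped quotient is recoverable.

## Gridded pipeline conventions

* A timestamp labels the **end** of its accumulation interval; the cosine
  map for time t uses [t − Δt, t] (`time_labels_start=True` flips this).
  Daily extremes group steps by the UTC day of the interval midpoint, so
  the 00:00-stamped step counts toward the previous day.
* Input flux encodings: per-step accumulated J m⁻² (hourly-archive
  convention, default), cumulative since forecast start (pairwise
  differenced, first step dropped), or already-mean W m⁻².
* Longitudes in [0, 360) or (−180, 180] are accepted and normalized
  internally; output keeps the input coordinates.  NetCDF output is CF
  flavoured (MRT in degC) through xarray's scipy backend (classic NetCDF),
  and round-trips bit-exactly.
* The grid path is the scalar chain broadcast over arrays — per-cell
  agreement with the scalar computation to 10⁻⁹ relative is a tested
  contract, not an aspiration.
* The projection factor is evaluated at the elevation derived from the
  interval-averaged cosine (arccos of the daytime mean), keeping the solar
  position treatment consistent between I* and f_p.  A config switch
  (`fp_from_interval_mean=False`) selects the instantaneous elevation at
  the interval end instead; the difference is visible only at low sun.

## Station validation

Observed MRT is computed from measured components with the same body model:
measured direct-normal irradiance is used as I* directly and f_p comes from
the instantaneous elevation at the station's location and timestamp.  Both
sides are averaged in synoptic windows aligned at 00 UTC (default 3 h —
time-averaged radiation agrees far better between models and stations than
instantaneous values); a window needs ≥ 50 % of its expected samples, else
it is missing.  Model series are shifted to interval midpoints before
windowing so both sides cover the same physical time.  Metrics per station
and variable: R² = cov²/(var·var) (population moments; undefined → NaN
under zero variance), bias = mean(model − obs), RMSE.  Grid-cell extraction
is nearest-neighbour with midpoint ties breaking to the lower index.
Because "network-average bias" is ambiguous, the summary reports both the
equal-weight station mean and the pair-count-weighted pool.

## Synthetic scenes

The generator is a single-layer Beer–Lambert clear-sky model: sun-normal
beam S₀ τ^(1/cos θ₀) (τ = 0.75 zenith transmittance by default), a fixed
fraction (0.4) of the extinguished horizontal beam as isotropic diffuse,
surface reflection by constant albedo (0.2), grey thermal emission from air
(ε = 0.8, 283 K) and surface (ε = 0.98, 288 K).  These defaults give
midlatitude clear-day magnitudes (peak global ~1000 W m⁻², thermal 300–400
W m⁻²).  All archive identities (direct + diffuse = downward; net =
downward − upward) hold exactly by construction, accumulation is
trapezoidal, and every stochastic feature (noise, missingness) is seeded.
The scene has no clouds, weather or aerosol variability: passing tests
demonstrate the correctness of the flux algebra, solar averaging and
statistics, not the NWP model's radiative skill, which only a comparison
against real reanalysis and station archives can establish.

## Numerical choices and limitations

* Internal temperature unit is kelvin; Celsius appears only at the output
  boundary.
* Out-of-range inputs (latitudes, cosines, elevations, negative fluxes)
  fail loudly; clipping happens only where the physics dictates it (below
  horizon, derived-component noise, the solar-constant cap).
* Test problem sizes — a ~5°-resolution synthetic day for the pipeline
  checks, 200 randomized cases for the brute-force cosine comparison,
  10 000 samples for metric recovery — were chosen as the smallest sizes
  at which the asserted tolerances are meaningful.
* Leap years are not treated specially (the 365.25-day year is built into
  the angular year fraction); day-of-year is 0-based from 1 January 00 UTC.
* The validation harness reads a package-defined TSV dialect; parsing
  native station-archive formats is left to the user.
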