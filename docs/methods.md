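# Methods

This note records the statistical and physical models implemented in
`dropfreeze`, the defaults and why they were chosen, and the limits of
what the synthetic-data tests demonstrate.

## Frozen fraction and censoring

An assay is a set of droplets, each either frozen at a recorded
temperature or censored (still liquid when the ramp ended). The
cumulative frozen fraction is

    f_ice(T) = #{droplets with freeze temperature >= T} / n_total,

with censored droplets in the denominator only. Excluding them would
bias f_ice upward, and with it every quantity downstream.

## Median freezing temperature

T50 is the sample median over all droplets, with censored droplets
ranked below every observed temperature — the one ordering that is
provably correct, since those droplets did not freeze anywhere in the
ramp. For an even count the median is the mean of the two middle order
statistics. No parametric curve is fitted to f_ice: the median is the
only estimator that needs no model of the curve shape. If fewer than
half the droplets froze, the median falls on a censored droplet and T50
is reported as undefined rather than extrapolated.

Uncertainty comes from a droplet bootstrap: droplets are resampled with
replacement (default 1000 resamples, percentile interval, seed recorded
in the output). Resamples whose median lands on a censored droplet are
discarded; with a defined point estimate these are rare. The percentile
interval of a sample median can, at very small n, exclude the point
estimate by one order statistic; the implementation widens the interval
to keep the bracket invariant.

## Buffer correction

Dissolved buffer salts depress both the equilibrium melting point and
the homogeneous nucleation temperature (a colligative effect). Protein
medians measured in buffer are therefore shifted onto the pure-water
scale by the offset between the water and buffer reference assays:

    T_het = T50(sample) + [T50(water) − T50(buffer)].

The correction is applied to point estimates; when all three medians
carry bootstrap intervals, their half-widths combine in quadrature. The
buffer is treated as a constant temperature offset, not through a
water-activity model — the offset is measured directly by the two
reference assays, which also absorbs buffer-composition differences.

## Ice-active-site density spectrum

Under the singular (time-independent) description, each droplet freezes
at the characteristic temperature of its best nucleation site, and sites
are Poisson-distributed among droplets. The cumulative number of sites
per unit solute mass active at or above T follows from the fraction of
droplets with no active site, 1 − f_ice:

    n_m(T) = −ln(1 − f_ice(T)) / m,   m = c · V_droplet,

reported in sites per gram (per-milligram display is a trivial
rescale). Points with f_ice = 0 carry no information (n_m = 0 boundary)
and points with f_ice = 1 make the estimator divergent; both are
excluded and counted, never clamped.

Because m normalizes concentration away, spectra of the same material at
different concentrations must coincide. The collapse check quantifies
this: for every pair of spectra, the median |log10 ratio| over the grid
points in their common temperature support (log-linear interpolation in
T), passing at ≤ 0.3 — agreement within a factor of 2. The threshold is
a configurable surrogate for what is usually judged by eye on a log
plot; factor-2 is stricter than the typical point scatter of freezing
spectra.

## Classical nucleation theory

Internal unit is kelvin; everything at the API boundary is °C.

* **Chemical potential.** Δμ(T) = k_B T ln(p_liq/p_ice) with the
  Murphy–Koop (2005) saturation-vapor-pressure parameterizations for
  supercooled water and hexagonal ice (enforced validity 150–273.16 K).
  The two curves cross at the triple point, 273.160 K, so a residual of
  order 10⁻⁴ k_B T remains at 273.15 K; the melting-point invariant is
  therefore asserted at the parameterization's own equilibrium
  temperature.
* **Critical cap.** r* = 2 σ_iw v_ice / Δμ, with v_ice = 3.25 × 10⁻²⁹ m³
  per molecule (ice density ≈ 0.92 g cm⁻³, held constant — its variation
  over 230–273 K is far below the σ_iw uncertainty). A cap of contact
  angle γ on a flat surface is reported in both conventions: the
  embryo-sphere diameter 2 r* and the surface footprint 2 r* sin γ.
  The comparison verdict uses the **footprint** by default, because a
  flat binding site limits the circle the cap cuts on it; reports name
  the convention used, and both columns are always emitted.
* **Shape factor.** f(γ) = (2 + cos γ)(1 − cos γ)²/4 scales the
  homogeneous barrier for heterogeneous nucleation; γ defaults to 45°
  (f ≈ 0.0581).
* **Rates.** Homogeneous nucleation uses, by default, the empirical
  water-activity parameterization of Koop et al. (2000):
  log₁₀ J = −906.7 + 8502 Δa_w − 26924 Δa_w² + 29180 Δa_w³ with
  Δa_w = 1 − p_ice/p_liq for pure water. The cubic was fitted for
  0.26 < Δa_w < 0.34; outside that window it extrapolates smoothly and
  underflows to zero at weak supercooling, which is exactly what a
  cooling-ramp simulator needs. The CNT form
  J = A exp(−16π σ³ v²/(3 Δμ² k_B T)) is available with
  A_hom = 10³⁷ cm⁻³ s⁻¹ and A_het = 10²⁶ cm⁻² s⁻¹ (literature
  order-of-magnitude constants, configurable; a decade in A shifts
  predicted temperatures by roughly 1 K).
* **Interfacial energy.** Published σ_iw values scatter widely and CNT
  exponents are brutally sensitive to them: the classical
  Pruppacher–Klett linear form (28.0 + 0.25 T_C mJ m⁻², provided as
  `sigma_id="pruppacher_klett"`) overshoots the empirical homogeneous
  rate by many orders at 236 K. The default, `cnt_fit_linear`
  (σ = 29.5773 + 0.11483 T_C mJ m⁻²), is this package's own calibration:
  a linear fit chosen so that the CNT rate with A_hom = 10³⁷ cm⁻³ s⁻¹
  reproduces the water-activity rate over 234–239 K — the same
  self-consistency practice used for CNT fits in the ice-nucleation
  literature. It extrapolates to 29.6 mJ m⁻² at 0 °C, inside the
  28–32 mJ m⁻² range of direct estimates. Every output table carries the
  parameterization ids that produced it.

## Binding-site geometry

A rectangular ice-binding site d1 × d2 (d1 ≤ d2) hosts a spherical cap
up to d1 across; larger caps must be ellipsoidal with diameters d1 and
d2. Equal mean curvature (the Young–Laplace argument) condenses the two
diameters into an equivalent spherical diameter — the harmonic mean
d_eq = 2 (1/d1 + 1/d2)⁻¹. The size range compared against the CNT line
is [d1, d_eq]; when a molecular weight is known, the cube-edge estimate
L = (MW/(N_A ρ))^(1/3) with ρ = 1.35 g cm⁻³ (the classical
globular-protein density, configurable) is recorded as an alternative
lower bound, since d1 and L are typically close (≈1.7 vs ≈2.0 nm for a
6.5 kDa protein). The verdict is boundary-inclusive: a site exactly as
large as the critical cap can host it.

## Synthetic assays

The generator's defaults are the assay conditions of the experiments
this package targets: 90 µm droplets, 1 °C min⁻¹, ramp −10 → −45 °C,
300 droplets per assay (droplet counts per run are rarely published;
300 gives f_ice resolution of ~0.3 % while keeping tests fast).

* **Homogeneous.** The ramp is discretized in 0.05 °C steps (time step
  dt = step/rate; discretization error ≪ 0.1 °C at 1 °C min⁻¹). Each
  unfrozen droplet freezes in a step with probability
  1 − exp(−J_hom V dt); sampling is by inverse transform on the discrete
  cumulative hazard, which is distributionally identical and vectorizes.
  With the default rate parameterization the simulated pure-water median
  is ≈ −34.6 °C; published homogeneous-rate datasets disagree by about
  1 K in the temperature at fixed J, and this offset from the −35.7 °C
  reference is of exactly that size.
* **Singular.** Site densities follow a log-linear spectrum
  n*(T) = exp(a + b (T0 − T)) — the near-straight form freezing spectra
  show on a log axis, and analytically invertible: a droplet of mass m
  freezes where m n*(T) = −ln u, u ~ U(0,1), so every test has a closed
  form (the median freezes where m n*(T50) = ln 2). The default
  spectrum (a = 23.5135, b = 1.8756 °C⁻¹, T0 = −34 °C) is derived in
  closed form from the target conditions: buffer-scale medians running
  from −37.2 °C at 0.03 mg mL⁻¹ to −35.7 °C at 0.5 mg mL⁻¹.
* **Combined.** Per droplet, the warmer of a singular and a homogeneous
  draw, minus a constant buffer depression (default 2.5 °C, the measured
  water-minus-buffer offset); droplets pushed below the ramp end are
  censored. With zero concentration this is the buffer-only control and
  consumes the same random stream as the homogeneous model, making the
  shift exact and testable to machine precision.

The fixture suite (water + buffer + 0.03/0.1/0.25/0.5 mg mL⁻¹) is
deterministic and byte-identical under a fixed seed; the two middle
concentrations are placeholders for a series whose endpoints are the
documented experimental range. Freezing temperatures are written with
4 decimals (0.1 mK), far below instrument accuracy.

What the synthetic tests do **not** show: the generator draws i.i.d.
droplets of identical volume with a single-component exponential
spectrum and a strictly additive buffer effect. Real assays have droplet
polydispersity, site-composition heterogeneity (curved spectra),
time-dependent (stochastic) nucleation components, and
concentration-dependent non-ideality of the buffer — passing the
recovery and collapse tests demonstrates the estimators are correct
under the stated model, not that the model exhausts real data.

## Numerical choices and degenerate inputs

* Temperatures are validated to (−273.15, 0) °C; assays need ≥ 1
  droplet; empty curves, empty grids, non-positive masses, diameters,
  and rates are rejected with specific errors rather than propagated as
  NaN.
* Curve grids are strictly decreasing; `grid="auto"` is the set of
  unique observed freezing temperatures, making f_ice invariant to input
  row order.
* Exponents of the empirical rate are clipped at 10^±300 to avoid
  overflow; the CNT-form rate underflows to exactly zero at weak
  supercooling.
* Bootstrap seeds, simulator seeds, and parameterization ids are
  recorded in every output; reports contain no timestamps, so reruns on
  identical inputs are byte-identical.

## Known limitations

* T50 uncertainty is reported as a bootstrap CI; instrument accuracy and
  run-to-run spread are separate error sources the package does not
  model.
* The CNT line depends on σ_iw and the kinetic prefactor; the default
  calibration ties it to one empirical homogeneous-rate
  parameterization, and swapping ids moves the line by ~0.5–1 nm at
  −35 °C (monotonicity and all invariants are preserved).
* Whether a published critical-cap size line means the embryo-sphere
  diameter or the cap footprint is convention-dependent; both are
  computed, and consumers must check which one a given comparison uses.
* No differential (per-kelvin) spectra, no image analysis of droplet
  freezing, no water-activity model of the buffer.
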