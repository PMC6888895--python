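# Methods

This note documents the models, parameter choices and numerical
conventions behind `oxilake`, and what the synthetic campaigns do and do
not establish about real data.

## Control volume and geometry

The surface mixed layer (SML) is treated as a single well-mixed control
volume above the thermocline. Its geometry comes from the lake's
hypsometry (depth–area table, depth positive downward, 1-m working grid):
`A_tot` is the planar area at depth 0, `A_th` the planar area at the SML
base, and the volume is the trapezoidal integral of area over the SML.
The littoral sediment area `A_sed` — the surface through which sediment
methane enters the layer laterally — has no unique definition from a
depth–area table alone; the default convention sums the lateral surface
of circular frusta between successive depth contours (equivalent radii
`r = sqrt(A/pi)`), which reduces to the cylinder wall for vertical-walled
basins and to approximately `A_tot − A_th` for gentle slopes. The
projected-ring convention (`A_tot − A_th`) is available as an option; on
the bundled basin fixtures the two agree within ~1%.

## Mass balance and its closures

The budget balances lateral input, thermocline diffusion and internal
(oxic) production against oxidation and emission; river throughflow and
ebullition are structurally zero for the systems targeted (no river
connection; source depths ≥ 20 m). Under steady state the closure for
production in per-volume units is

    P_net = (F_S − F_L − F_z) / (1 − alpha)          (internal_only)
    P_net = (F_S − F_z) / (1 − alpha) − F_L          (internal_plus_lateral)

where `alpha` is the oxidised fraction. The two `mox_scope` variants
differ in whether oxidation also consumes laterally imported methane;
published budget analyses are not consistent on this point, so both are
implemented and every result records which was used. The component-table
reproduction uses `internal_only`; the enclosure-comparison lateral
derivation is the `internal_plus_lateral` arithmetic
(`(F_S − F_z)/((1−alpha)·d) − P_net,enclosure`, `d` = SML thickness).
A non-steady storage term (finite-difference `dC/dt`) is supported for
stratification-onset periods but off by default.

Seasonality: `alpha = 0.3` during stratification (a conservative
oxidation allowance), `alpha = 0` and `F_L = 0` outside it (cold
sediments produce little methane); a transition month is split at
mid-month.

## Monte Carlo propagation

Each of `F_S`, `F_L`, `F_z` is drawn independently from an **untruncated**
normal with its measured mean and SD — negative draws are deliberately
retained, because the probability that the inferred production is
positive is itself a reported statistic. Defaults: 9999 iterations,
`numpy.random.default_rng` seeded explicitly (the seed is part of every
result; no hidden global state). Sample SDs use the n−1 denominator. For
a linear closure of Gaussians the analytic mean and SD
(`sqrt(sd_FS² + sd_FL² + sd_Fz²)/(1−alpha)`) are exact; the test suite
checks the simulation against this closed form and against the Gaussian
CDF for the positive-probability.

## Gas exchange

Chamber fluxes are the least-squares slope of the chamber CH₄ amount
(ideal gas at 1 atm and water temperature, 15-l headspace) versus time,
divided by the footprint area. Transfer velocities:
`k_CH4 = F/(C_surface − C_eq)`, normalised to a Schmidt number of 600 via
`k600 = k_CH4 (Sc_CH4(T)/600)^n` with `n = 1/2` (wavy-surface regime;
configurable to 2/3). `Sc_CH4(T)` uses the Wanninkhof (1992) freshwater
polynomial (≈ 616 at 20 °C); the equilibrium concentration uses the
Wiesenburg–Guinasso (1979) atmospheric solubility fit at zero salinity
with a default mixing ratio of 1.9 ppm (≈ 2.9 nmol l⁻¹ at 20 °C — two
orders of magnitude below typical SML oversaturation, so the exact
solubility choice is immaterial to the budget). The `k600(U10)` relation
is an ordinary least-squares line; alternative published transfer models
can be supplied as coefficients, none are hard-coded. A zero air–water
gradient (or zero flux) makes the inversion degenerate and raises rather
than returning 0.

## Vertical mixing

Density from temperature uses the UNESCO (Millero–Poisson) freshwater
polynomial. Basin-scale diffusivity comes from the heat-budget method:
the rate of change of hypsometrically integrated heat content below each
depth, divided by `A(z)·∂T/∂z` on the time-averaged profile
(centred differences, one-sided at boundaries, calendar-day intervals).
Cells with `|∂T/∂z| < 0.01 °C m⁻¹` (configurable) are flagged undefined —
the method degenerates in well-mixed water — and negative estimates are
treated as artefacts (NaN), never clipped to zero silently. The
thermocline methane flux is `F_z = K_z ∂C/∂z` with the 1-m centred
gradient at the SML base and, conservatively, the **maximum** defined
`K_z` within the bottom 3 m of the SML. Sign convention throughout the
package: flux *into* the SML is positive, so a methane peak below the
layer (concentration increasing downward) gives `F_z > 0`.

## OMC scaling and upscaling

`OMC = 100·P∀/(P∀ + A_sed F_L + A_th F_z)`. The morphology model
`OMC = a·exp(−b·x)` with `x = A_sed/∀` is fitted by OLS after
log-linearisation; `R²` and `p` are reported on the log scale (matching
how such fits are usually quoted) while the standard error is the
back-transformed residual RMSE in OMC percentage points. Lakes reported
as a range enter as the range midpoint. The 50% threshold is analytic:
`x* = ln(a/50)/b`. Predictions are clamped to [0, 100].

Global upscaling weights each size class of a lake inventory by its
emission share (areal intensity × total class area; constant intensity by
default) and averages the per-class OMC predictions. The default
area-to-morphology rule assumes geometric similarity
(`x = c/sqrt(area)`), with `c` fixed so that a 1 km² lake sits at
`x = 0.07 m² m⁻³` — the point where the two published dominance criteria
(area ≥ 1 km², ratio ≤ 0.07) coincide. With the bundled emulated
inventory (power-law abundance over 0.01–10⁵ km², decade classes with
census-order total areas) the emission-weighted global OMC lands in the
50–70% band; it is a band-level check, not a census reproduction — the
actual global figure depends on the inventory and per-class emission
intensities used.

## Synthetic campaigns

The generator produces an internally consistent campaign from imposed
truths: production, lateral input, diffusivity, the k600 relation and
noise levels. The surface emission is *derived* from the steady-state
budget, the surface concentration is then chosen so the wind series
delivers exactly that emission through the true transfer relation, and
chamber series are synthesised from the same relation — so a noise-free
campaign closes the budget to machine precision and the analysis pipeline
must return the imposed production (the end-to-end identity test).
Temperature series evolve by explicit finite-difference vertical
diffusion (CFL-checked), with surface heating confined to a convectively
homogenised upper layer so that below it the heat-budget assumptions hold
exactly. Methane profiles are an SML plateau with a Gaussian thermocline
peak (up to ~1400 nmol l⁻¹, peak ~1 m below the SML base).

Default conditions emulate a mid-size temperate basin in summer: 6-m SML
at ~20 °C over a ~6 °C hypolimnion, `K_z = 1.5×10⁻⁶ m² s⁻¹` below the
mixed layer, lateral input 1.4 mmol m⁻² d⁻¹, production 88 nmol l⁻¹ d⁻¹,
`k600 = 1.98·U10 + 0.94 cm h⁻¹`, wind ~3 ± 1.2 m s⁻¹; noise 5% on
methane and chamber slopes (lognormal on slopes), 0.02 °C on temperature;
component-table SDs mirror observed temporal variability (57% on
emission, 15% on lateral input, 100% on the small thermocline flux).
Campaign sizes (4 weekly profiles, 120 half-hour wind steps, 7 chamber
deployments) are typical of an intensive field season and keep the whole
suite fast.

What passing tests show — and do not. The synthetic campaigns establish
that the estimators are self-consistent, unbiased under the stated noise,
and that the heat-budget method matches an independent forward-diffusion
oracle to within 10%. They do not establish robustness to processes the
generator omits: internal seiches (which alias into heat-budget `K_z`),
lateral heterogeneity of the SML, chamber artefacts at high wind, or
non-Gaussian measurement error.

## Numerical conventions and edge cases

- Depth positive downward, 0 at the surface; 1-m working grid.
- Molar mass of CH₄: 16.04 g mol⁻¹; unit round trips are exact to 1e-12
  relative; unknown units raise, never guess.
- `alpha = 1` is a singular closure (raised); `alpha ∈ [0, 1)` enforced.
- Two-point regressions interpolate exactly and carry an overfit warning;
  degenerate designs (constant wind) raise.
- A negative derived lateral input is returned with a warning flag rather
  than raised — it is physically questionable but informative.
- File writes are atomic (temp file + rename); result JSON echoes the
  full configuration, seed and iteration count; percentages are rounded
  only in the Markdown report layer.

## Known limitations

- `A_sed` is convention-dependent; budgets for steep-sided basins differ
  by a few percent between conventions.
- The heat-budget method yields no estimate in well-mixed water (by
  design); `F_z` then relies on the defined cells near the SML base.
- Whole-system and per-volume component tables from multi-date field
  campaigns need not be mutually consistent under a single fixed volume
  (sampling dates can have different SML thicknesses); both unit tracks
  are supported and no reconciliation is attempted.
- The upscaling result is only as good as the inventory and the
  area-to-morphology rule supplied to it.
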