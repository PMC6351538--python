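# Methods

## The measurement model

Soil-to-atmosphere N₂O flux is measured with non-vented closed static
chambers: a cylinder (height *h* = 0.10 m, internal diameter 0.25 m) is
sealed over the soil and the headspace N₂O mole fraction is sampled at
0, 15, 30 and 45 minutes after closure. Under well-mixed, short-deployment
conditions the mole fraction rises linearly, so the flux estimate is the
OLS slope *b* (ppb min⁻¹) of concentration on elapsed minutes, converted
to an areal nitrogen mass flux with the ideal gas law:

    F = b · 1440 · 10⁻⁹ · P/(R·T) · (V/A) · M_N · 10³   [mg N₂O-N m⁻² d⁻¹]

with *P* the barometric pressure (Pa), *T* the chamber air temperature
(K), *R* = 8.314 J mol⁻¹ K⁻¹, *V/A* = *h* the headspace ratio of a
cylinder (m), and *M_N* = 28 g N per mol N₂O (two nitrogen atoms). The
conversion is exactly linear in *b* and in *V/A* and strictly decreasing
in *T*; both properties are asserted in the tests.

All four points enter the regression; nothing is dropped. Poor fits are
annotated with quality flags (`low_r2` below a configurable r² threshold,
default 0.7; `constant`; `too_few_points`) but never removed — flags make
quality visible without introducing a selection step that would bias
cumulative sums. Negative fluxes are retained throughout for the same
reason. Only the linear model is implemented; a curvature-correcting
model is a deliberate extension point, not a default, because the flux
definition above is the one the downstream statistics assume.

Whether one regresses concentration and then converts, or converts each
reading and then regresses, is immaterial: with one temperature and
pressure per deployment the two orders are algebraically identical. One
temperature/pressure per deployment is assumed; missing values fall back
to configured defaults (101.325 kPa, 25 °C) with a logged warning.

## Cumulative emissions and emission factors

Daily fluxes are integrated per experimental unit by the trapezoid rule
on the elapsed-day axis (day 0 = urine application; the pre-application
baseline sample carries a negative day), then converted mg m⁻² →
kg ha⁻¹ (×0.01). Integration runs from the first to the last sampled day
with no extrapolation. The rule is exact for fluxes linear in time and
invariant under inserting interpolated points; both are tested. The
monitoring-window length is checked against the expected 18–24 days and
reported, not enforced.

The urine-N emission factor is

    EF (%) = (N₂O-N emitted − N₂O-N control) / N applied × 100.

Control subtraction uses the mean cumulative emission of the control
replicates within the same site × pasture condition — replicates are not
paired across treatments, so a per-replicate pairing would be arbitrary.
EF is computed per urine replicate (replicate cumulative − control mean)
and the site EF is the mean of replicate EFs, which yields per-site SEMs.
Negative EFs are possible and kept. When the applied-N amount is unknown
(one reference site's urine could not be assayed) the EF is undefined —
`NaN`/`*` in outputs, never zero, and the site simply drops out of
EF-level inference.

Applied N can be stated directly (kg N ha⁻¹) or derived as
volume × concentration / wetted area × 10. The wetted area is an explicit
parameter defaulting to the chamber base area (0.0491 m²), because a
0.5 L application inside a 25 cm base (≈10.2 L m⁻²) is not consistent
with the nominal 1.27 L m⁻² application rate sometimes quoted for urine
events; making the area explicit avoids silently picking one geometry.

## Inference

Cumulative emissions are log-transformed before ANOVA with a recorded
offset δ = half the smallest positive value (controls can sit at or below
zero); EFs are square-root transformed with a recorded shift
s = −min(0, min EF). Both transforms are invertible on the data range and
their parameters are echoed into the run manifest.

Three classical fixed-effects analyses are written out directly as
expected-mean-square F-tests rather than delegated to a mixed-model
fitter, so each error stratum is explicit and unit-testable:

* **Split-plot ANOVA** (cumulative emissions): locations are blocks,
  pasture condition is the main-plot factor tested against
  condition-within-location (the main-plot error, (a−1)(b−1) df), and the
  nitrogen level (urine vs control) and its interaction with condition
  are tested against the pooled residual. The decomposition sums exactly
  to the total SS; the suite cross-checks every stratum against an
  independent sequential-SS OLS fit and against brute-force cell-sum
  bookkeeping on integer data, verifies the condition test's type-I error
  (0.05 ± 0.02 over 1000 null simulations at the full 7-site design), and
  confirms consistency with an exact restricted permutation test that
  swaps condition labels within locations.
* **Blocked one-way ANOVA** (EFs): randomized-complete-block
  decomposition with location blocks; with one EF per site × condition
  (the default "site-mean" mode) and two conditions, F(Condition) equals
  the paired-t statistic squared, which is tested. A replicate-EF mode
  with site as block is available by configuration.
* **Per-site t-tests** (EFs): two-sample, pooled variance by default
  (Welch by flag), two-sided, with significance letters at α = 0.05
  (same letter ⇔ p ≥ α). Zero-variance equal-mean groups return t = 0,
  p = 1 by convention. No multiple-testing correction is applied across
  sites — each site is reported on its own, and that choice is stated
  rather than hidden.

Because the regional cumulative contrast is conventionally judged at the
10% level while site contrasts use 5%, both α levels live in the
configuration (`alpha`, `alpha_regional`).

Site EFs are regressed on total campaign rainfall (including the week
before monitoring began) separately per pasture condition, by OLS with
one point per site; slope, intercept and r² are reported, and at least
three sites are required.

## The synthetic campaign generator

The generator is phenomenological — it emulates what chambers see, not
soil biogeochemistry (no water-filled pore space, no
nitrification/denitrification kinetics). Each unit's true daily flux is

    f(t) = baseline + A · [(t/p)·exp(1 − t/p)]^(p/τ)   for t ≥ 0,
    f(t) = baseline                                     for t < 0,

a surge-decay pulse peaking at exactly baseline + A on day p (default 3),
with τ (default p) sharpening or stretching the tail; the gamma-like
delayed peak reproduces the few-days-after-application maxima typical of
urine patches better than a pure exponential decay. Controls carry the
baseline only. The pulse amplitude is proportional to applied N
(0.022 mg m⁻² d⁻¹ per kg N ha⁻¹ at the AVC reference), multiplied by the
condition effect (LVC:AVC = 2.33, the regional EF ratio of the reference
campaign), a site effect, and a replicate effect.

Site effects are multiplicative log-normal with mean 1 (σ = 0.8),
matching the strictly positive, right-skewed spread of cumulative
emissions across sites (0.02–7.5 kg ha⁻¹), and are **shared by both
conditions of a site**, so the true LVC:AVC EF ratio equals the
multiplier ratio by construction. Replicate effects are log-normal with
σ = 0.3, chosen so simulated site SEM/mean ratios (≈13% with n = 5)
sit at the scale of the reference campaign's reported site SEMs; no
replicate-level dispersion is published, so this is a modelling choice,
not a fit.

Measurement noise is iid Gaussian on each concentration reading
(default 2 ppb around an ambient of 330 ppb), i.e. at the instrument
level, never on the flux. The chamber slope is the exact ideal-gas
inverse of the true flux, so a zero-noise campaign round-trips through
the full pipeline to its ground truth at float precision — the key
end-to-end identity in the acceptance suite. Ground truth (per-unit
fluxes and cumulatives, per-site EFs) is integrated on the same sampling
days as the measurements, making truth and estimate directly comparable
without discretization error.

Randomness uses one root seed spawning an independent child stream per
site, so adding a site never perturbs the draws of existing sites
(tested). The default design is 7 sites × 2 conditions × 2 treatments ×
5 replicates with sampling days (−1, 0, 1, 2, 3, 7, 10, 14, 17, 21) —
a pre-application baseline, the post-application day, daily sampling for
three days, twice-weekly through week three, once in the final week —
and per-site applied N of (464, 789, 112, 619, 1641, 546, 500) kg ha⁻¹.
Weather is per-site daily rainfall (Bernoulli wet days, gamma amounts)
and air temperature around a site mean, spanning one week before
application through the last sampling day.

What passing tests on synthetic campaigns do **not** show: the generator
has no spatial correlation, no temperature dependence of the pulse, no
rainfall-triggered re-peaks unless `rain_coupling` is switched on, and
its noise is homoscedastic in concentration. Agreement of the pipeline
with this generator's truth validates the arithmetic and the error-strata
bookkeeping, not the ecological realism of any particular field campaign.

## Numerical choices and degenerate inputs

* OLS slopes use the closed-form Σ formulas; r² is undefined (NaN) for
  zero concentration variance and the series is flagged `constant`.
* F statistics are NaN when their denominator mean square is zero
  (all-equal responses); sums of squares are clipped at 0 against
  −1e-16-scale round-off.
* Validation never raises on dirty data: `validate_campaign` returns a
  complete violation list with record coordinates; ingestion raises only
  for structural impossibilities (missing columns, orphan chambers,
  duplicate design rows).
* Result CSVs are written with 6-significant-digit floats and fixed
  column order, so reruns are byte-identical and diffable.

## Problem sizes used by the test and analysis runs

The shipped analyses run the full default design (140 units, 1400
deployments; seconds of compute). The test suite uses 2-site versions of
the same design for most end-to-end checks, the full 7-site design for
type-I calibration (1000 simulations), 100 seeds of the 2-site design
for parameter recovery, and a 4-site × 3-replicate design at 200
simulations per effect level for the power-monotonicity check. These
sizes are the package's chosen verification scale; all are configurable
upward through `CampaignDesignSpec`.

## Known limitations

* Linear flux model only; chamber-induced suppression of the gradient at
  long deployments is not corrected (the flag mechanism is the hook).
* EF is a one-month, direct-emission quantity: no annualization, no
  gap-filling, no leaching/volatilization (indirect) pathways.
* The split-plot/ RCBD implementations require balanced designs;
  unbalanced field campaigns need a mixed-model treatment that is
  intentionally out of scope here.
* Site-level regional inference treats the site EF as one observation;
  with 7 sites the rainfall regression has little leverage against
  influential sites, which is inherent to the design, not the estimator.
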