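# Methods

This note records the models, the defaults and the numerical choices behind
`cytohts`, and what the synthetic-data generators do and do not emulate.

## Death-fraction metrics and hit calling

The primary readout is the per-well dead/dying fraction: dead-stain objects
over live-stain objects, with the four imaging fields pooled by **summing
counts before taking the ratio**.  Pooling sums rather than averaging
per-field ratios keeps a sparse field from producing an unstable or
infinite ratio; with balanced fields the two definitions coincide.
Fractions above 1 are possible in principle (dye semantics) and are
QC-flagged rather than clipped.  Missing timepoints are errors, never
interpolated — interpolation would silently bias the AUC.

The AUC metric is the plain trapezoid of fraction over hours across the
0/24/48/72 h schedule, without baseline subtraction by default (a
`baseline_subtract` option exists).  Robust location/spread are median and
1.4826·MAD, the standard HTS choice; MAD = 0 falls back to IQR/1.349 and a
fully degenerate population is an explicit error.  Z-scores are computed on
normalized activities (either normalization scheme is affine, so the choice
does not alter z) over the library population, per plate by default with a
pooled option.

Sign convention: the raw death metrics *increase* with killing while the
selection rule is z < −3, so death-oriented metrics are negated before
z-scoring ("killing negative", a viability-like orientation); endpoint
luminescence already falls with killing and is not flipped.  A flag exposes
the raw orientation.

## Secondary triage

"Cell suppression" is defined per metric: for the luminescent viability
endpoint it is vehicle-relative signal loss, 100·(1 − RLU/median(vehicle));
for imaging metrics it is the control-window normalized effect (vehicle =
0, positive control = 100).  All three filter inequalities are strict, so
boundary equality (a 40.0-point difference, exactly 50% suppression) fails.
The two qualifying doses for selectivity need not be adjacent.  Replicates
are aggregated by median per (compound, cell line, dose) before filtering.

## Four-parameter logistic

The model is y(d) = bottom + (top − bottom)/(1 + 10^((log₁₀d − log₁₀IC50)·h)),
decreasing in dose for h > 0, with the midpoint (top+bottom)/2 at the IC50.
Fitting is bounded least squares (`scipy.optimize.least_squares`, tolerances
1e−12) with multi-start over h ∈ {0.5, 1, 2}; starts use top = max response,
bottom = min response, log IC50 = median log dose; best RSS wins, ties
broken by smallest |h|.  Default bounds: bottom ∈ [−10, 60], top ∈ [50,
150], h ∈ [0.05, 10], log IC50 within the data range ± 3 decades; a
`constrain_0_100` preset pins the plateaus for normalized-viability data.
Replicate points all enter the loss (no pre-averaging).  Non-convergence
from every start is an explicit error.

ICx is closed-form inversion.  The default mode is **absolute** on the
fraction-affected scale (fa = 1 − y/100 = x), because the combination index
needs doses achieving one common absolute effect across agents; relative
mode (span fraction) is available.  A plateau that prevents attaining x
yields `reachable=False`, deliberately distinct from fit failure.

The median-effect fit (log₁₀(fa/(1−fa)) regressed on log₁₀ dose) is provided
as an independent route to Dm and m.  It is exact on model data but very
noise-sensitive at the fa tails, where the logit diverges; practical use
should feed it mid-range points (the worked example uses fa ∈ (0.05,
0.95)).

## Combination analysis

All synergy computations run on the fraction-affected percent scale.
For fixed-ratio designs the combination's viability is fitted with the same
4PL along the drug-1 axis; CI at level x is D₁/(Dₓ)₁ + D₂/(Dₓ)₂ with D₂ =
ratio·D₁.  A level unreachable on any curve produces a per-level marker,
not a global failure.

Band boundaries are left-closed at 0.3/0.7/0.9 and right-closed at
1.1/1.45 — the printed intervals ("between 0.3 and 0.7") leave closure
ambiguous, so one convention is fixed, documented and tested; the partition
of [0, ∞) is total.

Loewe expected effect solves d₁/D₁(E) + d₂/D₂(E) = 1 by bisection on E with
tolerance 1e−8 in effect, bracketed between the larger single-agent effect
(where the dose sum is ≥ 1) and the higher plateau.  When one agent's
plateau prevents reaching E its reciprocal term is treated as 0 (infinite
dose requirement), the fallback convention used by matrix-synergy tools
when efficacies differ.  Because 4PL plateaus are asymptotic, the root
always exists just below the joint plateau; the cap-and-flag branch guards
degenerate numerics only.  HSA is max of the two single-agent effects.
Matrix summaries report mean delta and the peak delta with row-major
tie-breaking.

## Power, ddCt, proliferation ratio

The group-size computation iterates n upward from 2 (the minimum fittable
group) until the two-sided, equal-n, noncentral-t power reaches the target;
sidedness is a flag.  The noncentral-t lower tail can underflow in scipy at
large noncentrality and is treated as 0 there.  For the tumor-volume design
(Δ = 400, sd = 125, α = 0.05, power 0.80) the answer is 3 per group
(power(3) = 0.829, power(2) = 0.423).  2^−ΔΔCt and the (S+G2)/(subG1+G1)
ratio are direct arithmetic with domain guards.

## Synthetic data: what it emulates, and what it does not

Primary plates are 384-well with vehicle and positive-control columns (16
wells each by default), library wells at the 5 µM screening dose, 0/24/48/72
h timepoints and 4 fields per well; cell seeding defaults follow the assay
presets (400/600/900 cells per well depending on line).  Death kinetics per
well follow the simplest monotone saturating law, f(t) = f_max·(1 −
e^(−kt)); the null population draws f_max ~ N(0.10, 0.02) and actives are
shifted upward by `effect_sigma` null SDs (default 8).  Counts are Poisson
(live-stain, around exponential growth with a 32 h doubling) and
Binomial(tracker, f(t)) (dead-stain); an overdispersion knob is
deliberately absent from the default path.  The positive control mimics a
strong killer (f_max ≈ 0.75).

Calibration caveat: because the Binomial count variance grows with f, wells
in the high-death tail carry slightly more noise than the median well, so
the null one-sided z < −3 rate is mildly inflated (~0.17% observed vs the
Gaussian 0.135%) while the two-sided |z| ≥ 3 rate is calibrated at 0.27%.
Binomial 99% bounds in the calibration checks absorb this.  Real screens
add plate-position and batch effects that the generator omits by default,
so passing tests demonstrate correctness of the statistics, not robustness
to spatial artifacts (an optional edge gradient exists for stress testing).

The secondary-screen generator plants archetype compounds (pan-filter
passers, pan-toxic, inactive, weakly selective, off-target-toxic) whose
mean profiles keep ≥ 8-point margins from every filter boundary, with
replicate noise sd 1.5, so that the planted label set is recovered exactly
with overwhelming probability at any seed.

Dose–response simulation adds Gaussian noise to 4PL truth and truncates to
[−20, 150] viability points (instrument-plausible range).  Matrix
simulation generates exactly under Loewe, HSA or Bliss (Bliss exists only
as generator ground truth, not as a reporting model), or Loewe plus a
planted effect-point boost in chosen cells.

## Problem sizes and stochastic tolerances

The shipped checks use 2,600 simulated compounds (8 plates) for hit-calling
calibration, 200 seeded runs for noisy 4PL recovery, 10,000 simulations for
the power cross-check, and 8-dose/4-replicate assays (the standard
viability-assay design) for dose–response and sham-combination checks; the
whole suite runs in well under a minute of simulation time.  The sham CI at
high effect levels (x = 0.9) is intrinsically noisy under viability noise —
inverting the fitted curve deep in its tail amplifies slope error, giving a
per-run sd near 0.2 at noise sd 5 — so noisy-CI checks at a single seed use
the ±0.1 band at the canonical seed while the distributional test asserts
unbiasedness of the mean over 20 seeds.

## Known limitations

- No plate-effect correction (B-score, median polish): the underlying
  workflow applies none, and the scope ends at robust Z-scores.
- Hit counts from a real screen depend on the library's true activity
  distribution; the generator makes no attempt to reproduce any specific
  compound collection.
- Loewe inversion assumes monotone single-agent fits; non-monotone
  (hormetic) responses are out of scope.
- The CLI reads/writes plain CSV/TSV/JSON only; no plotting is
  load-bearing.
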