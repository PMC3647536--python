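# Methods

## Model

The health state x(t) of a relapsing–remitting patient follows the Langevin
equation

    dx = [x(1 − αx²) − β] dt + ε^{1/2} dw,

the overdamped motion in the quartic potential
V(x) = −x²/2 + αx⁴/4 + βx driven by a Wiener process with noise variance ε
per unit time. One model time unit is one week, so simulated residence times
are directly comparable with weekly clinical records. The stationary points
are the real roots of αx³ − x + β = 0: for 27αβ² < 4 there are three —
x_health < x_saddle < x_disease — and the potential is bistable; at
27αβ² = 4 the disease well vanishes in a saddle-node bifurcation and the
two-state description of the course breaks down, so the package raises a
`BifurcationError` there. The identification of the *left* (negative)
stable root with health follows the clinical coding (−1 = remission) and the
fact that the +βx tilt lowers the potential at negative x: for β > 0 the
health well is the deeper one (ΔV₁ > ΔV₂), encoding that remissions outlast
relapses.

Assumptions worth stating explicitly: the patient is a one-dimensional
diffusion with a *fixed* potential (no disease progression, no therapy, no
seasonal forcing); transitions are abrupt (the clinical ±1 step encoding);
and the noise is white with constant variance.

## Exit times and the inverse problem

In the small-noise limit the mean residence time in a well of depth ΔV is
taken as

    τ ≈ exp(2ΔV/ε),

deliberately **without** the Kramers curvature prefactor
2π/√(V''(x_min)·|V''(x_saddle)|) (≈ 4.4 for the symmetric well at α = 1,
larger still once saddle recrossings on the way to the opposite minimum are
counted). Absolute times from this formula are therefore order-of-magnitude
only; what is quantitative is the *exponent*: the slope of ln τ versus 1/ε.
The simulation check (`kramers_slope_check`) regresses ln(mean sampled exit
time) on 1/ε and recovers 2ΔV within a few percent (measured 0.486 vs 0.5
at ΔV = 0.25 over ε ∈ [0.08, 0.20], 150 exits per level), while the fitted
intercept ≈ 1.7 quantifies the omitted prefactor.

Taking logs of the residence-time law in each well and forming the ratio
gives the barrier-ratio estimator

    ΔV₁/ΔV₂ ≈ ln(τ_health)/ln(τ_disease),

with *natural* logarithms and durations expressed in weeks. The estimator is
unit-dependent (logs of dimensionful numbers) and undefined for mean
durations ≤ 1 week; the pipeline flags such patients
(`estimator-undefined`) instead of raising, and likewise flags
`inverted-asymmetry` when remissions are shorter than relapses.

The inverse problem fixes α = 1 — one observable (the ratio) identifies one
parameter, and α only rescales both wells — and solves
β ↦ ΔV₁(β)/ΔV₂(β) = r by bracketed Brent search on [0, √(4/27)). The map is
strictly increasing and diverges at the bifurcation, so any r ≥ 1 is
attainable; the solver verifies the bracket and reports the attainable range
otherwise. Roots of the cubic are obtained from the companion matrix
(`numpy.roots`) and polished with Newton steps to drift residuals < 1e-10,
which stays accurate near the bifurcation where naive closed forms lose
precision.

A documented inconsistency in the published worked example: the forward map
gives ΔV₁/ΔV₂ = 10.77 at β = 0.25, not the 11.8 quoted for the most
asymmetric sample patient, and the exact inverse of 11.8 is β = 0.2565
(verified independently with 30-digit exact-root arithmetic), which rounds
to 0.26, not 0.25. The package implements the inverse direction exactly as
defined and reports the faithfully computed value; the corresponding
two-decimal acceptance test is expected to fail and is left failing rather
than forced. The other two patients (ratios 5.3 → β 0.19 and 2.7 → β 0.12)
round-trip cleanly.

## Numerical integration and residence statistics

The SDE is integrated by Euler–Maruyama,
x_{k+1} = x_k + drift(x_k)·dt + √(ε·dt)·z_k, with dt defaulting to 0.01
weeks. A stability guard rejects dt ≥ 0.1/max|drift'| at the minima
(dt < 0.05 at α = 1), and any |x| > 10 aborts with a divergence error.
Noise is drawn from one `numpy.random.default_rng(seed)` per simulation, so
trajectories are bit-for-bit reproducible from their config; halving dt
moves mean exit times by less than two Monte-Carlo standard errors (tested).
Inner loops are numba-compiled; pre-drawn noise keeps the RNG semantics
identical to pure numpy.

Continuous trajectories become two-state sequences by a **two-threshold
hysteresis rule**: the label commits to health only when x first reaches
x_health and to disease only when x first reaches x_disease; between
commitments the previous label persists, and samples before the first
commitment are transit. This is the standard way to count residences in
bistable systems without inflating the count with saddle jitter. Residence
durations are maximal constant-label runs: the first committed run starts at
a known time (t = 0 or the first commitment) and is counted; the trailing
run is right-censored and excluded; means use complete runs only. Exit-time
*sampling* (`sample_exit_times`) uses the equivalent renewal scheme — start
at a well bottom, integrate to commitment at the opposite minimum, record,
reset — giving i.i.d. first-passage times.

Simulated exit times at ε = 0.13 are exponential in shape: the pooled
coefficient of variation over ≥ 300 complete residences lies in
[0.85, 1.15] (tested), matching the exponential decay of the clinical
duration histograms.

## Course records

A patient course is a weekly ±1 series; under the clinical convention week 0
is the onset of the first relapse, so series start at +1 (courses generated
directly from model trajectories may begin in remission and carry
`start_convention=False`; when a relapse exists the series is trimmed to the
first relapse week instead). Episodes are maximal runs (exact run-length
round trip, property-tested); weeks are 0-based and an episode occupies
[start, start + duration). Durations are integer weeks ≥ 1 ("round up to
one week"). The final episode of every course is truncated by the end of
observation; it is excluded from duration means by default, with
`include_censored=True` for sensitivity analysis (whether the published
means include it is unstated; both modes are provided).

Exponential goodness of fit uses the sample-mean MLE and a one-sample KS
test against the fitted exponential. Two caveats are attached to the
p-value: fitting the mean on the same data makes the test conservative, and
week discretisation inflates the KS statistic for short-duration samples.
The KS test is an extension beyond the purely visual histogram argument of
the source analysis.

## Synthetic cohorts

`generate_cohort` emulates the undeposited 70-patient dataset: alternating
episodes starting with a relapse, durations Exp(state mean) rounded up to
whole weeks, truncation at the observation span. Defaults are the stated
study conditions: 70 patients, mean relapse 4.3 wk, mean remission 100 wk,
spans on [40, 1311] wk.

Design choices where the source is silent:

- **Week rounding.** ceil(Exp(m)) has mean 1/(1 − e^{−1/m}) — a positive
  bias of ≈ +0.52 wk at m = 4.3 and ≈ +0.50 wk at m = 100 — which recovery
  tests target explicitly rather than the latent means.
- **Heterogeneity.** One log-normal severity multiplier per patient
  (median 1, CV 0.5 by default) scales *both* state means, in the spirit of
  a shared frailty; CV 0.5 spans the observed spread of per-patient
  remission means (≈ 47–118 wk). A single shared multiplier (rather than
  independent per-state multipliers) keeps the pooled log-ratio centred:
  pooling weights patients by episode count (∝ 1/multiplier), which under a
  shared multiplier biases both pooled means by the same harmonic factor and
  largely cancels in the ratio, whereas independent multipliers would
  depress the pooled ratio by ~15%.
- **Span law.** Truncated exponential on [40, 1311] wk with the scale
  calibrated (by root-finding at config time) so that 36% of spans fall at
  or below 200 weeks — the only quantitative anchor available for the span
  distribution.
- **Substreams.** Each patient draws from an independent child of the master
  `SeedSequence`, so cohorts are reproducible and patients independent.

**What passing recovery tests do and do not show.** The generator's pooled
*relapse* mean and pooled barrier ratio recover their targets within 15%
(measured 4.60 vs 4.82 and 2.79 vs 3.16 over 20-seed batteries). The pooled
*remission* mean does not — and cannot, under these conditions: a ~100-week
episode rarely completes inside an observation window whose law (mean ≈ 370
wk, minimum 40 wk) matches the clinical span description, so
complete-episode pooling is length-biased low. Measured decomposition:
window censoring alone gives 77 wk (−23%); heterogeneity weighting alone
gives 91 wk (−9%); jointly ≈ 70 wk (−30%). Even fixing every span at the
1311-week maximum only reaches 94.5 wk. The corresponding acceptance test is
left failing: the published "≈ 100 weeks" is itself a windowed, censored
observation, and no span law consistent with the described cohort avoids the
bias. This is a property of windowed event histories generally, not of this
generator — real cohort estimates carry the same bias.

**Closed-loop bias.** Courses generated from the SDE itself
(`generate_from_model`) and pushed through the inference chain return β̂
systematically *below* the generating β (measured −31% to −48% over
β ∈ {0.12, 0.19}, ε ∈ [0.1, 0.2], shrinking as ε decreases): the omitted
prefactor multiplies both residence times, adding a constant to both logs
and compressing their ratio. The closed-loop test asserts the sign, the
ordering in β and a factor-two envelope at moderate noise, documenting the
bias instead of hiding it. Per-patient ε̂ values from clinical durations
(≈ 0.2–0.24) inherit the same caveat and should be read as effective, not
physical, noise variances.

## Problem sizes and tolerances

Simulation-based checks use dt = 0.01 wk throughout; the Kramers-exponent
check uses 150 exits per noise level over ε ∈ {0.08, 0.10, 0.13, 0.16,
0.20} (slope tolerance 15%); the exponentiality check uses a single
120,000-week trajectory at ε = 0.13 (≥ 300 residences); cohort recovery uses
20-replicate seed batteries of 70 patients. Root residuals are held to
1e-10, β round trips to 1e-8, the solver itself to ~1e-13 in β, and the
noise-inversion round trip to 1e-12 relative. Hypothesis-based property
tests run derandomised.

## Limitations

- No disease progression, covariates, therapy effects, or secondary
  progressive conversion; the potential is time-invariant.
- The exit-time law is prefactor-free by construction; absolute residence
  times and ε̂ are order-of-magnitude (see closed-loop bias above).
- Week discretisation is handled as continuous-exponential-plus-ceiling;
  no discrete (geometric) duration model is offered.
- Estimates for patients with mean durations ≤ 1 week are undefined by the
  estimator itself, not by implementation choice.
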