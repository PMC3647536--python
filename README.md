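# msdwell

Stochastic double-well modelling of the relapsing–remitting multiple
sclerosis (RRMS) disease course.

## The problem and the model

In its early phase MS alternates between relapses (disease activity) and
remissions, with no periodicity: relapse onsets look random in time, relapse
durations are short (a few weeks) and remissions long (on the order of 100
weeks), and both are approximately exponentially distributed. `msdwell`
implements a minimal mechanistic–stochastic account of this course: the
health state *x* of a patient moves like an overdamped particle in an
asymmetric quartic double-well potential

```
V(x) = −x²/2 + α·x⁴/4 + β·x
dx   = [x(1 − αx²) − β] dt + ε^{1/2} dw
```

The two minima are the *health* (x ≈ −1, remission) and *disease* (x ≈ +1,
relapse) states; α > 0 controls the barrier height, β ≥ 0 tilts the
potential so the health well is deeper, and white noise of variance ε —
standing in for random biological variability such as gene-expression
noise — drives the erratic switching. The system is bistable iff
27αβ² < 4. In the small-noise limit the mean residence time in a well of
depth ΔV is τ ≈ e^{2ΔV/ε} (prefactor-free), so the log-ratio of observed
mean residence times,

```
ΔV₁/ΔV₂ ≈ ln(τ_health) / ln(τ_disease)      (durations in weeks),
```

estimates the asymmetry of a patient's potential, and inverting the
monotone β ↦ ΔV₁/ΔV₂ map (at α = 1) recovers the patient-specific tilt β.

The package provides, as importable modules:

- `msdwell.potential` — closed-form well geometry, barriers, exit-time
  algebra, the log-ratio barrier estimator and the β inversion;
- `msdwell.simulate` — seeded Euler–Maruyama integration, two-threshold
  hysteresis labelling, residence-time statistics, Kramers-exponent checks;
- `msdwell.records` — weekly ±1 patient course records, episode run-length
  encoding, censoring-aware duration summaries, exponential fits, cohort CSV
  I/O;
- `msdwell.cohort` — synthetic cohorts emulating the clinical encoding
  (70 patients, mean relapse 4.3 wk, mean remission 100 wk, observation
  spans 40–1311 wk), plus model-generated courses;
- `msdwell.pipeline` — the per-patient and pooled inference chain and JSON
  reports.

A thin CLI (`msdw generate|simulate|analyze|fit-beta`) wraps these, and
`examples/` contains one narrative script per capability.

## Worked example

```python
from msdwell import (PotentialParams, barrier_ratio_from_durations,
                     solve_beta, steady_states)

tau_health, tau_disease = 54.0, 2.1        # mean durations, weeks
ratio = barrier_ratio_from_durations(tau_health, tau_disease)
beta = solve_beta(ratio, alpha=1.0)
geo = steady_states(PotentialParams(1.0, beta))
print(ratio, beta, geo.dv_health, geo.dv_disease)
```

prints `5.376 0.192 0.469 0.087`: a patient with 54-week remissions and
2.1-week relapses has a health well about 5.4× deeper than the disease
well, reproduced by a tilt β ≈ 0.19. Running
`python examples/potential_geometry.py` does this for three sample patients:

```
patient 23: tau_h= 117.7 wk  tau_d= 1.5 wk  barrier ratio=11.76  beta=0.256  dV_h=0.555  dV_d=0.047  eps=0.233
patient 32: tau_h=  54.0 wk  tau_d= 2.1 wk  barrier ratio= 5.38  beta=0.192  dV_h=0.469  dV_d=0.087  eps=0.235
patient 53: tau_h=  47.0 wk  tau_d= 4.3 wk  barrier ratio= 2.64  beta=0.118  dV_h=0.378  dV_d=0.143  eps=0.196
```

and `python examples/kramers_exponent.py` verifies the simulator against the
exit-time law: the regression of ln(mean simulated exit time) on 1/ε gives a
slope of 0.486 against the theoretical 2ΔV = 0.5 (2.7% off), with the
intercept absorbing the curvature prefactor the closed form omits.

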