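"""Well geometry and the duration -> asymmetry inversion for three sample patients.

For each patient the mean remission (health) and relapse (disease) durations,
in weeks, estimate the barrier-depth ratio of their double-well potential as
ln(tau_health)/ln(tau_disease); inverting the ratio map at alpha = 1 gives the
tilt beta of a potential whose wells are asymmetric in exactly that ratio.
"""

from msdwell import (
    PotentialParams,
    barrier_ratio_from_durations,
    noise_from_exit_time,
    solve_beta,
    steady_states,
)

PATIENTS = {"23": (117.7, 1.5), "32": (54.0, 2.1), "53": (47.0, 4.3)}

print("symmetric reference (alpha=1, beta=0):", steady_states(PotentialParams(1.0, 0.0)))
print()
for pid, (tau_health, tau_disease) in PATIENTS.items():
    ratio = barrier_ratio_from_durations(tau_health, tau_disease)
    beta = solve_beta(ratio, alpha=1.0)
    geo = steady_states(PotentialParams(1.0, beta))
    eps = noise_from_exit_time(geo.dv_health, tau_health)
    print(
        f"patient {pid}: tau_h={tau_health:6.1f} wk  tau_d={tau_disease:4.1f} wk  "
        f"barrier ratio={ratio:5.2f}  beta={beta:.3f}  "
        f"dV_h={geo.dv_health:.3f}  dV_d={geo.dv_disease:.3f}  eps={eps:.3f}"
    )
print()
print("A larger ratio means the health well is much deeper than the disease well:")
print("long remissions, short and rare relapses. eps is the noise variance that")
print("would make the prefactor-free exit-time formula reproduce tau_health.")
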