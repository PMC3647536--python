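"""Simulate the stochastic health-state equation and extract residence times.

Integrates dx = [x(1 - x^2) - beta] dt + sqrt(eps) dw with beta = 0.08 and
eps = 0.13 (a small tilt: the health well is slightly deeper), labels the
trajectory with the two-threshold hysteresis rule and summarises how long the
model patient stays in each state.
"""

import numpy as np

from msdwell import (
    PotentialParams,
    SimulationConfig,
    label_states,
    residence_times,
    simulate,
)

config = SimulationConfig(
    params=PotentialParams(alpha=1.0, beta=0.08),
    epsilon=0.13,
    n_steps=2_000_000,  # 20,000 weeks at dt = 0.01
    dt=0.01,
    x_init=-1.0,
    seed=3,
)
trajectory = simulate(config)
labels = label_states(trajectory)
summary = residence_times(labels, config.dt)

print(f"simulated {config.n_steps * config.dt:.0f} weeks (seed {config.seed})")
print(f"complete residences: {len(summary.health_durations)} health, "
      f"{len(summary.disease_durations)} disease")
print(f"mean health (remission) residence: {summary.mean_health:8.1f} weeks")
print(f"mean disease (relapse) residence:  {summary.mean_disease:8.1f} weeks")
print(f"fraction of time committed to health: {np.mean(labels == -1):.2f}")
print()
print("Even this small tilt makes remissions an order of magnitude longer than")
print("relapses, while the switching itself stays erratic (noise-driven).")
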