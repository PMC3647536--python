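"""Stochastic simulation of the health-state equation and residence times.

The health state evolves by the Langevin equation

    dx = [x*(1 - alpha*x**2) - beta] dt + sqrt(epsilon) dw

integrated with the Euler-Maruyama scheme,

    x_{k+1} = x_k + drift(x_k)*dt + sqrt(epsilon*dt)*z_k,   z_k ~ N(0, 1).

One model time unit is one week, so simulated residence times are directly
comparable with clinical relapse/remission durations.

A continuous trajectory is turned into the two-state clinical description by
a two-threshold hysteresis rule: the label commits to *health* only when x
first reaches the health minimum and to *disease* only when x first reaches
the disease minimum; in between, the previous committed label persists.
This prevents jitter around the saddle from being counted as transitions,
the standard practice for residence-time statistics of bistable systems.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import em_path, first_passage_chunk
from .potential import PotentialGeometry, PotentialParams, steady_states

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "Trajectory",
    "ResidenceSummary",
    "KramersSlopeFit",
    "simulate",
    "label_states",
    "residence_times",
    "sample_exit_times",
    "kramers_slope_check",
    "write_trajectory_csv",
]

HEALTH, TRANSIT, DISEASE = -1, 0, 1

_CHUNK = 1 << 20  # noise increments drawn per kernel call in renewal sampling


class SimulationError(RuntimeError):
    """Raised when a trajectory diverges or a config is numerically unsafe."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one trajectory bit-for-bit."""

    params: PotentialParams
    epsilon: float
    n_steps: int
    dt: float = 0.01
    x_init: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not (self.epsilon >= 0 and math.isfinite(self.epsilon)):
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")

    def stability_limit(self) -> float:
        """Largest dt considered safe: 0.1 / max |drift'| at the minima."""
        if self.params.is_bistable:
            geo = steady_states(self.params)
            xs = (geo.x_health, geo.x_disease)
        else:
            xs = (self.x_init,)
        lipschitz = max(abs(1.0 - 3.0 * self.params.alpha * x**2) for x in xs)
        return math.inf if lipschitz == 0 else 0.1 / lipschitz


@dataclass(frozen=True)
class Trajectory:
    """A simulated path: uniformly spaced times (weeks) and states."""

    times: np.ndarray
    states: np.ndarray
    config: SimulationConfig

    def __len__(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class ResidenceSummary:
    """Complete residence times extracted from a labelled trajectory.

    Durations are in weeks; the trailing (right-censored) run is excluded.
    ``n_transitions`` counts committed-state switches.
    """

    health_durations: list = field(default_factory=list)
    disease_durations: list = field(default_factory=list)
    mean_health: float = math.nan
    mean_disease: float = math.nan
    n_transitions: int = 0


def simulate(config: SimulationConfig) -> Trajectory:
    """Integrate the health-state SDE with Euler-Maruyama.

    Noise increments come from ``numpy.random.default_rng(config.seed)``, so
    identical configs give identical trajectories.  Raises
    :class:`SimulationError` if |x| exceeds 10 (step size too large) or if
    dt violates the stability guard at the potential minima.
    """
    limit = config.stability_limit()
    if config.dt >= limit:
        raise SimulationError(
            f"dt={config.dt} is too large for stable integration near the minima "
            f"(require dt < {limit:.4g})"
        )
    rng = np.random.default_rng(config.seed)
    scale = math.sqrt(config.epsilon * config.dt)
    if scale > 0:
        noise = scale * rng.standard_normal(config.n_steps)
    else:
        noise = np.zeros(config.n_steps)
    states = np.empty(config.n_steps + 1)
    diverged = em_path(config.x_init, config.params.alpha, config.params.beta,
                       config.dt, noise, states)
    if diverged >= 0:
        raise SimulationError(
            f"trajectory diverged (|x| > 10) at step {diverged} "
            f"(t = {diverged * config.dt:.3f} weeks); reduce dt"
        )
    times = np.arange(config.n_steps + 1) * config.dt
    return Trajectory(times=times, states=states, config=config)


def label_states(traj: Trajectory, geometry: PotentialGeometry | None = None) -> np.ndarray:
    """Hysteresis labelling of a trajectory into {-1 health, 0 transit, +1 disease}.

    The label switches to health (-1) only when x first reaches
    ``geometry.x_health`` and to disease (+1) only when x first reaches
    ``geometry.x_disease``; otherwise the previous committed label persists.
    Samples before the first commitment are transit (0).
    """
    if geometry is None:
        geometry = steady_states(traj.config.params)
    x = traj.states
    raw = np.zeros(x.size, dtype=np.int8)
    raw[x <= geometry.x_health] = HEALTH
    raw[x >= geometry.x_disease] = DISEASE
    # forward-fill the last committed label
    idx = np.where(raw != 0, np.arange(x.size), -1)
    np.maximum.accumulate(idx, out=idx)
    labels = np.where(idx >= 0, raw[np.maximum(idx, 0)], TRANSIT)
    return labels.astype(np.int8)


def residence_times(labels: np.ndarray, dt: float) -> ResidenceSummary:
    """Durations of maximal constant-label runs, in weeks.

    The leading transit segment is discarded; the first committed run starts
    at a known time (t = 0 or the first commitment) and is counted; the
    trailing run is right-censored and excluded.  Returns an empty summary
    when no complete residence exists.
    """
    committed_from = int(np.argmax(labels != TRANSIT))
    if labels[committed_from] == TRANSIT:  # never committed
        return ResidenceSummary()
    lab = labels[committed_from:]
    changes = np.flatnonzero(np.diff(lab)) + 1
    bounds = np.concatenate(([0], changes, [lab.size]))
    lengths = np.diff(bounds)
    states = lab[bounds[:-1]]
    if lengths.size <= 1:  # single (censored) run
        return ResidenceSummary()
    lengths, states = lengths[:-1], states[:-1]  # drop trailing censored run
    health = [float(n * dt) for n, s in zip(lengths, states) if s == HEALTH]
    disease = [float(n * dt) for n, s in zip(lengths, states) if s == DISEASE]
    return ResidenceSummary(
        health_durations=health,
        disease_durations=disease,
        mean_health=float(np.mean(health)) if health else math.nan,
        mean_disease=float(np.mean(disease)) if disease else math.nan,
        n_transitions=len(health) + len(disease),
    )


def sample_exit_times(
    params: PotentialParams,
    epsilon: float,
    n_exits: int,
    seed: int = 0,
    dt: float = 0.01,
    from_state: str = "health",
    max_steps: int = 2_000_000_000,
) -> np.ndarray:
    """First-passage (exit) times from one well by renewal sampling.

    A walker starts at the bottom of the chosen well and is integrated until
    it commits to the opposite minimum; the elapsed time is recorded and the
    walker is reset, until ``n_exits`` independent exit times have been
    collected.  This matches the hysteresis definition of a residence used
    by :func:`label_states`.
    """
    if epsilon <= 0:
        raise ValueError("exit-time sampling requires epsilon > 0")
    geo = steady_states(params)
    if from_state == "health":
        start, target, direction = geo.x_health, geo.x_disease, 1.0
    elif from_state == "disease":
        start, target, direction = geo.x_disease, geo.x_health, -1.0
    else:
        raise ValueError(f"from_state must be 'health' or 'disease', got {from_state!r}")
    rng = np.random.default_rng(seed)
    scale = math.sqrt(epsilon * dt)
    times = np.empty(n_exits)
    x, t, count, steps = start, 0.0, 0, 0
    while count < n_exits:
        if steps >= max_steps:
            raise SimulationError(
                f"exit-time sampling exceeded {max_steps} steps with only "
                f"{count}/{n_exits} exits (epsilon={epsilon})"
            )
        noise = scale * rng.standard_normal(_CHUNK)
        x, t, count = first_passage_chunk(
            x, t, params.alpha, params.beta, dt, noise, target, direction, start,
            times, count,
        )
        steps += _CHUNK
    return times


@dataclass(frozen=True)
class KramersSlopeFit:
    """Regression of ln(mean exit time) on 1/epsilon against the 2*dV law."""

    slope: float
    intercept: float
    expected_slope: float
    epsilons: tuple
    mean_exit_times: tuple
    n_exits: int

    @property
    def relative_error(self) -> float:
        return abs(self.slope - self.expected_slope) / self.expected_slope


def kramers_slope_check(
    alpha: float,
    beta: float,
    epsilon_grid,
    reps: int = 200,
    seed: int = 0,
    dt: float = 0.01,
) -> KramersSlopeFit:
    """Monte-Carlo check of the exit-time exponent against exp(2*dV/epsilon).

    For each noise level the mean simulated exit time from the health well is
    estimated from ``reps`` renewal first passages, and ln(mean) is regressed
    on 1/epsilon.  Because the closed form omits the Kramers curvature
    prefactor, the *intercept* is not expected to vanish; the contract is on
    the slope, which should match 2*dv_health.
    """
    eps = np.asarray(list(epsilon_grid), dtype=float)
    if eps.size < 4:
        raise ValueError("epsilon_grid must contain at least 4 noise levels")
    if reps < 10:
        raise ValueError("need at least 10 exits per epsilon")
    geo = steady_states(PotentialParams(alpha, beta))
    params = PotentialParams(alpha, beta)
    ss = np.random.SeedSequence(seed)
    means = []
    for child, e in zip(ss.spawn(eps.size), eps):
        exits = sample_exit_times(
            params, float(e), reps, seed=child, dt=dt, from_state="health"
        )
        means.append(float(np.mean(exits)))
    slope, intercept = np.polyfit(1.0 / eps, np.log(means), 1)
    return KramersSlopeFit(
        slope=float(slope),
        intercept=float(intercept),
        expected_slope=2.0 * geo.dv_health,
        epsilons=tuple(float(e) for e in eps),
        mean_exit_times=tuple(means),
        n_exits=reps,
    )


def write_trajectory_csv(traj: Trajectory, path, labels: np.ndarray | None = None) -> None:
    """Tidy CSV export (time_weeks, x, label) with a JSON config sidecar."""
    if labels is None:
        labels = label_states(traj)
    path = Path(path)
    pd.DataFrame(
        {"time_weeks": traj.times, "x": traj.states, "label": labels}
    ).to_csv(path, index=False)
    cfg = asdict(traj.config)
    cfg["params"] = asdict(traj.config.params)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(cfg, indent=2))
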