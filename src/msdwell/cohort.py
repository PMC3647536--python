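"""Synthetic relapsing-remitting cohorts with the assumed statistical structure.

The reference clinical dataset (70 therapy-naive patients observed weekly,
spans 40-1311 weeks, mean relapse duration ~4.3 weeks, mean remission ~100
weeks) is not publicly deposited, so this module generates cohorts with the
same statistical structure:

* each course starts with a relapse and alternates states;
* episode durations are exponential with the state mean, then rounded up to
  an integer week (minimum one week), which adds a positive discretisation
  bias of roughly half a week to the realised means;
* per-patient heterogeneity enters through a single log-normal severity
  multiplier (median 1) applied to both state means, spanning the spread of
  per-patient remission means seen clinically;
* observation spans follow a truncated exponential on [40, 1311] weeks,
  calibrated so that ~36% of spans fall at or below 200 weeks.

Courses can also be generated from the mechanistic model itself
(:func:`generate_from_model`) for end-to-end closed-loop tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .potential import PotentialParams, steady_states
from .records import PatientCourse
from .simulate import HEALTH, SimulationConfig, label_states, simulate

__all__ = ["CohortConfig", "generate_patient", "generate_cohort", "generate_from_model"]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generating parameters (defaults mirror the clinical set)."""

    n_patients: int = 70
    mean_relapse_weeks: float = 4.3
    mean_remission_weeks: float = 100.0
    span_min_weeks: int = 40
    span_max_weeks: int = 1311
    heterogeneity_cv: float = 0.5
    seed: int = 0
    #: calibration anchor of the span law: fraction of spans <= anchor week
    span_anchor_weeks: float = 200.0
    span_anchor_fraction: float = 0.36

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_relapse_weeks <= 0 or self.mean_remission_weeks <= 0:
            raise ValueError("state means must be positive")
        if not (2 <= self.span_min_weeks <= self.span_max_weeks):
            raise ValueError("need 2 <= span_min_weeks <= span_max_weeks")
        if self.heterogeneity_cv < 0:
            raise ValueError("heterogeneity_cv must be non-negative")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_patient(
    mean_relapse: float,
    mean_remission: float,
    span_weeks: int,
    seed,
    patient_id: str = "P000",
) -> PatientCourse:
    """One synthetic course: alternating ceil-exponential episodes from relapse onset.

    Durations are drawn Exp(state mean) and rounded up to whole weeks
    (minimum 1); the series is truncated at ``span_weeks``, leaving a
    right-censored final episode, as in the clinical encoding.
    """
    if mean_relapse <= 0 or mean_remission <= 0:
        raise ValueError("state means must be positive")
    if span_weeks < 2:
        raise ValueError("span_weeks must be >= 2")
    rng = _as_rng(seed)
    series = np.empty(int(span_weeks), dtype=np.int8)
    pos, state = 0, 1
    while pos < span_weeks:
        mean = mean_relapse if state == 1 else mean_remission
        dur = max(1, math.ceil(rng.exponential(mean)))
        dur = min(dur, int(span_weeks) - pos)
        series[pos : pos + dur] = state
        pos += dur
        state = -state
    return PatientCourse(patient_id=patient_id, series=series)


def _span_scale(config: CohortConfig) -> float:
    """Scale of the truncated-exponential span law from the anchor quantile."""
    lo, hi = float(config.span_min_weeks), float(config.span_max_weeks)
    a, q = config.span_anchor_weeks, config.span_anchor_fraction
    if not (lo < a < hi):
        return (hi - lo) / 3.0  # anchor not usable; fall back to a generic shape

    def mismatch(scale: float) -> float:
        cdf = -math.expm1(-(a - lo) / scale)
        norm = -math.expm1(-(hi - lo) / scale)
        return cdf / norm - q

    return float(brentq(mismatch, 1e-3, 1e6))


def _sample_spans(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = float(config.span_min_weeks), float(config.span_max_weeks)
    if lo == hi:
        return np.full(config.n_patients, int(lo))
    scale = _span_scale(config)
    u = rng.uniform(size=config.n_patients)
    norm = -math.expm1(-(hi - lo) / scale)
    spans = lo - scale * np.log1p(-u * norm)
    return np.clip(np.ceil(spans), config.span_min_weeks, config.span_max_weeks).astype(int)


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[PatientCourse]:
    """A full synthetic cohort, deterministic under ``config.seed``.

    Per-patient state means are the cohort means scaled by one log-normal
    severity multiplier (median 1, coefficient of variation
    ``heterogeneity_cv``) shared by both states; each patient course is drawn
    from an independent substream of the master seed.
    """
    ss = np.random.SeedSequence(config.seed)
    cohort_stream, *patient_streams = ss.spawn(config.n_patients + 1)
    rng = np.random.default_rng(cohort_stream)
    sigma = math.sqrt(math.log1p(config.heterogeneity_cv**2))
    multipliers = np.exp(sigma * rng.standard_normal(config.n_patients))
    spans = _sample_spans(config, rng)
    width = len(str(config.n_patients))
    return [
        generate_patient(
            mean_relapse=config.mean_relapse_weeks * m,
            mean_remission=config.mean_remission_weeks * m,
            span_weeks=int(span),
            seed=np.random.default_rng(stream),
            patient_id=f"P{i + 1:0{width}d}",
        )
        for i, (m, span, stream) in enumerate(zip(multipliers, spans, patient_streams))
    ]


def generate_from_model(
    params: PotentialParams,
    epsilon: float,
    span_weeks: int,
    seed: int = 0,
    dt: float = 0.01,
    patient_id: str = "model",
) -> PatientCourse:
    """A weekly +/-1 course produced by the stochastic model itself.

    The Langevin trajectory is integrated over ``span_weeks`` weeks, labelled
    with the hysteresis rule, and downsampled to one label per week (the
    committed state at week end).  Weeks before the first commitment are
    dropped, and the series is trimmed to the first relapse week so that the
    clinical onset convention holds; if no relapse ever occurs the all-health
    course is returned with ``start_convention=False``.
    """
    geometry = steady_states(params)
    n_steps = int(round(span_weeks / dt))
    traj = simulate(
        SimulationConfig(
            params=params,
            epsilon=epsilon,
            n_steps=n_steps,
            dt=dt,
            x_init=geometry.x_health,
            seed=seed,
        )
    )
    labels = label_states(traj, geometry)
    steps_per_week = int(round(1.0 / dt))
    weekly = labels[steps_per_week::steps_per_week]  # committed state at week end
    weekly = weekly[weekly != 0]
    if weekly.size == 0:
        raise ValueError("trajectory never committed to a state; increase span_weeks")
    onsets = np.flatnonzero(weekly == 1)
    if onsets.size == 0:
        return PatientCourse(
            patient_id=patient_id,
            series=np.full(weekly.size, HEALTH, dtype=np.int8),
            start_convention=False,
        )
    return PatientCourse(patient_id=patient_id, series=weekly[onsets[0] :])
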