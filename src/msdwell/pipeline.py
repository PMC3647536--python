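"""Per-patient and cohort inference: durations -> barriers -> potential shape.

For each patient the chain is

1. mean complete-episode durations tau_health (remission) and tau_disease
   (relapse), in weeks;
2. barrier ratio dV_health/dV_disease = ln(tau_health)/ln(tau_disease);
3. the asymmetry parameter beta solved (at alpha fixed to 1, which only
   rescales the wells) so the double-well reproduces that ratio;
4. the noise variance epsilon from the health-side exit-time relation
   epsilon = 2*dV_health/ln(tau_health); the disease side gives the same
   value by construction of the beta fit, which is asserted, not assumed.

Patients whose mean durations make the log-ratio estimator undefined (a mean
at or below one week, or remissions shorter than relapses) are returned with
flags rather than raising, so cohort analyses degrade gracefully.

Cohort-level estimates pool complete episodes across patients first and then
form means and the ratio (not a mean of per-patient ratios).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import records
from .potential import (
    PotentialParams,
    barrier_ratio_from_durations,
    noise_from_exit_time,
    solve_beta,
    steady_states,
)

__all__ = [
    "PatientInference",
    "CohortReport",
    "analyze_patient",
    "analyze_cohort",
    "reconstruct_potential",
    "save_report",
]

FLAG_NO_HEALTH = "no-complete-remission"
FLAG_NO_DISEASE = "no-complete-relapse"
FLAG_UNDEFINED = "estimator-undefined"
FLAG_INVERTED = "inverted-asymmetry"


@dataclass(frozen=True)
class PatientInference:
    """Estimated double-well parameters for one patient.

    ``tau_health_weeks``/``tau_disease_weeks`` are the mean complete
    remission/relapse durations.  Fields downstream of a failed estimator
    are NaN and the reason is recorded in ``flags``.
    """

    patient_id: str
    tau_health_weeks: float
    tau_disease_weeks: float
    n_health: int
    n_disease: int
    alpha: float = 1.0
    barrier_ratio: float = math.nan
    beta_hat: float = math.nan
    dv_health_hat: float = math.nan
    dv_disease_hat: float = math.nan
    epsilon_hat: float = math.nan
    flags: tuple = ()


def _infer_from_means(
    patient_id: str,
    tau_health: float,
    tau_disease: float,
    n_health: int,
    n_disease: int,
    alpha: float,
) -> PatientInference:
    flags = []
    if n_health == 0:
        flags.append(FLAG_NO_HEALTH)
    if n_disease == 0:
        flags.append(FLAG_NO_DISEASE)
    if not flags and (tau_health <= 1.0 or tau_disease <= 1.0):
        flags.append(FLAG_UNDEFINED)
    base = dict(
        patient_id=patient_id,
        tau_health_weeks=tau_health,
        tau_disease_weeks=tau_disease,
        n_health=n_health,
        n_disease=n_disease,
        alpha=alpha,
    )
    if flags:
        return PatientInference(**base, flags=tuple(flags))
    ratio = barrier_ratio_from_durations(tau_health, tau_disease)
    if ratio < 1.0:
        return PatientInference(**base, barrier_ratio=ratio, flags=(FLAG_INVERTED,))
    beta = solve_beta(ratio, alpha)
    geo = steady_states(PotentialParams(alpha, beta))
    eps_health = noise_from_exit_time(geo.dv_health, tau_health)
    eps_disease = noise_from_exit_time(geo.dv_disease, tau_disease)
    assert math.isclose(eps_health, eps_disease, rel_tol=1e-9), (
        "health- and disease-side noise estimates must agree by construction"
    )
    return PatientInference(
        **base,
        barrier_ratio=ratio,
        beta_hat=beta,
        dv_health_hat=geo.dv_health,
        dv_disease_hat=geo.dv_disease,
        epsilon_hat=eps_health,
    )


def analyze_patient(
    course: records.PatientCourse,
    alpha: float = 1.0,
    include_censored: bool = False,
) -> PatientInference:
    """Run the full inference chain on one patient course."""
    summary = records.duration_summary(course, include_censored=include_censored)
    return _infer_from_means(
        patient_id=course.patient_id,
        tau_health=summary.mean_remission_weeks,
        tau_disease=summary.mean_relapse_weeks,
        n_health=summary.n_remissions,
        n_disease=summary.n_relapses,
        alpha=alpha,
    )


@dataclass(frozen=True)
class CohortReport:
    """Per-patient inferences plus pooled-episode cohort estimates."""

    patients: list
    pooled: PatientInference
    n_patients: int
    histograms: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _plain(asdict(self))


def _plain(obj):
    """Recursively convert numpy scalars/arrays for JSON serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    return obj


def analyze_cohort(
    cohort: Sequence[records.PatientCourse],
    alpha: float = 1.0,
    include_censored: bool = False,
    relapse_bin_weeks: float = 2.0,
    remission_bin_weeks: float = 20.0,
    span_bin_weeks: float = 100.0,
    provenance: dict | None = None,
) -> CohortReport:
    """Per-patient inference plus pooled statistics and histogram tables.

    Pooling concatenates the complete episodes of all patients and computes
    means and the barrier ratio on the pooled lists, matching the convention
    of averaging durations over the whole cohort before forming the ratio.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    patients = [analyze_patient(c, alpha=alpha, include_censored=include_censored) for c in cohort]
    pooled_relapses: list = []
    pooled_remissions: list = []
    for course in cohort:
        s = records.duration_summary(course, include_censored=include_censored)
        pooled_relapses.extend(s.relapse_durations)
        pooled_remissions.extend(s.remission_durations)
    pooled = _infer_from_means(
        patient_id="POOLED",
        tau_health=float(np.mean(pooled_remissions)) if pooled_remissions else math.nan,
        tau_disease=float(np.mean(pooled_relapses)) if pooled_relapses else math.nan,
        n_health=len(pooled_remissions),
        n_disease=len(pooled_relapses),
        alpha=alpha,
    )
    histograms = {}
    for name, (counts, edges) in {
        "relapse_durations": records.pooled_histogram(cohort, "relapse", relapse_bin_weeks),
        "remission_durations": records.pooled_histogram(cohort, "remission", remission_bin_weeks),
        "observation_spans": records.span_histogram(cohort, span_bin_weeks),
    }.items():
        histograms[name] = {"counts": counts.tolist(), "edges": edges.tolist()}
    return CohortReport(
        patients=patients,
        pooled=pooled,
        n_patients=len(cohort),
        histograms=histograms,
        provenance=provenance or {},
    )


def reconstruct_potential(
    inference: PatientInference | float,
    x_grid: np.ndarray | None = None,
    alpha: float | None = None,
):
    """Tabulate the fitted potential V(x) on a grid, with annotated extrema.

    Accepts a :class:`PatientInference` (using its ``beta_hat`` and
    ``alpha``) or a plain beta value.  Returns ``(table, geometry)`` where
    ``table`` is a DataFrame with columns ``x`` and ``V``.
    """
    from .potential import potential  # local import to keep module surface tidy

    if isinstance(inference, PatientInference):
        beta, a = inference.beta_hat, inference.alpha
    else:
        beta, a = float(inference), 1.0
    if alpha is not None:
        a = alpha
    if not math.isfinite(beta):
        raise ValueError("beta is undefined for this inference (see its flags)")
    params = PotentialParams(a, beta)
    geometry = steady_states(params)
    if x_grid is None:
        x_grid = np.linspace(-2.0, 2.0, 401)
    x_grid = np.asarray(x_grid, dtype=float)
    table = pd.DataFrame({"x": x_grid, "V": potential(x_grid, params)})
    return table, geometry


def save_report(report: CohortReport, path) -> None:
    """Serialize a cohort report to JSON."""
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))
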