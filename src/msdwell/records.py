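"""Patient relapse/remission course records: data model, I/O and statistics.

A patient's relapsing-remitting course is encoded as a weekly series of +1
(relapse, *no health*) and -1 (remission, *health*) values.  The observation
window conventionally starts at the onset of the first relapse, so the first
value is +1; episode durations are integer weeks (exacerbations shorter than
a week are rounded up to one week).  Weeks are 0-based and an episode
occupies the half-open interval [start, start + duration).

The final episode of a course is truncated by the end of the observation
window (right-censored) and is excluded from mean-duration statistics by
default; a flag restores it for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RELAPSE",
    "REMISSION",
    "PatientCourse",
    "Episode",
    "DurationSummary",
    "ExponentialFit",
    "episodes_from_series",
    "series_from_episodes",
    "duration_summary",
    "fit_exponential",
    "pooled_histogram",
    "span_histogram",
    "read_cohort_csv",
    "write_cohort_csv",
]

RELAPSE = 1
REMISSION = -1
_STATE_NAME = {RELAPSE: "relapse", REMISSION: "remission"}
_STATE_CODE = {v: k for k, v in _STATE_NAME.items()}


class Episode(NamedTuple):
    """One maximal run of a single state."""

    state: str  # 'relapse' | 'remission'
    start_week: int
    duration_weeks: int


@dataclass(frozen=True)
class PatientCourse:
    """Weekly +/-1 health-state series for one patient.

    ``start_convention=True`` (the clinical default) asserts that week 0 is
    the onset of the first relapse, i.e. the series starts at +1.  Courses
    produced directly from model trajectories may begin in remission; they
    carry ``start_convention=False``.
    """

    patient_id: str
    series: np.ndarray
    start_convention: bool = True

    def __post_init__(self) -> None:
        series = np.asarray(self.series, dtype=np.int8)
        object.__setattr__(self, "series", series)
        if series.ndim != 1 or series.size == 0:
            raise ValueError(f"{self.patient_id}: series must be a non-empty 1-d vector")
        if not np.isin(series, (RELAPSE, REMISSION)).all():
            bad = np.unique(series[~np.isin(series, (RELAPSE, REMISSION))])
            raise ValueError(f"{self.patient_id}: series values must be +/-1, found {bad}")
        if self.start_convention and series[0] != RELAPSE:
            raise ValueError(
                f"{self.patient_id}: series must start with a relapse (+1) under the "
                "onset convention"
            )

    @property
    def span_weeks(self) -> int:
        return int(self.series.size)


@dataclass(frozen=True)
class DurationSummary:
    """Per-state episode durations for one patient, censoring-aware."""

    patient_id: str
    relapse_durations: List[int]
    remission_durations: List[int]
    mean_relapse_weeks: float
    mean_remission_weeks: float
    n_relapses: int
    n_remissions: int
    span_weeks: int
    censored_episode: Episode | None = None


@dataclass(frozen=True)
class ExponentialFit:
    """Maximum-likelihood exponential fit with a KS goodness-of-fit p-value.

    The MLE of the exponential mean is the sample mean.  The one-sample
    Kolmogorov-Smirnov test is run against Exp(fitted mean); note that (a)
    estimating the mean from the same data makes the test conservative in
    level, and (b) week discretisation of intrinsically continuous durations
    inflates the KS statistic, so small p-values on strongly discretised
    samples should be read with care.
    """

    mean: float
    n: int
    gof_pvalue: float


def episodes_from_series(course: PatientCourse) -> List[Episode]:
    """Run-length encode the weekly series into contiguous alternating episodes."""
    s = course.series
    changes = np.flatnonzero(np.diff(s)) + 1
    bounds = np.concatenate(([0], changes, [s.size]))
    return [
        Episode(_STATE_NAME[int(s[b])], int(b), int(e - b))
        for b, e in zip(bounds[:-1], bounds[1:])
    ]


def _validate_episodes(episodes: Sequence[Episode]) -> None:
    if not episodes:
        raise ValueError("episode list is empty")
    pos = episodes[0].start_week
    if pos != 0:
        raise ValueError(f"first episode must start at week 0, got {pos}")
    prev_state = None
    for ep in episodes:
        if ep.state not in _STATE_CODE:
            raise ValueError(f"unknown state {ep.state!r}")
        if ep.duration_weeks < 1:
            raise ValueError(f"episode durations must be >= 1 week, got {ep.duration_weeks}")
        if ep.start_week != pos:
            raise ValueError(
                f"episodes not contiguous: expected start {pos}, got {ep.start_week}"
            )
        if ep.state == prev_state:
            raise ValueError(f"episodes must alternate states, got consecutive {ep.state}")
        pos = ep.start_week + ep.duration_weeks
        prev_state = ep.state


def series_from_episodes(
    episodes: Sequence[Episode], patient_id: str = "patient"
) -> PatientCourse:
    """Inverse of :func:`episodes_from_series` (exact round trip)."""
    _validate_episodes(episodes)
    total = sum(ep.duration_weeks for ep in episodes)
    series = np.empty(total, dtype=np.int8)
    for ep in episodes:
        series[ep.start_week : ep.start_week + ep.duration_weeks] = _STATE_CODE[ep.state]
    return PatientCourse(
        patient_id=patient_id,
        series=series,
        start_convention=episodes[0].state == "relapse",
    )


def duration_summary(course: PatientCourse, include_censored: bool = False) -> DurationSummary:
    """Per-state episode durations and means for one course.

    The final episode is right-censored by the observation window and is
    excluded from the duration lists and means unless ``include_censored``.
    """
    episodes = episodes_from_series(course)
    censored = None if include_censored else episodes[-1]
    complete = episodes if include_censored else episodes[:-1]
    relapses = [ep.duration_weeks for ep in complete if ep.state == "relapse"]
    remissions = [ep.duration_weeks for ep in complete if ep.state == "remission"]
    return DurationSummary(
        patient_id=course.patient_id,
        relapse_durations=relapses,
        remission_durations=remissions,
        mean_relapse_weeks=float(np.mean(relapses)) if relapses else math.nan,
        mean_remission_weeks=float(np.mean(remissions)) if remissions else math.nan,
        n_relapses=len(relapses),
        n_remissions=len(remissions),
        span_weeks=course.span_weeks,
        censored_episode=censored,
    )


def fit_exponential(durations: Sequence[float]) -> ExponentialFit:
    """MLE exponential fit plus a KS test against the fitted distribution."""
    durations = np.asarray(durations, dtype=float)
    if durations.size < 5:
        raise ValueError(f"need at least 5 durations to fit, got {durations.size}")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    mean = float(durations.mean())
    ks = stats.kstest(durations, "expon", args=(0.0, mean))
    return ExponentialFit(mean=mean, n=int(durations.size), gof_pvalue=float(ks.pvalue))


def _histogram(values: Sequence[float], bin_width: float):
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.array([], dtype=int), np.array([])
    lo = 1.0  # durations are >= 1 week
    n_bins = int(np.ceil((values.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


def pooled_histogram(
    cohort: Iterable[PatientCourse],
    state: str = "relapse",
    bin_width_weeks: float = 1.0,
    include_censored: bool = False,
):
    """Histogram of episode durations of one state pooled over patients.

    Returns ``(counts, edges)`` with bins ``[1, 1+w), [1+w, 1+2w), ...``.
    """
    if bin_width_weeks < 1:
        raise ValueError("bin width must be at least 1 week")
    if state not in _STATE_CODE:
        raise ValueError(f"state must be 'relapse' or 'remission', got {state!r}")
    durations: list = []
    for course in cohort:
        summary = duration_summary(course, include_censored=include_censored)
        durations.extend(
            summary.relapse_durations if state == "relapse" else summary.remission_durations
        )
    return _histogram(durations, bin_width_weeks)


def span_histogram(cohort: Iterable[PatientCourse], bin_width_weeks: float = 100.0):
    """Histogram of per-patient observation spans (length of the RR phase)."""
    spans = [c.span_weeks for c in cohort]
    return _histogram(spans, bin_width_weeks)


_CSV_COLUMNS = ["patient_id", "state", "start_week", "duration_weeks"]


def write_cohort_csv(cohort: Sequence[PatientCourse], path) -> None:
    """Write a cohort in long episode format (one row per episode)."""
    rows = []
    for course in cohort:
        for ep in episodes_from_series(course):
            rows.append(
                {
                    "patient_id": course.patient_id,
                    "state": _STATE_CODE[ep.state],
                    "start_week": ep.start_week,
                    "duration_weeks": ep.duration_weeks,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path) -> List[PatientCourse]:
    """Read a long-format cohort CSV back into PatientCourse objects.

    Episodes of each patient must be contiguous rows, ordered by start week;
    a patient id appearing in two separate blocks is reported as a duplicate.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty cohort file") from None
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if frame.empty:
        raise ValueError(f"{path}: no episode rows")
    bad = ~frame["state"].isin((RELAPSE, REMISSION))
    if bad.any():
        line = int(frame.index[bad][0]) + 2  # header + 1-based
        raise ValueError(
            f"{path}:{line}: unknown state code {frame.loc[bad, 'state'].iloc[0]!r} "
            "(expected +1 or -1)"
        )
    block_ids = frame["patient_id"].loc[frame["patient_id"].shift() != frame["patient_id"]]
    dup = block_ids[block_ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate patient_id {dup.iloc[0]!r}")
    cohort = []
    for pid, group in frame.groupby("patient_id", sort=False):
        group = group.sort_values("start_week")
        episodes = [
            Episode(_STATE_NAME[int(r.state)], int(r.start_week), int(r.duration_weeks))
            for r in group.itertuples()
        ]
        try:
            cohort.append(series_from_episodes(episodes, patient_id=str(pid)))
        except ValueError as exc:
            line = int(group.index[0]) + 2
            raise ValueError(f"{path}:{line}: patient {pid!r}: {exc}") from None
    return cohort
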