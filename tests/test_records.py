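"""Course records: run-length encoding, censoring, fits, histograms, CSV I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msdwell import (
    CohortConfig,
    Episode,
    PatientCourse,
    duration_summary,
    episodes_from_series,
    fit_exponential,
    generate_cohort,
    pooled_histogram,
    read_cohort_csv,
    series_from_episodes,
    span_histogram,
    write_cohort_csv,
)

# weekly +/-1 series obeying the onset convention (first week is a relapse)
valid_series = st.lists(st.sampled_from([1, -1]), min_size=1, max_size=120).map(
    lambda tail: np.array([1] + tail, dtype=np.int8)
)


def test_run_length_encoding_example():
    course = PatientCourse("p", np.array([1, 1, -1, -1, -1, 1]))
    assert episodes_from_series(course) == [
        Episode("relapse", 0, 2),
        Episode("remission", 2, 3),
        Episode("relapse", 5, 1),
    ]


def test_single_state_series_is_one_episode():
    course = PatientCourse("p", np.ones(7, dtype=np.int8))
    assert episodes_from_series(course) == [Episode("relapse", 0, 7)]


@settings(max_examples=200, derandomize=True)
@given(series=valid_series)
def test_series_episode_round_trip(series):
    course = PatientCourse("p", series)
    back = series_from_episodes(episodes_from_series(course), patient_id="p")
    assert np.array_equal(back.series, course.series)
    episodes = episodes_from_series(course)
    assert sum(ep.duration_weeks for ep in episodes) == course.span_weeks


def test_invalid_episode_lists_are_rejected():
    with pytest.raises(ValueError, match="empty"):
        series_from_episodes([])
    with pytest.raises(ValueError, match="contiguous"):
        series_from_episodes([Episode("relapse", 0, 2), Episode("remission", 3, 1)])
    with pytest.raises(ValueError, match="alternate"):
        series_from_episodes([Episode("relapse", 0, 2), Episode("relapse", 2, 1)])
    with pytest.raises(ValueError, match="unknown state"):
        series_from_episodes([Episode("flare", 0, 2)])


def test_course_validation():
    with pytest.raises(ValueError, match="non-empty"):
        PatientCourse("p", np.array([]))
    with pytest.raises(ValueError, match=r"\+/-1"):
        PatientCourse("p", np.array([1, 0, -1]))
    with pytest.raises(ValueError, match="relapse"):
        PatientCourse("p", np.array([-1, 1]))
    # model-generated courses may start in remission when flagged
    PatientCourse("p", np.array([-1, -1]), start_convention=False)


def test_duration_summary_censors_trailing_episode():
    course = PatientCourse("p", np.array([1, 1, -1, -1, -1, 1]))
    s = duration_summary(course)
    assert s.relapse_durations == [2] and s.remission_durations == [3]
    assert s.mean_relapse_weeks == 2.0 and s.mean_remission_weeks == 3.0
    assert s.censored_episode == Episode("relapse", 5, 1)
    s_all = duration_summary(course, include_censored=True)
    assert s_all.mean_relapse_weeks == pytest.approx(1.5)
    assert s_all.censored_episode is None


def test_single_episode_course_has_no_complete_durations():
    s = duration_summary(PatientCourse("p", np.ones(9, dtype=np.int8)))
    assert s.n_relapses == 0 and s.n_remissions == 0
    assert np.isnan(s.mean_relapse_weeks)
    assert s.censored_episode == Episode("relapse", 0, 9)


def test_exponential_fit_recovers_simulated_means():
    rng = np.random.default_rng(42)
    small = rng.exponential(4.3, size=500)
    fit = fit_exponential(small)
    assert fit.mean == pytest.approx(4.3, rel=0.10)
    assert fit.gof_pvalue > 0.01
    large = rng.exponential(100.0, size=300)
    assert fit_exponential(large).mean == pytest.approx(100.0, rel=0.15)


def test_exponential_fit_rejects_degenerate_samples():
    fit = fit_exponential([5.0] * 100)
    assert fit.gof_pvalue < 1e-6
    with pytest.raises(ValueError, match="at least 5"):
        fit_exponential([1.0, 2.0])


def test_pooled_histogram_hand_binning():
    course = series_from_episodes(
        [
            Episode("relapse", 0, 1),
            Episode("remission", 1, 1),
            Episode("relapse", 2, 1),
            Episode("remission", 3, 1),
            Episode("relapse", 4, 2),
            Episode("remission", 6, 1),
            Episode("relapse", 7, 5),
            Episode("remission", 12, 1),
            Episode("relapse", 13, 1),  # censored trailing episode
        ],
        patient_id="p",
    )
    # complete relapse durations: [1, 2, 5, 1] -> bins [1,3),[3,5),[5,7)
    counts, edges = pooled_histogram([course], "relapse", bin_width_weeks=2)
    assert counts.tolist() == [3, 0, 1]
    assert edges.tolist() == [1.0, 3.0, 5.0, 7.0]


def test_empty_cohort_histogram_is_empty():
    counts, edges = pooled_histogram([], "relapse", 2)
    assert counts.size == 0 and edges.size == 0
    counts, edges = span_histogram([], 100)
    assert counts.size == 0


def test_pooled_duration_histograms_decay_like_exponentials():
    """First bins of the pooled relapse histogram are non-increasing in >=90% of replicates."""
    good = 0
    for seed in range(20):
        cohort = generate_cohort(CohortConfig(seed=seed))
        counts, _ = pooled_histogram(cohort, "relapse", bin_width_weeks=4)
        if len(counts) >= 3 and counts[0] >= counts[1] >= counts[2]:
            good += 1
    assert good >= 18


def test_cohort_csv_round_trip(tmp_path):
    cohort = generate_cohort(CohortConfig(n_patients=12, seed=5))
    path = tmp_path / "cohort.csv"
    write_cohort_csv(cohort, path)
    back = read_cohort_csv(path)
    assert [c.patient_id for c in back] == [c.patient_id for c in cohort]
    for a, b in zip(cohort, back):
        assert np.array_equal(a.series, b.series)
        assert a.start_convention == b.start_convention


def test_cohort_csv_errors(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(ValueError, match="empty"):
        read_cohort_csv(empty)

    bad_state = tmp_path / "bad.csv"
    bad_state.write_text(
        "patient_id,state,start_week,duration_weeks\np1,1,0,2\np1,2,2,3\n"
    )
    with pytest.raises(ValueError, match="unknown state"):
        read_cohort_csv(bad_state)

    dup = tmp_path / "dup.csv"
    dup.write_text(
        "patient_id,state,start_week,duration_weeks\n"
        "p1,1,0,2\np2,1,0,3\np1,1,0,2\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_cohort_csv(dup)

    gap = tmp_path / "gap.csv"
    gap.write_text(
        "patient_id,state,start_week,duration_weeks\np1,1,0,2\np1,-1,5,3\n"
    )
    with pytest.raises(ValueError, match="contiguous"):
        read_cohort_csv(gap)
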