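"""Closed-form double-well mathematics: geometry, barriers and inversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msdwell import (
    BifurcationError,
    ExitTimeEstimate,
    PotentialParams,
    barrier_ratio,
    barrier_ratio_from_durations,
    drift,
    kramers_mean_exit_time,
    noise_from_exit_time,
    potential,
    solve_beta,
    steady_states,
)

# strategy over the bistable parameter region (stay clear of the saddle-node
# boundary so barrier differences remain well-conditioned)
bistable_params = st.builds(
    lambda alpha, frac: PotentialParams(alpha, frac * math.sqrt(4.0 / (27.0 * alpha))),
    alpha=st.floats(0.2, 5.0),
    frac=st.floats(0.0, 0.95),
)


@pytest.mark.parametrize(
    "x, alpha, beta, expected",
    [(0.0, 1.0, 0.0, 0.0), (1.0, 1.0, 0.0, -0.25), (-1.0, 1.0, 0.08, -0.33)],
)
def test_potential_closed_form_values(x, alpha, beta, expected):
    assert potential(x, PotentialParams(alpha, beta)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "x, alpha, beta, expected",
    [(1.0, 1.0, 0.0, 0.0), (0.0, 1.0, 0.08, -0.08), (0.5, 1.0, 0.0, 0.375)],
)
def test_drift_closed_form_values(x, alpha, beta, expected):
    assert drift(x, PotentialParams(alpha, beta)) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(params=bistable_params)
def test_drift_is_negative_gradient_of_potential(params):
    """Central finite differences of V must reproduce -drift on a grid."""
    x = np.linspace(-2.0, 2.0, 81)
    h = 1e-6
    grad = (potential(x + h, params) - potential(x - h, params)) / (2 * h)
    np.testing.assert_allclose(drift(x, params), -grad, rtol=1e-6, atol=1e-8)


def test_symmetric_well_is_even_with_equal_barriers(symmetric_params):
    x = np.linspace(-2.0, 2.0, 101)
    np.testing.assert_allclose(
        potential(x, symmetric_params), potential(-x, symmetric_params), atol=1e-14
    )
    geo = steady_states(symmetric_params)
    assert (geo.x_health, geo.x_saddle, geo.x_disease) == pytest.approx((-1.0, 0.0, 1.0), abs=1e-12)
    assert geo.dv_health == pytest.approx(0.25, abs=1e-13)
    assert geo.dv_disease == pytest.approx(0.25, abs=1e-13)


@settings(max_examples=50, derandomize=True)
@given(params=bistable_params)
def test_stationary_points_are_ordered_drift_zeros(params):
    geo = steady_states(params)
    assert geo.x_health < geo.x_saddle < geo.x_disease
    for root in (geo.x_health, geo.x_saddle, geo.x_disease):
        assert abs(drift(root, params)) < 1e-10
    assert geo.dv_health > 0 and geo.dv_disease > 0
    if params.beta > 1e-9:  # below this the barrier gap (~2*beta) is lost to rounding
        assert geo.dv_health > geo.dv_disease


@pytest.mark.parametrize("beta", [0.0, 0.08, 0.19, 0.3])
def test_stationary_points_match_brute_force_sign_scan(beta):
    """Roots agree with a dense sign-change scan of the drift (independent oracle)."""
    params = PotentialParams(1.0, beta)
    grid = np.linspace(-3.0, 3.0, 1_000_001)
    f = drift(grid, params)
    crossings = grid[:-1][(f[:-1] < 0) != (f[1:] < 0)]
    geo = steady_states(params)
    roots = np.array([geo.x_health, geo.x_saddle, geo.x_disease])
    assert crossings.size == 3
    np.testing.assert_allclose(np.sort(crossings), roots, atol=6.1e-6)


@pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
def test_bifurcation_boundary_is_sharp(alpha):
    """Three states just inside 27*alpha*beta^2 = 4; an error at and beyond it."""
    beta_c = math.sqrt(4.0 / (27.0 * alpha))
    steady_states(PotentialParams(alpha, 0.999 * beta_c))  # must not raise
    for beta in (beta_c, 1.2 * beta_c):
        with pytest.raises(BifurcationError):
            steady_states(PotentialParams(alpha, beta))


def test_barrier_ratio_monotone_in_beta():
    betas = np.linspace(0.0, 0.38, 39)
    ratios = [barrier_ratio(PotentialParams(1.0, b)) for b in betas]
    dv2 = [steady_states(PotentialParams(1.0, b)).dv_disease for b in betas]
    assert ratios[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(ratios) > 0)
    assert np.all(np.diff(dv2) < 0)


def test_barrier_ratio_examples():
    assert barrier_ratio(PotentialParams(1.0, 0.19)) == pytest.approx(5.3, abs=0.1)
    assert barrier_ratio(PotentialParams(1.0, 0.12)) == pytest.approx(2.7, abs=0.1)
    # the forward map at the printed beta for the most asymmetric patient gives
    # ~10.8, not that patient's log-ratio estimate of 11.8 (see docs/methods.md)
    assert barrier_ratio(PotentialParams(1.0, 0.25)) == pytest.approx(10.7746, abs=1e-3)


@pytest.mark.parametrize("beta", [0.05, 0.08, 0.12, 0.19, 0.25, 0.3])
def test_solve_beta_round_trip(beta):
    ratio = barrier_ratio(PotentialParams(1.0, beta))
    assert abs(solve_beta(ratio, 1.0) - beta) < 1e-8


def test_solve_beta_edges():
    assert solve_beta(1.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        solve_beta(0.8, 1.0)
    with pytest.raises(ValueError, match="attainable"):
        solve_beta(1e15, 1.0)


def test_duration_log_ratio_estimator():
    assert barrier_ratio_from_durations(100.0, 4.3) == pytest.approx(3.157, abs=1e-3)
    assert barrier_ratio_from_durations(117.7, 1.5) == pytest.approx(11.76, abs=0.01)
    e = math.e
    assert barrier_ratio_from_durations(e, e) == pytest.approx(1.0, abs=1e-14)
    for bad in [(1.0, 4.3), (100.0, 0.9)]:
        with pytest.raises(ValueError):
            barrier_ratio_from_durations(*bad)


def test_exit_time_algebra():
    tau = kramers_mean_exit_time(0.25, 0.13)
    assert tau == pytest.approx(math.exp(0.5 / 0.13), rel=1e-14)  # ~46.9 weeks
    assert kramers_mean_exit_time(0.5, 0.13) == pytest.approx(tau**2, rel=1e-12)
    # inversion round-trips to machine precision
    assert noise_from_exit_time(0.25, tau) == pytest.approx(0.13, rel=1e-12)
    assert noise_from_exit_time(0.5465, 117.7) == pytest.approx(
        2 * 0.5465 / math.log(117.7), rel=1e-14
    )
    with pytest.raises(ValueError):
        noise_from_exit_time(0.25, 1.0)
    with pytest.raises(ValueError):
        kramers_mean_exit_time(-0.1, 0.13)
    est = ExitTimeEstimate.from_barrier(0.25, 0.13)
    assert est.mean_exit_time == pytest.approx(math.exp(2 * est.barrier / est.noise_variance),
                                               rel=1e-12)


def test_params_validation():
    with pytest.raises(ValueError):
        PotentialParams(alpha=-1.0)
    with pytest.raises(ValueError):
        PotentialParams(alpha=1.0, beta=-0.1)
    assert PotentialParams(1.0, 0.1).is_bistable
    assert not PotentialParams(1.0, 0.5).is_bistable
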