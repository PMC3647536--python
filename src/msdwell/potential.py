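"""Closed-form mathematics of the tilted double-well health-state potential.

The health state ``x`` of a relapsing-remitting patient is modelled as an
overdamped particle in the quartic potential

    V(x) = -x**2 / 2 + alpha * x**4 / 4 + beta * x

with ``alpha > 0`` a control parameter setting the barrier height and
``beta >= 0`` an asymmetry (tilt) parameter that deepens the *health* well
(the negative-``x`` minimum, matching the clinical convention that -1 codes
remission and +1 codes relapse).  The deterministic dynamics are

    dx/dt = -V'(x) = x * (1 - alpha * x**2) - beta.

For ``27 * alpha * beta**2 < 4`` the cubic has three real stationary points
(bistable regime); at the saddle-node bifurcation boundary one well vanishes
and the two-state description of the disease course breaks down.

This module also carries the noise-driven exit-time algebra: in the
small-noise limit the mean residence time in a well of depth ``dV`` under
white noise of variance ``epsilon`` scales as ``exp(2 * dV / epsilon)``
(no prefactor), so the log-ratio of the two mean residence times estimates
the ratio of the two barriers — the quantity inverted here for ``beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BifurcationError",
    "PotentialParams",
    "PotentialGeometry",
    "ExitTimeEstimate",
    "potential",
    "drift",
    "steady_states",
    "barrier_ratio",
    "solve_beta",
    "barrier_ratio_from_durations",
    "kramers_mean_exit_time",
    "noise_from_exit_time",
]

#: 27 * alpha * beta**2 >= 4 marks the saddle-node bifurcation.
_BISTABLE_BOUND = 4.0


class BifurcationError(ValueError):
    """Raised when (alpha, beta) lie outside the bistable regime."""


@dataclass(frozen=True)
class PotentialParams:
    """Shape parameters of the double-well potential.

    Parameters
    ----------
    alpha : float
        Positive control parameter of the well height.  ``alpha = 1`` puts
        the symmetric-well minima at x = -1 and x = +1.
    beta : float
        Non-negative asymmetry parameter.  ``beta = 0`` gives a symmetric
        well; increasing ``beta`` deepens the health well and flattens the
        disease well until the saddle-node bifurcation at
        ``27 * alpha * beta**2 = 4``.
    """

    alpha: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta >= 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be non-negative and finite, got {self.beta}")

    @property
    def is_bistable(self) -> bool:
        """True when the potential has two minima separated by a saddle."""
        return 27.0 * self.alpha * self.beta**2 < _BISTABLE_BOUND

    @property
    def beta_bifurcation(self) -> float:
        """beta value of the saddle-node bifurcation for this alpha."""
        return math.sqrt(_BISTABLE_BOUND / (27.0 * self.alpha))


@dataclass(frozen=True)
class PotentialGeometry:
    """Stationary points and barrier depths of a bistable potential.

    ``x_health < x_saddle < x_disease``; ``dv_health`` is the depth of the
    health well below the saddle (V(x_saddle) - V(x_health)) and
    ``dv_disease`` the depth of the disease well.  For beta > 0 the health
    well is the deeper one.
    """

    x_health: float
    x_saddle: float
    x_disease: float
    dv_health: float
    dv_disease: float

    @property
    def ratio(self) -> float:
        """Barrier-depth ratio dv_health / dv_disease (>= 1 for beta >= 0)."""
        return self.dv_health / self.dv_disease


@dataclass(frozen=True)
class ExitTimeEstimate:
    """Mean residence time in a well, tied to its barrier and noise level.

    Consistency ``mean_exit_time = exp(2 * barrier / noise_variance)`` holds
    by construction for instances built from either closed form.
    """

    mean_exit_time: float
    barrier: float
    noise_variance: float

    @classmethod
    def from_barrier(cls, barrier: float, epsilon: float) -> "ExitTimeEstimate":
        return cls(kramers_mean_exit_time(barrier, epsilon), barrier, epsilon)

    @classmethod
    def from_exit_time(cls, barrier: float, mean_exit_time: float) -> "ExitTimeEstimate":
        return cls(mean_exit_time, barrier, noise_from_exit_time(barrier, mean_exit_time))


def potential(x, params: PotentialParams):
    """Evaluate V(x) = -x**2/2 + alpha*x**4/4 + beta*x (vectorised in x)."""
    x = np.asarray(x, dtype=float)
    v = -0.5 * x**2 + 0.25 * params.alpha * x**4 + params.beta * x
    return float(v) if v.ndim == 0 else v


def drift(x, params: PotentialParams):
    """Deterministic drift -V'(x) = x*(1 - alpha*x**2) - beta (vectorised)."""
    x = np.asarray(x, dtype=float)
    f = x * (1.0 - params.alpha * x**2) - params.beta
    return float(f) if f.ndim == 0 else f


def steady_states(params: PotentialParams) -> PotentialGeometry:
    """Solve for the three stationary points and the two barrier depths.

    The stationary points are the real roots of
    ``alpha * x**3 - x + beta = 0``, found via the companion-matrix
    eigenvalues (numpy.roots) and polished with Newton steps so that the
    drift residual at each root is below 1e-10 even close to the
    bifurcation.

    Raises
    ------
    BifurcationError
        If ``27 * alpha * beta**2 >= 4`` (monostable regime: the cubic has
        fewer than three distinct real roots and the two-state metaphor
        breaks down).
    """
    if not params.is_bistable:
        raise BifurcationError(
            f"(alpha={params.alpha}, beta={params.beta}) is outside the bistable "
            f"regime: 27*alpha*beta^2 = {27 * params.alpha * params.beta ** 2:.6g} >= 4. "
            f"For this alpha, beta must be below {params.beta_bifurcation:.6g}."
        )
    roots = np.roots([params.alpha, 0.0, -1.0, params.beta])
    roots = np.sort(np.real(roots))
    # Newton polish on f(x) = drift(x); f'(x) = 1 - 3*alpha*x^2 is nonzero at
    # each simple root inside the bistable regime.
    for _ in range(4):
        f = drift(roots, params)
        fp = 1.0 - 3.0 * params.alpha * roots**2
        roots = roots - f / fp
    resid = np.abs(drift(roots, params))
    if np.any(resid > 1e-10):
        raise ArithmeticError(f"stationary-point residuals too large: {resid}")
    x1, x0, x2 = (float(r) for r in roots)
    v0 = potential(x0, params)
    return PotentialGeometry(
        x_health=x1,
        x_saddle=x0,
        x_disease=x2,
        dv_health=v0 - potential(x1, params),
        dv_disease=v0 - potential(x2, params),
    )


def barrier_ratio(params: PotentialParams) -> float:
    """Barrier-depth ratio dv_health/dv_disease; 1 at beta = 0, increasing in beta."""
    return steady_states(params).ratio


def solve_beta(target_ratio: float, alpha: float = 1.0) -> float:
    """Invert the monotone beta -> barrier-ratio map at fixed alpha.

    Finds ``beta`` in ``[0, beta_bifurcation)`` such that the double-well
    barrier ratio equals ``target_ratio``, by bracketed root search
    (Brent).  The ratio grows without bound as beta approaches the
    saddle-node bifurcation (the disease well flattens away), so any finite
    ratio >= 1 is attainable up to floating-point resolution of the shallow
    barrier.

    Parameters
    ----------
    target_ratio : float
        Desired dv_health/dv_disease, must be >= 1.
    alpha : float
        Control parameter held fixed (the clinical inversion uses alpha = 1).
    """
    if not (target_ratio >= 1.0 and math.isfinite(target_ratio)):
        raise ValueError(f"target_ratio must be >= 1, got {target_ratio}")
    if target_ratio == 1.0:
        return 0.0
    beta_max = math.sqrt(_BISTABLE_BOUND / (27.0 * alpha))
    hi = (1.0 - 1e-6) * beta_max

    def mismatch(beta: float) -> float:
        return barrier_ratio(PotentialParams(alpha, beta)) - target_ratio

    if mismatch(hi) < 0.0:
        attainable = barrier_ratio(PotentialParams(alpha, hi))
        raise ValueError(
            f"target_ratio={target_ratio} exceeds the numerically attainable range "
            f"[1, {attainable:.6g}] before the saddle-node bifurcation at "
            f"beta={beta_max:.6g} (alpha={alpha})"
        )
    return float(brentq(mismatch, 0.0, hi, xtol=1e-13, rtol=8.9e-16))


def barrier_ratio_from_durations(tau_health: float, tau_disease: float) -> float:
    """Estimate dv_health/dv_disease as ln(tau_health)/ln(tau_disease).

    ``tau_health`` and ``tau_disease`` are the mean residence times (in
    weeks) in remission and relapse.  Both must exceed 1 week: the log-ratio
    estimator is undefined (or non-positive) at or below one week, and its
    value depends on the time unit — durations must be expressed in weeks,
    matching the clinical encoding.
    """
    if not (tau_health > 1.0 and tau_disease > 1.0):
        raise ValueError(
            "log-ratio barrier estimator requires both mean durations > 1 week; "
            f"got tau_health={tau_health}, tau_disease={tau_disease}"
        )
    return math.log(tau_health) / math.log(tau_disease)


def kramers_mean_exit_time(barrier: float, epsilon: float) -> float:
    """Small-noise mean exit time exp(2*barrier/epsilon), in weeks.

    Prefactor-free form: the curvature prefactor of the full Kramers rate is
    deliberately omitted, so absolute times are order-of-magnitude while the
    exponent (slope of ln tau versus 1/epsilon) is quantitative.
    """
    if not (barrier > 0 and epsilon > 0):
        raise ValueError(f"barrier and epsilon must be positive, got {barrier}, {epsilon}")
    return math.exp(2.0 * barrier / epsilon)


def noise_from_exit_time(barrier: float, mean_exit_time: float) -> float:
    """Invert the exit-time formula for the noise variance epsilon.

    ``epsilon = 2*barrier/ln(mean_exit_time)``; requires the mean exit time
    to exceed 1 week so the logarithm is positive.  Round-trips with
    :func:`kramers_mean_exit_time`.
    """
    if not barrier > 0:
        raise ValueError(f"barrier must be positive, got {barrier}")
    if not mean_exit_time > 1.0:
        raise ValueError(
            f"mean_exit_time must exceed 1 week (ln must be positive), got {mean_exit_time}"
        )
    return 2.0 * barrier / math.log(mean_exit_time)
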