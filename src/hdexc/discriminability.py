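"""Instantaneous and cumulative discriminability between input histories.

Two input histories drive the neuron to (generally different) states at the
time reference t = 0, set immediately after the last input event.  Because
firing in these linear models depends on the voltage alone, the squared
difference of the two voltage trajectories during the subsequent free
evolution — the *instantaneous discriminability* — measures how separable
the two histories are at each moment; its time integral from 0 to infinity
is the *cumulative discriminability* D, a positive-semidefinite quadratic
form in the state difference at t = 0.

Closed forms:

* IF: ``d(t) = dv0^2 e^(-2 alpha t)`` and ``D = dv0^2 / (2 alpha)``.
* Oscillatory GIF: the voltage difference is a damped sinusoid
  ``e^(-lam t) (c cos(w t) + d sin(w t))``, so ``d(t)`` is a squared damped
  sinusoid and D is assembled from the elementary integrals of
  ``e^(-2 lam t) {cos^2, sin^2, sin cos}(w t)``.
* Real-eigenvalue GIF: bi-exponential voltage difference, integrated
  term by term.

An adaptive quadrature of ``d(t)`` is provided as an independent check.
Marginally stable models (``alpha = 0`` or ``lam = 0``) have infinite
memory; their cumulative discriminability is reported as ``inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate

from .models import LinearNeuronModel, SpikeTrain, propagate_train, propagator

__all__ = [
    "StateDifference",
    "DiscriminabilityResult",
    "instantaneous_discriminability",
    "cumulative_discriminability",
    "cumulative_discriminability_quadrature",
    "train_discriminability",
    "argmax_instantaneous",
    "state_difference",
    "quadratic_form_matrix",
]


@dataclass(frozen=True)
class StateDifference:
    """Difference in (v, w) between two histories at t = 0+ (``dw`` unused for IF)."""

    dv: float
    dw: float = 0.0

    def as_array(self, dim: int) -> np.ndarray:
        if dim == 1:
            return np.array([self.dv])
        return np.array([self.dv, self.dw])

    def __mul__(self, c: float) -> "StateDifference":
        return StateDifference(c * self.dv, c * self.dw)

    __rmul__ = __mul__


@dataclass
class DiscriminabilityResult:
    """Cumulative value, argmax of the instantaneous trajectory, and the state difference."""

    cumulative: float
    t_max: float
    d_max: float
    sd: StateDifference
    trajectory_t: Optional[np.ndarray] = None
    trajectory_d: Optional[np.ndarray] = None


def state_difference(
    model: LinearNeuronModel, train_a: SpikeTrain, train_b: SpikeTrain
) -> StateDifference:
    """State difference at t = 0+ between two trains ending at t = 0."""
    for name, tr in (("A", train_a), ("B", train_b)):
        if not tr.ends_at_zero:
            raise ValueError(
                f"train {name} must end at t = 0 (re-reference the event times)"
            )
    xa = propagate_train(model, train_a)
    xb = propagate_train(model, train_b)
    return StateDifference(xa.v - xb.v, xa.w - xb.w)


def _voltage_difference_coefficients(model: LinearNeuronModel, sd: StateDifference):
    """Coefficients of the free voltage-difference trajectory.

    Oscillatory GIF: returns (c, d) with dv(t) = e^(-lam t)(c cos wt + d sin wt).
    Real-eigenvalue GIF: returns (c1, c2) with dv(t) = c1 e^(mu1 t) + c2 e^(mu2 t).
    """
    A = model.A
    x0 = sd.as_array(2)
    if model.oscillatory:
        lam, om = model.lam, model.omega
        c = x0[0]
        d = ((A[0, 0] + lam) * x0[0] + A[0, 1] * x0[1]) / om
        return c, d
    mu1, mu2 = (ev.real for ev in model.eigenvalues)
    I = np.eye(2)
    c1 = ((A - mu2 * I) @ x0)[0] / (mu1 - mu2)
    c2 = ((A - mu1 * I) @ x0)[0] / (mu2 - mu1)
    return c1, c2


def instantaneous_discriminability(model: LinearNeuronModel, sd: StateDifference, t):
    """Squared voltage difference at time(s) ``t >= 0`` after the last event."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("instantaneous discriminability is defined for t >= 0")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if model.dim == 1:
        dv = sd.dv * np.exp(-model.alpha * t)
    elif model.oscillatory:
        c, d = _voltage_difference_coefficients(model, sd)
        dv = np.exp(-model.lam * t) * (c * np.cos(model.omega * t) + d * np.sin(model.omega * t))
    else:
        c1, c2 = _voltage_difference_coefficients(model, sd)
        mu1, mu2 = (ev.real for ev in model.eigenvalues)
        dv = c1 * np.exp(mu1 * t) + c2 * np.exp(mu2 * t)
    out = dv * dv
    return float(out[0]) if scalar else out


def quadratic_form_matrix(model: LinearNeuronModel) -> np.ndarray:
    """Matrix W of the cumulative discriminability quadratic form D = sd' W sd.

    Assembled in closed form from the elementary integrals
    ``I_cc, I_ss, I_sc = int_0^inf e^(-2 lam t) {cos^2, sin^2, sin cos}(w t) dt``
    (oscillatory case) or the bi-exponential integrals (real case).
    Raises for marginally stable models (divergent integral).
    """
    if not model.is_stable:
        raise FloatingPointError("cumulative discriminability diverges for marginally stable models")
    if model.dim == 1:
        return np.array([[1.0 / (2.0 * model.alpha)]])
    A = model.A
    if model.oscillatory:
        lam, om = model.lam, model.omega
        k = 2.0 * lam
        i_cc = 0.5 / k + 0.5 * k / (k * k + 4.0 * om * om)
        i_ss = 0.5 / k - 0.5 * k / (k * k + 4.0 * om * om)
        i_sc = om / (k * k + 4.0 * om * om)
        # dv(t) = e^(-lam t) (c cos + d sin), with (c, d) linear in sd:
        # c = e1' sd, d = g' sd where g = [(A00+lam)/om, A01/om]
        e1 = np.array([1.0, 0.0])
        g = np.array([(A[0, 0] + lam) / om, A[0, 1] / om])
        return (
            i_cc * np.outer(e1, e1)
            + i_ss * np.outer(g, g)
            + i_sc * (np.outer(e1, g) + np.outer(g, e1))
        )
    mu1, mu2 = (ev.real for ev in model.eigenvalues)
    I = np.eye(2)
    # dv(t) = p1' sd e^(mu1 t) + p2' sd e^(mu2 t)
    p1 = (A - mu2 * I)[0] / (mu1 - mu2)
    p2 = (A - mu1 * I)[0] / (mu2 - mu1)
    return (
        np.outer(p1, p1) / (-2.0 * mu1)
        + np.outer(p2, p2) / (-2.0 * mu2)
        + (np.outer(p1, p2) + np.outer(p2, p1)) / (-(mu1 + mu2))
    )


def cumulative_discriminability(model: LinearNeuronModel, sd: StateDifference) -> float:
    """Closed-form cumulative discriminability ``D = int_0^inf dv(t)^2 dt``.

    Returns ``inf`` for marginally stable models with a nonzero difference
    (perfect integrator / undamped oscillator: infinite memory).
    """
    x0 = sd.as_array(model.dim)
    if not model.is_stable:
        if np.allclose(x0, 0.0):
            return 0.0
        return math.inf
    W = quadratic_form_matrix(model)
    return float(x0 @ W @ x0)


def cumulative_discriminability_quadrature(
    model: LinearNeuronModel, sd: StateDifference, tol: float = 1e-12
) -> float:
    """Adaptive-quadrature evaluation of the cumulative discriminability.

    Independent numerical check of the closed form: integrates the
    instantaneous discriminability out to a horizon where its envelope has
    decayed below ``tol`` relative to the initial state magnitude.
    """
    x0 = sd.as_array(model.dim)
    norm2 = float(x0 @ x0)
    if norm2 == 0.0:
        return 0.0
    if not model.is_stable:
        return math.inf
    decay = model.decay
    horizon = max(1.0, -math.log(tol) / (2.0 * decay))
    period_pts = None
    if model.dim == 2 and model.oscillatory:
        # break the integration at the sinusoid zeros for quadrature accuracy
        n = int(horizon * model.omega / math.pi) + 1
        period_pts = min(n, 40)
    if period_pts and period_pts > 1:
        edges = np.linspace(0.0, horizon, period_pts + 1)
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(
                lambda t: instantaneous_discriminability(model, sd, t),
                a, b, epsabs=1e-14, epsrel=1e-11, limit=200,
            )
            total += val
        return total
    val, _ = integrate.quad(
        lambda t: instantaneous_discriminability(model, sd, t),
        0.0, horizon, epsabs=1e-14, epsrel=1e-11, limit=200,
    )
    return val


def argmax_instantaneous(model: LinearNeuronModel, sd: StateDifference):
    """Time and value of the maximal instantaneous discriminability on t >= 0.

    IF (and real-eigenvalue GIF with same-sign coefficients): monotone decay,
    maximum at t = 0.  Oscillatory GIF: the extrema of the damped sinusoid
    occur where ``tan(w t - phi) = -lam/w``; the decaying envelope makes the
    first nonnegative extremum the largest interior candidate, compared
    against the value at t = 0.
    """
    d0 = instantaneous_discriminability(model, sd, 0.0)
    if model.dim == 1:
        return 0.0, d0
    if model.oscillatory:
        c, d = _voltage_difference_coefficients(model, sd)
        if c == 0.0 and d == 0.0:
            return 0.0, 0.0
        lam, om = model.lam, model.omega
        phi = math.atan2(d, c)  # dv = R e^(-lam t) cos(w t - phi)
        psi = math.atan(-lam / om)
        # critical times of dv: w t - phi = psi + k pi
        t_crit = (phi + psi) / om
        while t_crit < 0.0:
            t_crit += math.pi / om
        d_crit = instantaneous_discriminability(model, sd, t_crit)
        if d_crit > d0:
            return t_crit, float(d_crit)
        return 0.0, float(d0)
    # real eigenvalues: dv^2 may have one interior extremum; check it
    c1, c2 = _voltage_difference_coefficients(model, sd)
    mu1, mu2 = (ev.real for ev in model.eigenvalues)
    if c1 * c2 < 0:  # dv' = 0 at a single positive time if the ratio is right
        ratio = -(c2 * mu2) / (c1 * mu1)
        if ratio > 0:
            t_crit = math.log(ratio) / (mu1 - mu2)
            if t_crit > 0:
                d_crit = instantaneous_discriminability(model, sd, t_crit)
                if d_crit > d0:
                    return t_crit, float(d_crit)
    return 0.0, float(d0)


def train_discriminability(
    model: LinearNeuronModel,
    train_a: SpikeTrain,
    train_b: SpikeTrain,
    t_grid: Optional[np.ndarray] = None,
) -> DiscriminabilityResult:
    """Full discriminability result for two input trains ending at t = 0.

    The state difference is computed by exact propagation of both trains
    (events shared by the two trains cancel exactly, by linearity); the
    cumulative value uses the closed-form quadratic form, and the argmax of
    the instantaneous trajectory is located in closed form.
    """
    sd = state_difference(model, train_a, train_b)
    cum = cumulative_discriminability(model, sd)
    t_max, d_max = argmax_instantaneous(model, sd)
    traj_t = traj_d = None
    if t_grid is not None:
        traj_t = np.asarray(t_grid, dtype=float)
        traj_d = instantaneous_discriminability(model, sd, traj_t)
    return DiscriminabilityResult(cum, t_max, d_max, sd, traj_t, traj_d)
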