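"""History-dependent excitability (HDE).

The HDE at a moment in time is the minimal amplitude of an instantaneous
excitatory event that makes the neuron reach its firing threshold.  For a
linear model with a fixed voltage threshold ``theta`` and immediate-crossing
spiking it reduces to ``theta - v(t)`` along the free evolution — the
analytic mode.  For arbitrary simulators (or for delayed crossings within a
look-ahead horizon) the HDE is probed numerically by branching the
simulation at the probe time with different event amplitudes and bisecting
on the minimal spike-evoking amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy import optimize

from .models import LinearNeuronModel, NeuronState, free_evolution, propagator

__all__ = [
    "HDEConfig",
    "HDETrajectory",
    "HDEProbe",
    "hde_trajectory",
    "numerical_hde",
    "linear_threshold_simulator",
]


class SpikePredicateError(RuntimeError):
    """The simulator's spike predicate is not monotone in the event amplitude."""


@dataclass(frozen=True)
class HDEConfig:
    """Threshold and probing parameters.

    theta : firing-threshold voltage (default 3, keeping unit-amplitude
        worked examples subthreshold).
    horizon : look-ahead window for delayed threshold crossing (u.t.);
        0 means the crossing must occur at the event itself.
    s_bounds : bracketing interval for the amplitude bisection.
    tol : bisection tolerance on the amplitude.
    """

    theta: float = 3.0
    horizon: float = 0.0
    s_bounds: tuple[float, float] = (0.0, 10.0)
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be > 0")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if not self.s_bounds[0] < self.s_bounds[1]:
            raise ValueError("s_bounds must be an increasing pair")


@dataclass
class HDETrajectory:
    """Minimal spike-evoking amplitude sampled on a time grid."""

    times: np.ndarray
    values: np.ndarray


class HDEProbe(NamedTuple):
    """Result of a numerical HDE probe.

    ``status`` is "ok" when the minimal amplitude lies inside the bracket,
    "above_bracket" when even the upper bound fails to evoke a spike
    (amplitude reported as +inf), and "below_bracket" when the lower bound
    already spikes (the true minimum is at or below it).
    """

    amplitude: float
    status: str


def hde_trajectory(
    model: LinearNeuronModel,
    state0: NeuronState,
    t_grid,
    config: HDEConfig,
) -> HDETrajectory:
    """Analytic HDE along the free evolution: ``theta - v(t)`` (horizon 0)."""
    if config.horizon != 0.0:
        raise ValueError("analytic HDE requires horizon = 0; use numerical_hde otherwise")
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise ValueError("time grid must be nonnegative")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    x0 = state0.as_array(model.dim)
    values = np.empty_like(t_grid)
    for i, t in enumerate(t_grid):
        values[i] = config.theta - (propagator(model, float(t)) @ x0)[0]
    return HDETrajectory(t_grid, values)


def numerical_hde(
    simulator: Callable[[float, float], bool],
    t_probe: float,
    config: HDEConfig,
) -> HDEProbe:
    """Minimal spike-evoking amplitude at ``t_probe`` by bisection.

    ``simulator(t_probe, amplitude)`` must report whether a spike occurs
    within ``config.horizon`` after an event of that amplitude applied at
    the probe time, and must be monotone in the amplitude (a violation at
    the bracket endpoints raises :class:`SpikePredicateError`).
    """
    lo, hi = config.s_bounds
    spikes_lo = bool(simulator(t_probe, lo))
    spikes_hi = bool(simulator(t_probe, hi))
    if spikes_lo and not spikes_hi:
        raise SpikePredicateError(
            "spike at the lower amplitude bound but not at the upper: "
            "the spike predicate is not monotone in amplitude"
        )
    if spikes_lo:
        return HDEProbe(lo, "below_bracket")
    if not spikes_hi:
        return HDEProbe(math.inf, "above_bracket")
    while hi - lo > config.tol:
        mid = 0.5 * (lo + hi)
        if simulator(t_probe, mid):
            hi = mid
        else:
            lo = mid
    return HDEProbe(0.5 * (lo + hi), "ok")


def linear_threshold_simulator(
    model: LinearNeuronModel,
    state0: NeuronState,
    config: HDEConfig,
    n_scan: int = 512,
) -> Callable[[float, float], bool]:
    """Spike predicate for a linear model with a fixed voltage threshold.

    The returned callback evolves ``state0`` freely to the probe time,
    applies the event, and reports whether the voltage reaches
    ``config.theta`` within ``config.horizon`` afterwards (at the event
    itself when the horizon is 0).  The post-event maximum is located by a
    dense scan refined with bounded scalar minimization, which is reliable
    for these damped (at most bi-harmonic) trajectories.
    """

    def spikes(t_probe: float, amplitude: float) -> bool:
        st = free_evolution(model, state0, t_probe)
        x = st.as_array(model.dim)
        x[0] += amplitude
        if x[0] >= config.theta:
            return True
        if config.horizon == 0.0:
            return False

        def v_of(t: float) -> float:
            return float((propagator(model, t) @ x)[0])

        ts = np.linspace(0.0, config.horizon, n_scan)
        vs = np.array([v_of(t) for t in ts])
        i = int(np.argmax(vs))
        if vs[i] >= config.theta:
            return True
        a = ts[max(i - 1, 0)]
        b = ts[min(i + 1, n_scan - 1)]
        if b > a:
            res = optimize.minimize_scalar(lambda t: -v_of(t), bounds=(a, b), method="bounded")
            if -res.fun >= config.theta:
                return True
        return False

    return spikes
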