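"""Linear subthreshold neuron models and exact propagation under pulse inputs.

Two model families are supported, both dimensionless (time in arbitrary
units, "u.t."):

* **IF** — the leaky integrate-and-fire membrane, a single linear ODE
  ``dv/dt = -alpha * v`` with decay rate ``alpha >= 0``.
* **GIF** — the generalized integrate-and-fire membrane, a two-variable
  linear system in which a recovery variable ``w`` tracks the voltage and
  (for the resonant parameter regime) produces damped subthreshold
  oscillations.  The system is parameterized by its eigenvalues
  ``-lam +/- i*omega`` (decay rate ``lam`` and intrinsic angular frequency
  ``omega``), realized by the relaxing-recovery system::

      dv/dt = -a*v - b*w        a = 2*lam - 1
      dw/dt =  v   - w          b = (lam - 1)**2 + omega**2

Excitatory synaptic events (EPSPs) are instantaneous, voltage-independent
shifts of ``v``; the spike-generation mechanism is not modeled.  Free
evolution is computed in closed form from the eigenstructure — no
time-stepping is involved anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LinearNeuronModel",
    "NeuronState",
    "SpikeTrain",
    "construct_model",
    "if_model",
    "gif_model",
    "gif_model_structural",
    "gif_model_real",
    "free_evolution",
    "apply_epsp",
    "propagate_train",
    "propagator",
    "psp_kernel",
    "damping_coefficient",
]


class ParameterError(ValueError):
    """Invalid or sign-violating model parameter."""


class StabilityError(ValueError):
    """Requested model is not (strictly) stable where stability is required."""


@dataclass(frozen=True)
class LinearNeuronModel:
    """A linear subthreshold neuron model in unified matrix form.

    Attributes
    ----------
    kind : {"IF", "GIF"}
    alpha : float
        IF decay rate (per u.t.); ``nan`` for GIF.
    lam : float
        Magnitude of the real part of the eigenvalues (decay rate).  For an
        IF model this equals ``alpha``; for a real-eigenvalue GIF it is the
        mean decay rate ``-(mu1 + mu2)/2``.
    omega : float
        Imaginary part of the GIF eigenvalues (intrinsic angular frequency);
        ``0`` for IF and for real-eigenvalue GIF models.
    A : numpy.ndarray
        System matrix: shape (1, 1) holding ``-alpha`` for IF, (2, 2) for GIF.
    eigenvalues : tuple of complex
        ``(-alpha,)`` for IF; ``(mu1, mu2)`` for GIF.
    """

    kind: str
    alpha: float
    lam: float
    omega: float
    A: np.ndarray = field(repr=False)
    eigenvalues: tuple

    @property
    def dim(self) -> int:
        return self.A.shape[0]

    @property
    def oscillatory(self) -> bool:
        """True when the eigenvalues are complex (damped oscillations)."""
        return self.omega > 0.0

    @property
    def decay(self) -> float:
        """Slowest decay rate: governs the envelope of every free trajectory."""
        return min(-ev.real for ev in self.eigenvalues)

    @property
    def is_stable(self) -> bool:
        return all(ev.real < 0 for ev in self.eigenvalues)


@dataclass
class NeuronState:
    """Membrane state: voltage deviation ``v`` from rest and recovery ``w``.

    ``w`` is ignored for IF models.  ``t`` is an optional time stamp.
    """

    v: float
    w: float = 0.0
    t: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v) and math.isfinite(self.w)):
            raise ParameterError("state entries must be finite")

    @classmethod
    def rest(cls, t: float | None = None) -> "NeuronState":
        return cls(0.0, 0.0, t)

    def as_array(self, dim: int) -> np.ndarray:
        if dim == 1:
            return np.array([self.v], dtype=float)
        return np.array([self.v, self.w], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray, t: float | None = None) -> "NeuronState":
        if x.shape[0] == 1:
            return cls(float(x[0]), 0.0, t)
        return cls(float(x[0]), float(x[1]), t)


@dataclass
class SpikeTrain:
    """An ordered train of instantaneous EPSPs.

    ``times`` are strictly increasing event times (u.t.); ``amplitudes`` is
    either a shared positive scalar or one positive amplitude per event.
    For discriminability computations the convention is that the last event
    is at t = 0 and all earlier events at negative times.
    """

    times: np.ndarray
    amplitudes: np.ndarray

    def __init__(self, times: Sequence[float], amplitudes: float | Sequence[float] = 1.0):
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ParameterError("train must contain at least one event")
        if not np.all(np.isfinite(times)):
            raise ParameterError("event times must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ParameterError("event times must be strictly increasing")
        amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), times.shape).copy()
        if not np.all(np.isfinite(amplitudes)) or np.any(amplitudes <= 0):
            raise ParameterError("amplitudes must be finite and positive")
        self.times = times
        self.amplitudes = amplitudes

    def __len__(self) -> int:
        return self.times.size

    @property
    def ends_at_zero(self) -> bool:
        return abs(self.times[-1]) < 1e-12

    def shifted(self, dt: float) -> "SpikeTrain":
        return SpikeTrain(self.times + dt, self.amplitudes)

    def appended(self, extra_times: Sequence[float], amplitude: float = 1.0) -> "SpikeTrain":
        """Append later events (all strictly after the current last one)."""
        extra_times = np.asarray(extra_times, dtype=float)
        amps = np.broadcast_to(np.asarray(amplitude, dtype=float), extra_times.shape)
        return SpikeTrain(
            np.concatenate([self.times, extra_times]),
            np.concatenate([self.amplitudes, amps]),
        )


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def if_model(alpha: float = 1.0) -> LinearNeuronModel:
    """Leaky integrate-and-fire model with decay rate ``alpha >= 0``.

    ``alpha = 0`` (the perfect integrator) is legal; downstream cumulative
    quantities then diverge and are reported as infinite.
    """
    if not math.isfinite(alpha) or alpha < 0:
        raise ParameterError(f"IF decay rate must be finite and >= 0, got {alpha}")
    A = np.array([[-alpha]], dtype=float)
    return LinearNeuronModel("IF", alpha, alpha, 0.0, A, (-alpha + 0j,))


def _gif_from_structural(a: float, b: float) -> LinearNeuronModel:
    A = np.array([[-a, -b], [1.0, -1.0]], dtype=float)
    tr = -a - 1.0
    det = a + b
    lam = -tr / 2.0
    disc = tr * tr - 4.0 * det
    if disc < 0:
        omega = math.sqrt(-disc) / 2.0
        eigs = (complex(-lam, omega), complex(-lam, -omega))
    else:
        r = math.sqrt(disc) / 2.0
        eigs = (complex(-lam - r), complex(-lam + r))
        omega = 0.0
    return LinearNeuronModel("GIF", math.nan, lam, omega, A, eigs)


def gif_model(lam: float = 1.0, omega: float = 2.0) -> LinearNeuronModel:
    """Oscillatory GIF model with eigenvalues ``-lam +/- i*omega``.

    The canonical model of this package has ``lam = 1`` and ``omega = 2``.
    """
    if not (math.isfinite(lam) and math.isfinite(omega)):
        raise ParameterError("lam and omega must be finite")
    if lam <= 0:
        raise StabilityError(f"GIF decay rate must be > 0, got {lam}")
    if omega <= 0:
        raise ParameterError(f"GIF intrinsic frequency must be > 0, got {omega}")
    a = 2.0 * lam - 1.0
    b = (lam - 1.0) ** 2 + omega ** 2
    return _gif_from_structural(a, b)


def gif_model_structural(a: float, b: float) -> LinearNeuronModel:
    """GIF model from the structural pair (effective leak ``a``, coupling ``b``)."""
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ParameterError("structural parameters must be finite")
    model = _gif_from_structural(a, b)
    if not model.is_stable:
        raise StabilityError("structural GIF parameters yield an unstable model")
    return model


def gif_model_real(mu1: float, mu2: float) -> LinearNeuronModel:
    """Non-oscillatory GIF model with two real eigenvalues ``mu1 < mu2 < 0``."""
    if not (math.isfinite(mu1) and math.isfinite(mu2)):
        raise ParameterError("eigenvalues must be finite")
    if not (mu1 < mu2 < 0):
        raise StabilityError(f"real eigenvalues must satisfy mu1 < mu2 < 0, got {mu1}, {mu2}")
    a = -(mu1 + mu2) - 1.0
    b = mu1 * mu2 - a
    return _gif_from_structural(a, b)


def construct_model(kind: str, **params) -> LinearNeuronModel:
    """Dispatching constructor: ``construct_model("GIF", lam=1, omega=2)`` etc.

    GIF models accept eigenvalue parameters (``lam``, ``omega``), the
    structural pair (``a``, ``b``), or two real eigenvalues (``mu1``, ``mu2``).
    """
    kind = kind.upper()
    if kind == "IF":
        return if_model(params.get("alpha", 1.0))
    if kind == "GIF":
        if {"mu1", "mu2"} <= params.keys():
            return gif_model_real(params["mu1"], params["mu2"])
        if {"a", "b"} <= params.keys():
            return gif_model_structural(params["a"], params["b"])
        return gif_model(params.get("lam", 1.0), params.get("omega", 2.0))
    raise ParameterError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def propagator(model: LinearNeuronModel, t: float) -> np.ndarray:
    """Closed-form matrix exponential ``exp(A*t)``.

    IF: the scalar ``e^(-alpha t)``.  Complex-eigenvalue GIF: the damped
    rotation ``e^(-lam t) [cos(w t) I + sin(w t)/w (A + lam I)]``.  Real
    distinct eigenvalues: the Lagrange two-point form; a repeated eigenvalue
    uses its confluent limit.
    """
    if model.dim == 1:
        return np.array([[math.exp(-model.alpha * t)]])
    A = model.A
    I = np.eye(2)
    if model.oscillatory:
        lam, om = model.lam, model.omega
        return math.exp(-lam * t) * (
            math.cos(om * t) * I + (math.sin(om * t) / om) * (A + lam * I)
        )
    mu1, mu2 = (ev.real for ev in model.eigenvalues)
    if abs(mu1 - mu2) > 1e-12 * max(abs(mu1), abs(mu2), 1.0):
        return (
            math.exp(mu1 * t) * (A - mu2 * I) - math.exp(mu2 * t) * (A - mu1 * I)
        ) / (mu1 - mu2)
    mu = 0.5 * (mu1 + mu2)
    return math.exp(mu * t) * (I + t * (A - mu * I))


def free_evolution(model: LinearNeuronModel, state: NeuronState, t: float) -> NeuronState:
    """Evolve ``state`` for a duration ``t >= 0`` under the intrinsic dynamics."""
    if t < 0:
        raise ValueError(f"free evolution requires t >= 0, got {t}")
    x = propagator(model, t) @ state.as_array(model.dim)
    t_out = None if state.t is None else state.t + t
    return NeuronState.from_array(x, t_out)


def apply_epsp(state: NeuronState, amplitude: float) -> NeuronState:
    """Apply an instantaneous EPSP: ``v -> v + amplitude``, ``w`` unchanged."""
    if not math.isfinite(amplitude):
        raise ParameterError("EPSP amplitude must be finite")
    return NeuronState(state.v + amplitude, state.w, state.t)


def propagate_train(
    model: LinearNeuronModel,
    train: SpikeTrain,
    initial_state: NeuronState | None = None,
) -> NeuronState:
    """State immediately after the last event of ``train``.

    Alternates exact free evolution over each inter-event interval with the
    instantaneous EPSP jump at each event (the jump of an event is included
    at its own time).  With the discriminability convention (last event at
    t = 0) the result is the state at t = 0+.
    """
    state = initial_state if initial_state is not None else NeuronState.rest()
    x = state.as_array(model.dim)
    prev = None
    for t_ev, s in zip(train.times, train.amplitudes):
        if prev is not None:
            x = propagator(model, t_ev - prev) @ x
        x = x.copy()
        x[0] += s
        prev = t_ev
    return NeuronState.from_array(x, float(train.times[-1]))


def psp_kernel(model: LinearNeuronModel, t):
    """Causal PSP kernel: response of (v, w) at lag ``t`` to a unit EPSP at rest.

    Zero for ``t < 0``; the value at ``t = 0`` is the full jump (``Kv(0) = 1``).
    Accepts scalars or arrays of lags and returns ``(Kv, Kw)`` with the same
    shape (``Kw`` is identically 0 for IF).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    kv = np.zeros_like(t)
    kw = np.zeros_like(t)
    causal = t >= 0
    tc = t[causal]
    if model.dim == 1:
        kv[causal] = np.exp(-model.alpha * tc)
    elif model.oscillatory:
        lam, om = model.lam, model.omega
        A = model.A
        env = np.exp(-lam * tc)
        # exp(A t) e1 = e^(-lam t)[cos(w t) e1 + sin(w t)/w (A + lam I) e1]
        c0v, c0w = 1.0, 0.0
        c1v = (A[0, 0] + lam) / om
        c1w = (A[1, 0]) / om
        kv[causal] = env * (np.cos(om * tc) * c0v + np.sin(om * tc) * c1v)
        kw[causal] = env * (np.cos(om * tc) * c0w + np.sin(om * tc) * c1w)
    else:
        for tt, idx in zip(tc, np.nonzero(causal)[0]):
            col = propagator(model, float(tt))[:, 0]
            kv[idx], kw[idx] = col[0], col[1]
    if scalar:
        return float(kv[0]), float(kw[0])
    return kv, kw


def damping_coefficient(model: LinearNeuronModel) -> float:
    """Peak-to-peak damping ratio Q of the free voltage oscillation.

    Successive voltage peaks are one intrinsic period ``2*pi/omega`` apart,
    so ``Q = exp(-2*pi*lam/omega)``.  Defined only for oscillatory GIF models.
    """
    if model.dim == 1 or not model.oscillatory:
        raise ValueError("damping coefficient is defined only for oscillatory GIF models")
    return math.exp(-2.0 * math.pi * model.lam / model.omega)
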