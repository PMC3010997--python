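"""Structured discriminability experiments.

* Doublet maps: D over a grid of (ISI1, ISI2) input pairs, and the location
  of the off-diagonal local maximum that intrinsic oscillations create.
* Fixed-duration triplets: "accelerating" vs "decelerating" three-event
  trains with the same total duration 2m, middle event shifted by +/- delta/2.
* Sensitivity: the minimal ISI difference delta_isi_min at which the
  triplet discriminability reaches a significance threshold theta_D
  (analytic inversion for IF, scan + bisection for GIF; left undefined when
  the threshold is crossed more than once or never).
* Parameter sweeps of delta_isi_min over decay rate, intrinsic frequency,
  or both at a fixed damping ratio, with a matched IF model alongside.
* Memory decay: D after appending common trailing events to both trains,
  quantifying the exponential forgetting of early input structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .discriminability import (
    StateDifference,
    cumulative_discriminability,
    quadratic_form_matrix,
    train_discriminability,
)
from .models import LinearNeuronModel, SpikeTrain, gif_model, if_model, psp_kernel

__all__ = [
    "SensitivityConfig",
    "SensitivityResult",
    "doublet_discriminability",
    "triplet_discriminability",
    "triplet_discriminability_if_closed",
    "delta_isi_min",
    "delta_isi_min_if_analytic",
    "sweep_sensitivity",
    "doublet_map",
    "locate_doublet_maximum",
    "memory_decay_curve",
]


@dataclass(frozen=True)
class SensitivityConfig:
    """Parameters of the delta_isi_min sensitivity analysis.

    theta_d : discriminability significance threshold (default 0.5).
    mean_isi : mean ISI m of the fixed-duration triplets (total duration 2m).
    amplitude : EPSP amplitude s (default 2, which keeps delta_isi_min
        defined at the canonical parameters; with s = 1 the required
        difference exceeds the admissible range 2m at m = 1).
    n_grid : scan resolution for threshold-crossing counting (coarser grids
        can miss paired crossings).
    root_tol : bisection tolerance on delta.
    """

    theta_d: float = 0.5
    mean_isi: float = 1.0
    amplitude: float = 2.0
    n_grid: int = 2000
    root_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.theta_d > 0:
            raise ValueError("theta_d must be > 0")
        if not self.mean_isi > 0:
            raise ValueError("mean_isi must be > 0")
        if self.n_grid < 8:
            raise ValueError("n_grid too coarse")


@dataclass
class SensitivityResult:
    """delta_isi_min (None when undefined) and the crossing count behind it."""

    delta_isi_min: Optional[float]
    n_crossings: int

    @property
    def defined(self) -> bool:
        return self.delta_isi_min is not None


def doublet_discriminability(
    model: LinearNeuronModel, isi1: float, isi2: float, s: float = 1.0
) -> float:
    """Cumulative D between the doublets {-isi1, 0} and {-isi2, 0}."""
    if isi1 <= 0 or isi2 <= 0:
        raise ValueError("ISIs must be positive")
    res = train_discriminability(
        model, SpikeTrain([-isi1, 0.0], s), SpikeTrain([-isi2, 0.0], s)
    )
    return res.cumulative


def triplet_discriminability(
    model: LinearNeuronModel, mean_isi: float, delta_isi: float, s: float = 1.0
) -> float:
    """Cumulative D between fixed-duration accelerating/decelerating triplets.

    Accelerating: events at {-2m, -(m - delta/2), 0}; decelerating: the
    middle event mirrored to -(m + delta/2).  Only the middle events differ.
    """
    m, d = mean_isi, delta_isi
    if not 0 <= d < 2 * m:
        raise ValueError("delta_isi must lie in [0, 2*mean_isi)")
    if d == 0.0:
        return 0.0
    acc = SpikeTrain([-2 * m, -(m - d / 2), 0.0], s)
    dec = SpikeTrain([-2 * m, -(m + d / 2), 0.0], s)
    return train_discriminability(model, acc, dec).cumulative


def triplet_discriminability_if_closed(
    alpha: float, mean_isi: float, delta_isi: float, s: float = 1.0
) -> float:
    """IF triplet discriminability in closed form: (2 s^2/alpha) e^(-2 alpha m) sinh^2(alpha delta/2)."""
    if alpha == 0.0:
        return math.inf if delta_isi > 0 else 0.0
    return (2.0 * s * s / alpha) * math.exp(-2.0 * alpha * mean_isi) * math.sinh(
        alpha * delta_isi / 2.0
    ) ** 2


def delta_isi_min_if_analytic(
    alpha: float, config: SensitivityConfig
) -> SensitivityResult:
    """Analytic inversion of the IF triplet closed form.

    delta_min = (2/alpha) asinh(e^(alpha m) sqrt(theta_d alpha / (2 s^2))),
    undefined (clipped) when the required difference reaches 2m.  The IF
    curve is monotone increasing in delta, so the crossing count is 0 or 1.
    """
    m, s, theta = config.mean_isi, config.amplitude, config.theta_d
    if alpha == 0.0:
        return SensitivityResult(None, 0)
    delta = (2.0 / alpha) * math.asinh(
        math.exp(alpha * m) * math.sqrt(theta * alpha / (2.0 * s * s))
    )
    if delta >= 2.0 * m:
        return SensitivityResult(None, 0)
    return SensitivityResult(delta, 1)


def delta_isi_min(model: LinearNeuronModel, config: SensitivityConfig) -> SensitivityResult:
    """Minimal ISI difference at which the triplet discriminability reaches theta_d.

    IF models use the analytic inversion.  GIF models scan D(delta) - theta_d
    on a uniform grid over [0, 2m), count sign changes, and bisect; the
    result is defined only when there is exactly one crossing (non-monotone
    GIF curves can cross the threshold several times, in which case the
    sensitivity is left undefined).
    """
    if model.dim == 1:
        return delta_isi_min_if_analytic(model.alpha, config)
    m = config.mean_isi
    upper = 2.0 * m * (1.0 - 1e-9)
    deltas = np.linspace(0.0, upper, config.n_grid)
    f = np.array(
        [triplet_discriminability(model, m, d, config.amplitude) for d in deltas]
    ) - config.theta_d
    sign = np.sign(f)
    crossings = []
    for i in range(len(deltas) - 1):
        if sign[i] == 0.0:
            continue
        if sign[i] * sign[i + 1] < 0:
            crossings.append((deltas[i], deltas[i + 1]))
    n = len(crossings)
    if n != 1:
        return SensitivityResult(None, n)
    a, b = crossings[0]
    root = optimize.brentq(
        lambda d: triplet_discriminability(model, m, d, config.amplitude) - config.theta_d,
        a, b, xtol=config.root_tol,
    )
    return SensitivityResult(float(root), 1)


def sweep_sensitivity(
    kind: str,
    values,
    config: SensitivityConfig,
    lam0: float = 1.0,
    omega0: float = 2.0,
) -> pd.DataFrame:
    """delta_isi_min for a family of GIF models and their matched IF models.

    ``kind`` selects the sweep: "lam" varies the decay rate at fixed
    intrinsic frequency, "omega" the converse, and "ratio" scales both by a
    common factor, keeping the damping ratio lam/omega (hence the damping
    coefficient Q) fixed.  The matched IF model has alpha equal to the GIF
    decay rate at each grid point.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sweep")
    rows = []
    for val in values:
        if kind == "lam":
            lam, omega = val, omega0
        elif kind == "omega":
            lam, omega = lam0, val
        elif kind == "ratio":
            lam, omega = val * lam0, val * omega0
        else:
            raise ValueError(f"unknown sweep kind {kind!r}")
        gif_res = delta_isi_min(gif_model(lam, omega), config)
        if_res = delta_isi_min_if_analytic(lam, config)
        rows.append(
            {
                "kind": kind,
                "param": val,
                "lam": lam,
                "omega": omega,
                "alpha": lam,
                "mean_isi": config.mean_isi,
                "gif_delta_isi_min": gif_res.delta_isi_min,
                "gif_n_crossings": gif_res.n_crossings,
                "if_delta_isi_min": if_res.delta_isi_min,
                "if_n_crossings": if_res.n_crossings,
            }
        )
    return pd.DataFrame(rows)


def doublet_map(model: LinearNeuronModel, isi_grid, s: float = 1.0) -> np.ndarray:
    """Cumulative D over a (ISI1, ISI2) grid of input doublets (raw values).

    By linearity the shared final event cancels and the state difference is
    ``s (K(isi1) - K(isi2))`` with K the PSP kernel, so the map is evaluated
    as a quadratic form over kernel samples rather than by train-by-train
    propagation.
    """
    isi_grid = np.asarray(isi_grid, dtype=float)
    if np.any(isi_grid <= 0):
        raise ValueError("ISI grid must be positive")
    kv, kw = psp_kernel(model, isi_grid)
    K = np.stack([kv, kw], axis=1) if model.dim == 2 else kv[:, None]
    diff = s * (K[:, None, :] - K[None, :, :])  # (n, n, dim)
    W = quadratic_form_matrix(model)
    return np.einsum("ijk,kl,ijl->ij", diff, W, diff)


def locate_doublet_maximum(
    model: LinearNeuronModel,
    search_region: Optional[tuple] = None,
    n_grid: int = 120,
    s: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    """Off-diagonal ridge maximum of the doublet map, canonically ordered.

    Locates the interior point that is simultaneously a local maximum of
    D(ISI1, ISI2) along each ISI coordinate (the peak of the ridge that
    intrinsic oscillations carve into the map; the IF map, monotone in each
    ISI, has none).  The raw cumulative map additionally rises without an
    interior turning point as both ISIs shrink together toward coincident
    events, so a strict two-dimensional maximum does not exist; the
    coordinate-wise maximum is the well-defined, parameter-trackable
    feature.  Candidates come from a grid scan of the region (default: up
    to twice the intrinsic period per ISI) and are refined by alternating
    bounded one-dimensional maximization to a fixed point.  Returns
    (isi1*, isi2*) with isi1* <= isi2*, or None when no interior
    coordinate-wise maximum exists in the region.
    """
    if model.dim != 2 or not model.oscillatory:
        raise ValueError("doublet-map local maxima require an oscillatory GIF model")
    period = 2.0 * math.pi / model.omega
    if search_region is None:
        search_region = ((0.02 * period, 2.0 * period), (0.02 * period, 2.0 * period))
    (lo1, hi1), (lo2, hi2) = search_region
    g1 = np.linspace(lo1, hi1, n_grid)
    g2 = np.linspace(lo2, hi2, n_grid)
    kv1, kw1 = psp_kernel(model, g1)
    kv2, kw2 = psp_kernel(model, g2)
    K1 = np.stack([kv1, kw1], axis=1)
    K2 = np.stack([kv2, kw2], axis=1)
    diff = s * (K1[:, None, :] - K2[None, :, :])
    W = quadratic_form_matrix(model)
    D = np.einsum("ijk,kl,ijl->ij", diff, W, diff)
    best = None
    for i in range(1, n_grid - 1):
        for j in range(1, n_grid - 1):
            if (
                D[i, j] > D[i - 1, j] and D[i, j] > D[i + 1, j]
                and D[i, j] > D[i, j - 1] and D[i, j] > D[i, j + 1]
            ):
                if best is None or D[i, j] > best[0]:
                    best = (D[i, j], g1[i], g2[j])
    if best is None:
        return None

    def dfun(x1: float, x2: float) -> float:
        return doublet_discriminability(model, x1, x2, s)

    def grad(x: np.ndarray) -> np.ndarray:
        h = 1e-6
        return np.array([
            (dfun(x[0] + h, x[1]) - dfun(x[0] - h, x[1])) / (2 * h),
            (dfun(x[0], x[1] + h) - dfun(x[0], x[1] - h)) / (2 * h),
        ])

    sol = optimize.root(grad, x0=np.array([best[1], best[2]]), method="hybr",
                        options={"xtol": tol})
    isi1, isi2 = float(sol.x[0]), float(sol.x[1])
    # validate: stationary, inside the region, curved downward along each coordinate
    if float(np.abs(grad(sol.x)).max()) > 1e-6:
        return None
    h = 1e-4
    if not (lo1 < isi1 < hi1 and lo2 < isi2 < hi2):
        return None
    d0 = dfun(isi1, isi2)
    if (dfun(isi1 + h, isi2) + dfun(isi1 - h, isi2) - 2 * d0 >= 0
            or dfun(isi1, isi2 + h) + dfun(isi1, isi2 - h) - 2 * d0 >= 0):
        return None
    return (isi1, isi2) if isi1 <= isi2 else (isi2, isi1)


def memory_decay_curve(
    model: LinearNeuronModel,
    train_a: SpikeTrain,
    train_b: SpikeTrain,
    appended_isi: float,
    n_append: int,
    appended_amplitude: float = 1.0,
) -> np.ndarray:
    """D after appending k = 0..n_append common trailing events to both trains.

    Each step appends one more shared event ``appended_isi`` after the
    previous last event (times re-referenced so the last event is at 0).
    The memory of the early difference decays exponentially: per step the
    ratio is e^(-2 alpha L) for the IF model, and exactly Q^2 for the GIF
    model when L is one intrinsic period 2 pi / omega.
    """
    if appended_isi <= 0:
        raise ValueError("appended_isi must be > 0")
    out = np.empty(n_append + 1)
    for k in range(n_append + 1):
        if k == 0:
            ta, tb = train_a, train_b
        else:
            tail = appended_isi * np.arange(1, k + 1)
            ta = train_a.appended(tail, appended_amplitude).shifted(-k * appended_isi)
            tb = train_b.appended(tail, appended_amplitude).shifted(-k * appended_isi)
        out[k] = train_discriminability(model, ta, tb).cumulative
    return out
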