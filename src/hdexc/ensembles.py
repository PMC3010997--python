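"""Random input trains and ensemble discriminability statistics.

Input trains are built by concatenating interspike intervals (ISIs) drawn
from an exponential distribution (the standard irregular-firing model; the
rate is 1/mean) or from a narrow positive-truncated gaussian.  The mean
cumulative discriminability over random train pairs is estimated by Monte
Carlo and — for the construction in which the two trains differ only in a
single ISI — computed in closed form by integrating the pairwise
discriminability against the exponential ISI density.

Determinism: every ensemble run takes a mandatory master seed; each train
pair uses a generator keyed by (seed, pair index), so results are
bit-reproducible and individual pairs can be regenerated in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .discriminability import (
    StateDifference,
    cumulative_discriminability,
    quadratic_form_matrix,
    state_difference,
)
from .models import LinearNeuronModel, SpikeTrain

__all__ = [
    "ISIDistribution",
    "EnsembleSpec",
    "EnsembleResult",
    "sample_train",
    "mc_mean_discriminability",
    "closed_mean_discriminability_exponential",
    "discriminability_histogram",
    "histogram_from_values",
    "state_difference_cloud",
    "isoline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ISIDistribution:
    """ISI distribution: exponential(mean) or positive-truncated gaussian(mean, sd).

    The exponential family has sd = mean by construction.  Gaussian draws
    that fall at or below zero are redrawn (with the default narrow sd the
    truncation rate is negligible; redraw counts are logged at debug level).
    """

    family: str
    mean: float
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "gaussian"):
            raise ValueError(f"unknown ISI family {self.family!r}")
        if not self.mean > 0:
            raise ValueError("mean ISI must be > 0")
        if self.family == "gaussian":
            if self.sd is None:
                object.__setattr__(self, "sd", 0.05)
            if not self.sd > 0:
                raise ValueError("gaussian sd must be > 0")

    @property
    def rate(self) -> float:
        return 1.0 / self.mean

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "exponential":
            return rng.exponential(self.mean, size)
        isis = rng.normal(self.mean, self.sd, size)
        n_redraw = 0
        bad = isis <= 0
        while np.any(bad):
            n_redraw += int(bad.sum())
            isis[bad] = rng.normal(self.mean, self.sd, int(bad.sum()))
            bad = isis <= 0
        if n_redraw:
            logger.debug("gaussian ISI truncation: %d redraws", n_redraw)
        return isis


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of a random-train discriminability ensemble.

    ``n_isis`` is the number of ISIs per train (1 for doublets, 2 for
    triplets).  ``shared_draws`` forces pairwise-identical trains (a null
    control whose mean discriminability is exactly zero).
    """

    dist_a: ISIDistribution
    dist_b: ISIDistribution
    n_isis: int = 1
    n_pairs: int = 10000
    seed: int = 0
    s: float = 1.0
    shared_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_isis < 1:
            raise ValueError("n_isis must be >= 1")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class EnsembleResult:
    """Mean/sd/sem of the cumulative discriminability over an ensemble."""

    mean: float
    sd: float
    sem: float
    n_pairs: int
    seed: int
    values: Optional[np.ndarray] = None
    hist_edges: Optional[np.ndarray] = None
    hist_density: Optional[np.ndarray] = None
    cloud: Optional[np.ndarray] = None
    levels: Optional[tuple] = None


def sample_train(
    dist: ISIDistribution,
    n_isis: int,
    rng: np.random.Generator,
    amplitude: float = 1.0,
) -> SpikeTrain:
    """Random train of ``n_isis + 1`` events, referenced so the last is at t = 0."""
    isis = dist.draw(rng, n_isis)
    times = np.concatenate([-np.cumsum(isis[::-1])[::-1], [0.0]])
    return SpikeTrain(times, amplitude)


def _pair_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _sample_pair_sd(
    model: LinearNeuronModel, spec: EnsembleSpec, index: int
) -> StateDifference:
    rng = _pair_rng(spec.seed, index)
    train_a = sample_train(spec.dist_a, spec.n_isis, rng, spec.s)
    if spec.shared_draws:
        train_b = train_a
    else:
        train_b = sample_train(spec.dist_b, spec.n_isis, rng, spec.s)
    return state_difference(model, train_a, train_b)


def mc_mean_discriminability(
    model: LinearNeuronModel,
    spec: EnsembleSpec,
    keep_values: bool = False,
    keep_cloud: bool = False,
    hist_bins: Optional[int] = None,
) -> EnsembleResult:
    """Monte-Carlo ensemble of cumulative discriminability over random train pairs."""
    values = np.empty(spec.n_pairs)
    cloud = np.empty((spec.n_pairs, 2)) if keep_cloud else None
    for i in range(spec.n_pairs):
        sd = _sample_pair_sd(model, spec, i)
        values[i] = cumulative_discriminability(model, sd)
        if keep_cloud:
            cloud[i] = (sd.dv, sd.dw)
    mean = float(values.mean())
    std = float(values.std(ddof=1)) if spec.n_pairs > 1 else 0.0
    sem = std / math.sqrt(spec.n_pairs)
    edges = density = None
    if hist_bins is not None:
        edges, density = histogram_from_values(values, hist_bins)
    return EnsembleResult(
        mean, std, sem, spec.n_pairs, spec.seed,
        values if keep_values else None, edges, density, cloud,
    )


def closed_mean_discriminability_exponential(
    model: LinearNeuronModel, rate_a: float, rate_b: float, s: float = 1.0
) -> float:
    """Closed-form mean discriminability for exponential single-differing-ISI pairs.

    The two trains share every event except one: the differing event lies an
    exponentially distributed interval (rate ``rate_a`` vs ``rate_b``)
    before the following shared event.  For the IF model::

        E[D] = s^2/(2 alpha) [ r_a/(r_a + 2 alpha) + r_b/(r_b + 2 alpha)
                               - 2 r_a r_b / ((r_a + alpha)(r_b + alpha)) ]

    For the GIF the expectation of the quadratic form is assembled from the
    Laplace transforms of the PSP kernel: E[K] = r (rI - A)^{-1} e1 and
    E[K K^T] = r Y with (A - r/2 I) Y + Y (A^T - r/2 I) = -e1 e1^T.
    """
    if rate_a <= 0 or rate_b <= 0:
        raise ValueError("rates must be > 0")
    if not model.is_stable:
        return math.inf
    if model.dim == 1:
        al = model.alpha
        return (s * s / (2.0 * al)) * (
            rate_a / (rate_a + 2.0 * al)
            + rate_b / (rate_b + 2.0 * al)
            - 2.0 * rate_a * rate_b / ((rate_a + al) * (rate_b + al))
        )
    A = model.A
    W = quadratic_form_matrix(model)
    e1 = np.array([1.0, 0.0])
    I = np.eye(2)
    C = np.outer(e1, e1)

    def mean_kernel(r: float) -> np.ndarray:
        return r * np.linalg.solve(r * I - A, e1)

    def mean_outer(r: float) -> np.ndarray:
        return r * linalg.solve_continuous_lyapunov(A - 0.5 * r * I, -C)

    ka, kb = mean_kernel(rate_a), mean_kernel(rate_b)
    ma, mb = mean_outer(rate_a), mean_outer(rate_b)
    return float(s * s * (np.trace(W @ ma) + np.trace(W @ mb) - 2.0 * ka @ W @ kb))


def histogram_from_values(values: np.ndarray, bins: int):
    """Normalized density of discriminability values on log-spaced bins.

    Mass concentrates near zero, so the first bin is an explicit zero bin
    and the remaining edges are log-spaced over the positive values.
    """
    values = np.asarray(values, dtype=float)
    vmax = values.max()
    if vmax <= 0.0:
        edges = np.array([0.0, 1.0])
        density = np.array([1.0])
        return edges, density
    pos = values[values > 0]
    lo = pos.min()
    edges = np.concatenate([[0.0], np.geomspace(lo, vmax, bins)])
    edges[-1] = np.nextafter(edges[-1], np.inf)
    density, edges = np.histogram(values, bins=edges, density=True)
    return edges, density


def discriminability_histogram(model: LinearNeuronModel, spec: EnsembleSpec, bins: int):
    """Monte-Carlo density of the cumulative discriminability over an ensemble."""
    if spec.n_pairs < bins:
        raise ValueError("n_pairs must be >= bins")
    result = mc_mean_discriminability(model, spec, keep_values=True)
    return histogram_from_values(result.values, bins)


def state_difference_cloud(
    model: LinearNeuronModel,
    spec: EnsembleSpec,
    levels: tuple = (1, 2, 4, 8, 32, 64),
) -> EnsembleResult:
    """Sampled (dv, dw) state differences with discriminability isoline levels.

    Only meaningful for the two-variable GIF (the IF state difference is a
    scalar); use the scalar ensemble statistics for IF models instead.
    """
    if model.dim != 2:
        raise ValueError("state-difference clouds require a GIF model; IF differences are 1-D")
    result = mc_mean_discriminability(model, spec, keep_values=True, keep_cloud=True)
    result.levels = levels
    return result


def isoline(model: LinearNeuronModel, level: float, n_points: int = 200) -> np.ndarray:
    """Points of the constant-discriminability ellipse ``sd' W sd = level``.

    A level of 0 degenerates to the origin (the quadratic form is positive
    definite for stable GIF models).
    """
    if model.dim != 2:
        raise ValueError("isolines are defined for GIF models")
    if level < 0:
        raise ValueError("level must be >= 0")
    if level == 0.0:
        return np.zeros((1, 2))
    W = quadratic_form_matrix(model)
    L = np.linalg.cholesky(W)
    theta = np.linspace(0.0, 2.0 * math.pi, n_points)
    circle = math.sqrt(level) * np.stack([np.cos(theta), np.sin(theta)])
    return np.linalg.solve(L.T, circle).T
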