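"""Shared fixtures: canonical models and an independent ODE oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hdexc import gif_model, if_model


@pytest.fixture
def canonical_gif():
    """GIF with eigenvalues -1 +/- 2i (unit decay, intrinsic frequency 2)."""
    return gif_model(1.0, 2.0)


@pytest.fixture
def canonical_if():
    """IF with unit decay rate."""
    return if_model(1.0)


def ode_evolve(model, x0, t):
    """Independent free-evolution oracle: high-accuracy ODE integration."""
    x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(
        lambda _, x: model.A @ x,
        (0.0, t),
        x0,
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
    )
    return sol.y[:, -1]
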