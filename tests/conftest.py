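"""Shared fixtures and independent oracles for the test-suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from larvenet import ModelParameters, ParameterWarning, load_codling_moth_table
from larvenet.synthetic import generate_parameter_ensemble

#: Biologically plausible draw ranges used by the property suites: rates
#: bracket the reference set by roughly a factor of three either way.
DRAW_RANGES = {
    "theta": (0.1, 0.5),
    "alpha": (0.1, 0.6),
    "eta": (10.0, 100.0),
    "beta": (0.05, 0.5),
    "gamma": (0.3, 2.0),
    "kappa": (0.1, 0.6),
    "mu": (0.02, 0.3),
    "delta": (0.01, 0.1),
    "en0": (0.05, 0.5),
    "b": (10.0, 20.0),
}


def draw_parameter_sets(n: int, seed: int) -> list[ModelParameters]:
    """Seeded uniform draws over DRAW_RANGES (start-offset warnings muted)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ParameterWarning)
        return generate_parameter_ensemble(DRAW_RANGES, n=n, seed=seed)


def dense_grid_stopping_oracle(
    params: ModelParameters, horizon: float, step: float = 1e-4
) -> tuple[float | None, int]:
    """Brute-force stopping time: dense evaluation of the net-energy
    polynomial with secant refinement inside the bracketing cell.

    The energy expression is written out inline so the oracle shares no
    code path with the package's ``net_energy``/``find_stopping_time``.
    Returns (root or None, number of sign changes on the grid).
    """
    p = params
    mb = p.mu * p.beta
    g = p.gamma
    t = np.arange(0.0, horizon + step, step)
    en = (
        mb * t / g**2
        - (mb / g - p.kappa) * t**2 / 2.0
        + mb * np.exp(-g * t) / g**3
        - p.delta * t**3 / 3.0
        + p.en0
        - mb / g**3
    )
    signs = np.sign(en)
    changes = int(np.count_nonzero(np.diff(signs[signs != 0]) != 0))
    below = np.nonzero(en <= 0.0)[0]
    below = below[below > 0]
    if below.size == 0:
        return None, changes
    i = int(below[0])
    # secant within the 1e-4-wide cell; curvature error is O(step^2)
    t0, t1, e0, e1 = t[i - 1], t[i], en[i - 1], en[i]
    root = t0 + step * e0 / (e0 - e1) if e1 != e0 else t1
    return float(root), changes


@pytest.fixture(scope="session")
def ref_params() -> ModelParameters:
    """The packaged reference parameter set (worked-example captions +
    development time from the packaged consumption table)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def codling_table():
    return load_codling_moth_table()
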