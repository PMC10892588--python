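"""Seeded synthetic data with the statistical structure the fitters assume.

Consumption tables follow the quadratic-in-time cumulative herbivory
curve; ITC time courses follow the saturating-slope exposure curve.  Both
carry multiplicative lognormal noise — the natural error model for
strictly positive measurements — applied as value·exp(σZ), Z ~ N(0, 1).
The factor has median one and mean exp(σ²/2); no bias correction is
applied, so σ = 0 reproduces the model values exactly.

All generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import ConsumptionTable
from .model import herbivory, itc_concentration
from .parameters import PARAM_KEYS, ModelParameters

__all__ = [
    "NoiseSpec",
    "generate_consumption_data",
    "generate_itc_data",
    "generate_parameter_ensemble",
]

#: Default per-instar durations (days): the packaged codling-moth table.
DEFAULT_DURATIONS = (3.54, 3.27, 3.27, 4.5)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal noise: value·exp(σZ), Z ~ N(0,1), seeded."""

    sigma: float = 0.05
    seed: int = 0
    kind: str = "lognormal"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind != "lognormal":
            raise ValueError(f"unsupported noise kind {self.kind!r}")

    def factors(self, n: int) -> np.ndarray:
        if self.sigma == 0.0:
            return np.ones(n)
        rng = np.random.default_rng(self.seed)
        return np.exp(self.sigma * rng.standard_normal(n))


def generate_consumption_data(
    theta: float,
    durations=DEFAULT_DURATIONS,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
) -> ConsumptionTable:
    """Synthetic per-instar cumulative consumption table.

    Mean consumption at each instar end is θt²/2 at the running-sum times;
    lognormal noise is applied per instar.  Because the table records a
    running total, noised values are repaired to be strictly increasing
    by a cumulative maximum (plus a negligible relative bump on exact
    ties).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    dur = np.asarray(durations, dtype=float)
    if dur.size == 0 or np.any(dur <= 0):
        raise ValueError("durations must be positive")
    times = np.cumsum(dur)
    b = float(times[-1])
    mean = np.asarray(herbivory(times, theta, b), dtype=float)
    values = mean * noise.factors(times.size)
    values = np.maximum.accumulate(values)
    for i in range(1, values.size):  # strictness repair on ties
        if values[i] <= values[i - 1]:
            values[i] = values[i - 1] * (1.0 + 1e-9)
    return ConsumptionTable(np.arange(1, dur.size + 1), dur, values)


def generate_itc_data(
    beta: float,
    gamma: float,
    times,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
) -> pd.DataFrame:
    """Synthetic ITC time course as a ``t_days,value`` table.

    Mean concentration follows the saturating-slope exposure curve
    I(t) = (β/γ²)(γt − 1 + e^{−γt}); multiplicative lognormal noise per
    sample, seeded.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(t <= 0):
        raise ValueError("times must be positive")
    mean = np.asarray(itc_concentration(t, beta, gamma), dtype=float)
    return pd.DataFrame({"t_days": t, "value": mean * noise.factors(t.size)})


def generate_parameter_ensemble(
    ranges: dict[str, tuple[float, float]],
    n: int,
    seed: int,
    base: ModelParameters | None = None,
) -> list[ModelParameters]:
    """Draw n parameter sets uniformly within per-parameter ranges.

    Parameters absent from ``ranges`` stay at their value in ``base``
    (the reference set by default).  Every draw passes ModelParameters
    validation.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    unknown = set(ranges) - set(PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter(s) in ranges: {sorted(unknown)}")
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"range for {name} has high < low")
    base = base or ModelParameters()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
        out.append(base.replace(**draws))
    return out
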