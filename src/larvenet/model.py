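"""Closed-form state solutions and the numerical cross-check integrator.

Every state of the model solves a first-order linear non-autonomous ODE
with a ramp forcing term, so all solutions are available in closed form:

* herbivory        H' = θt            →  H = θt²/2   (zero beyond b)
* GLS ingestion    G' = αt            →  G = αt²/2
* free gut GLS     F' = αt − ηF       →  F = (α/η²)(ηt − 1 + e^{−ηt})
* ITC exposure     I' = βt − γI       →  I = (β/γ²)(γt − 1 + e^{−γt})
* net energy       EN' = κt − μI − δt²
                   →  EN = μβt/γ² − (μβ/γ−κ)t²/2 + μβe^{−γt}/γ³
                         − δt³/3 + EN0 − μβ/γ³

:func:`integrate_model` integrates the coupled system numerically and is
used throughout the test-suite as an independent check on the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import ModelParameters

__all__ = [
    "herbivory",
    "gls_ingestion",
    "itc_concentration",
    "net_energy",
    "net_energy_rate",
    "ramp_relaxation",
    "TimeGrid",
    "Trajectory",
    "evaluate_closed_forms",
    "integrate_model",
]

STATE_LABELS = ("H", "G", "F", "I", "EN")

#: Grids may not extend past this multiple of the development time b.
MAX_HORIZON_FACTOR = 10.0


def _check_times(t: np.ndarray | float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def ramp_relaxation(t, rate: float, clearance: float):
    """Solution of ``x' = rate·t − clearance·x`` with ``x(0) = 0``.

    Equals ``(rate/clearance²)(clearance·t − 1 + e^{−clearance·t})`` for
    positive clearance and degrades continuously to the ramp integral
    ``rate·t²/2`` as clearance → 0.  This is the shared functional form of
    the ITC concentration and the free-GLS content.

    For ``clearance·t < 1e−4`` the truncated series
    ``(rate t²/2)(1 − z/3 + z²/12 − z³/60)``, z = clearance·t, is used to
    avoid catastrophic cancellation between ``clearance·t`` and
    ``e^{−clearance·t} − 1``.
    """
    t = _check_times(t)
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if clearance < 0:
        raise ValueError("clearance must be non-negative")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    z = clearance * t
    out = np.empty_like(t)
    small = z < 1e-4
    zs = z[small]
    out[small] = 0.5 * rate * t[small] ** 2 * (1 - zs / 3 + zs**2 / 12 - zs**3 / 60)
    if clearance > 0:
        zl = z[~small]
        out[~small] = rate / clearance**2 * (zl - 1 + np.exp(-zl))
    return float(out[0]) if scalar else out


def herbivory(t, theta: float, b: float):
    """Cumulative leaf consumption H(t) in mg.

    ``θt²/2`` during development (0 ≤ t ≤ b) and 0 after development ends
    (herbivory stops at t = b); strictly increasing on (0, b] when θ > 0.
    """
    t = _check_times(t)
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if b <= 0:
        raise ValueError("b must be strictly positive")
    return np.where(t <= b, 0.5 * theta * np.square(t), 0.0)[()]


def gls_ingestion(t, alpha: float, b: float):
    """Cumulative glucosinolate ingestion G(t) = αt²/2 on [0, b], 0 beyond.

    Ingestion tracks herbivory exactly: ``G(t)/H(t) = α/θ`` at all times,
    because a chewing larva takes up leaf GLS in proportion to the tissue
    it consumes.
    """
    t = _check_times(t)
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if b <= 0:
        raise ValueError("b must be strictly positive")
    return np.where(t <= b, 0.5 * alpha * np.square(t), 0.0)[()]


def itc_concentration(t, beta: float, gamma: float):
    """Gut isothiocyanate concentration I(t).

    ``(β/γ²)(γt − 1 + e^{−γt})`` — formation from hydrolysed GLS at rate
    βt, first-order clearance at rate γ.  Strictly increasing for t > 0
    whenever β > 0 (``I' = (β/γ)(1 − e^{−γt}) > 0``), concave-up early and
    asymptotically linear with slope β/γ.  γ = 0 returns the continuous
    limit βt²/2.
    """
    return ramp_relaxation(t, beta, gamma)


def net_energy(t, params: ModelParameters):
    """Net energy EN(t): cumulative benefit minus toxin and foraging costs.

    EN(0) = EN0 exactly; the curve is unimodal — monotonically increasing
    first, decreasing later — whenever costs are present (μβ > 0 or δ > 0).
    """
    t = _check_times(t)
    p = params
    mb = p.mu * p.beta
    if mb == 0.0:
        # no toxin cost: gamma never enters
        return (p.en0 + 0.5 * p.kappa * np.square(t) - p.delta * t**3 / 3.0)[()]
    g = p.gamma
    if g <= 0:
        raise ValueError("gamma must be strictly positive when mu*beta > 0")
    return (
        mb * t / g**2
        - (mb / g - p.kappa) * np.square(t) / 2.0
        + mb * np.exp(-g * t) / g**3
        - p.delta * t**3 / 3.0
        + p.en0
        - mb / g**3
    )[()]


def net_energy_rate(t, params: ModelParameters):
    """Instantaneous net-energy balance EN'(t) = κt − μ·I(t) − δt².

    The benefit rate grows linearly while the toxin cost μI and foraging
    cost δt² eventually dominate, so the rate crosses zero at most once.
    """
    t = _check_times(t)
    p = params
    return (p.kappa * t - p.mu * itc_concentration(t, p.beta, p.gamma) - p.delta * np.square(t))[()]


@dataclass(frozen=True)
class TimeGrid:
    """A strictly increasing grid of non-negative times, in days."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if t[0] < 0:
            raise ValueError("times must start at or after 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "TimeGrid":
        if step <= 0:
            raise ValueError("step must be positive")
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        times = start + step * np.arange(n)
        times[-1] = min(times[-1], stop)  # rounding must not overshoot stop
        return cls(times)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Trajectory:
    """Named state series (subset of H, G, F, I, EN) on a common time grid."""

    grid: TimeGrid
    series: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, values in self.series.items():
            if label not in STATE_LABELS:
                raise ValueError(f"unknown state label {label!r}; allowed: {STATE_LABELS}")
            values = np.asarray(values, dtype=float)
            if values.shape != self.grid.times.shape:
                raise ValueError(f"series {label!r} does not align with the time grid")
            self.series[label] = values
        for label in ("H", "G", "I"):
            if label in self.series and np.any(self.series[label] < -1e-12):
                raise ValueError(f"series {label!r} must be non-negative")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.series[label]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with a ``t`` column followed by the state columns."""
        data: dict[str, np.ndarray] = {"t": self.grid.times}
        for label in STATE_LABELS:
            if label in self.series:
                data[label] = self.series[label]
        return pd.DataFrame(data)


def evaluate_closed_forms(
    params: ModelParameters, grid: TimeGrid, outputs: tuple[str, ...] = STATE_LABELS
) -> Trajectory:
    """Evaluate the closed-form solutions for the requested states on a grid."""
    t = grid.times
    fns = {
        "H": lambda: herbivory(t, params.theta, params.b),
        "G": lambda: gls_ingestion(t, params.alpha, params.b),
        "F": lambda: ramp_relaxation(t, params.alpha, params.eta),
        "I": lambda: itc_concentration(t, params.beta, params.gamma),
        "EN": lambda: net_energy(t, params),
    }
    return Trajectory(grid, {label: np.asarray(fns[label]()) for label in outputs})


def integrate_model(
    params: ModelParameters,
    grid: TimeGrid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Numerically integrate the coupled five-state system.

    Integrates H' = θt, G' = αt, F' = αt − ηF, I' = βt − γI,
    EN' = κt − μI − δt² from (0, 0, 0, 0, EN0) with an adaptive
    stiffness-switching stepper (the free-GLS balance is stiff whenever
    η ≫ 1/b) and samples the solution on ``grid``.  Herbivory and
    ingestion forcing switch off beyond t = b.

    Serves as the independent numerical cross-check of the closed forms:
    on grids within [0, b] the two agree to better than 1e−6 at the
    default tolerances.
    """
    t = grid.times
    p = params
    if t[-1] > MAX_HORIZON_FACTOR * p.b:
        raise ValueError(
            f"grid extends to {t[-1]:g} days, beyond {MAX_HORIZON_FACTOR:g}*b = "
            f"{MAX_HORIZON_FACTOR * p.b:g}; refusing runaway horizon"
        )

    def rhs(tt: float, y: np.ndarray) -> list[float]:
        feeding = tt <= p.b
        itc = y[3]
        return [
            p.theta * tt if feeding else 0.0,
            p.alpha * tt if feeding else 0.0,
            p.alpha * tt - p.eta * y[2],
            p.beta * tt - p.gamma * itc,
            p.kappa * tt - p.mu * itc - p.delta * tt**2,
        ]

    y0 = [0.0, 0.0, 0.0, 0.0, p.en0]
    if t[-1] == 0.0:  # degenerate single-point grid at the origin
        return Trajectory(grid, {k: np.full_like(t, v) for k, v in zip(STATE_LABELS, y0)})
    sol = solve_ivp(
        rhs, (0.0, float(t[-1])), y0, t_eval=t, method=method, rtol=rtol, atol=atol
    )
    if not sol.success:  # pragma: no cover - DOP853 does not fail on linear systems
        raise RuntimeError(f"integration failed: {sol.message}")
    series: Mapping[str, np.ndarray] = dict(zip(STATE_LABELS, sol.y))
    return Trajectory(grid, {k: np.maximum(v, 0.0) if k in ("H", "G", "I") else v
                             for k, v in series.items()})
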