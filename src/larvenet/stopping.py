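"""Herbivory stopping time T and survival classification.

Under optimal foraging theory a larva feeds only while its net energy is
positive: once EN(t) returns to zero — at the stopping time T — further
feeding would drive it negative, so herbivory ends.  T below the
development time b means the larva starves before completing its final
instar.

Two routes to T are provided:

* :func:`find_stopping_time` brackets the unique zero crossing of the
  exact closed form EN(t) on a coarse grid and refines it with a
  safeguarded bracketed root finder (Brent).
* :func:`approx_stopping_time` drops the decaying exponential e^{−γT} and
  the small offset EN0 − μβ/γ³ from EN, divides by T and solves the
  remaining quadratic

      (δ/3)T² + ((μβ/γ − κ)/2)T − μβ/γ² = 0

  for its positive root.  The approximation is good whenever e^{−γT} is
  negligible at the root and the starting offset is small relative to the
  energy peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import net_energy
from .parameters import ModelParameters

__all__ = [
    "StoppingResult",
    "find_stopping_time",
    "approx_stopping_time",
    "classify_survival",
    "sweep_parameters",
    "HORIZON_FACTOR",
]

#: Default search horizon, as a multiple of the development time b.
#: A stopping time beyond 10·b is biologically indistinguishable from
#: survival.
HORIZON_FACTOR = 10.0

DIES_EARLY = "dies_early"
SURVIVES = "survives"


@dataclass(frozen=True)
class StoppingResult:
    """Outcome of a stopping-time search.

    Attributes
    ----------
    T : float or None
        Stopping time in days; ``None`` when EN stays positive on the
        whole search horizon.
    method : str
        ``"root_numeric"`` (bracketed root of the exact EN) or
        ``"root_approx"`` (quadratic approximation).
    residual : float or None
        |EN(T)| at the reported root (None when T is None).
    survived : bool or None
        ``T >= b`` (survival), ``None`` when undecidable — i.e. no root
        found but the horizon did not reach b.
    horizon : float
        Search upper bound used, days.
    degenerate : bool
        True for the flagged EN0 = 0 edge case in which net energy is
        negative immediately after t = 0 (reported as T = 0).
    """

    T: float | None
    method: str
    residual: float | None
    survived: bool | None
    horizon: float
    degenerate: bool = False


def find_stopping_time(
    params: ModelParameters,
    horizon: float | None = None,
    n_coarse: int = 10_000,
) -> StoppingResult:
    """Locate the zero crossing of net energy on (0, horizon].

    A coarse grid of ``n_coarse`` points brackets the sign change of the
    exact closed form EN(t); Brent's method refines the bracket until
    |EN(T)| ≤ 1e−9·max(1, EN0).  Because EN is unimodal (rising then
    falling) whenever costs are present, the crossing is unique and the
    coarse grid cannot skip it.

    Returns a result with ``T=None`` when EN never reaches zero on the
    horizon (e.g. with μ = δ = 0 there are no costs and EN grows without
    bound).
    """
    if horizon is None:
        horizon = HORIZON_FACTOR * params.b
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    en = lambda t: net_energy(t, params)

    if params.en0 == 0.0:
        # EN(0) = 0 exactly; the leading small-t behaviour EN ~ kappa*t^2/2
        # decides whether the energy rises or is immediately negative
        # (evaluating EN at tiny t is dominated by cancellation noise).
        if params.kappa == 0.0:
            if params.mu * params.beta > 0 or params.delta > 0:
                return StoppingResult(
                    T=0.0, method="root_numeric", residual=0.0,
                    survived=False, horizon=horizon, degenerate=True,
                )
            # no benefit, no costs: EN identically zero, never depleted
            return StoppingResult(
                T=None, method="root_numeric", residual=None,
                survived=True if horizon >= params.b else None, horizon=horizon,
            )

    ts = np.linspace(0.0, horizon, n_coarse)
    values = np.asarray(en(ts))
    negative = np.nonzero(values <= 0.0)[0]
    # index 0 is EN(0) = EN0 >= 0; a nonpositive value later brackets the root
    negative = negative[negative > 0]
    if negative.size == 0:
        return StoppingResult(
            T=None, method="root_numeric", residual=None,
            survived=True if horizon >= params.b else None,
            horizon=horizon,
        )
    i = int(negative[0])
    if values[i] == 0.0:
        root = float(ts[i])
    else:
        root = float(brentq(en, ts[i - 1], ts[i], xtol=1e-13, rtol=8.9e-16))
    residual = abs(en(root))
    return StoppingResult(
        T=root, method="root_numeric", residual=residual,
        survived=root >= params.b, horizon=horizon,
    )


def _approx_energy(t: float, params: ModelParameters) -> float:
    """EN with the exponential term and starting offset dropped (the
    polynomial the quadratic root must annihilate after division by T)."""
    p = params
    mb = p.mu * p.beta
    g = p.gamma
    return mb * t / g**2 - (mb / g - p.kappa) * t**2 / 2.0 - p.delta * t**3 / 3.0


def approx_stopping_time(params: ModelParameters) -> float | None:
    """Analytic approximation of the stopping time.

    Solves ``(δ/3)T² + ((μβ/γ − κ)/2)T − μβ/γ² = 0`` for its positive
    root, using the numerically stable branch of the quadratic formula.
    The constant term is ≤ 0, so whenever δ > 0 and μβ > 0 there is
    exactly one positive root regardless of the sign of κ − μβ/γ.

    Returns ``None`` when no positive root exists (for instance δ = 0
    with benefit rate κ exceeding the asymptotic toxin-cost rate μβ/γ:
    the approximate energy then grows forever).  A finite result is
    accepted only after checking that it annihilates the approximated
    energy polynomial to ≤ 1e−9 (relative to its largest term).
    """
    p = params
    mb = p.mu * p.beta
    g = p.gamma
    a = p.delta / 3.0
    lin = (mb / g - p.kappa) / 2.0
    const = -mb / g**2

    if a == 0.0:
        if lin > 0.0:
            root = -const / lin
        else:
            return None  # approximate energy never returns to zero
        if root <= 0.0:
            return None
    else:
        disc = lin * lin - 4.0 * a * const  # >= lin^2 since const <= 0
        s = math.sqrt(disc)
        if const == 0.0:
            root = -lin / a if lin < 0.0 else None
            if root is None:
                return None
        elif lin <= 0.0:
            root = (-lin + s) / (2.0 * a)
        else:
            root = -2.0 * const / (lin + s)

    # accept only if the root actually annihilates the approximated energy
    scale = max(1.0, abs(mb * root / g**2), abs(lin * root**2), abs(a * root**3))
    residual = abs(_approx_energy(root, p))
    if residual > 1e-9 * scale:  # pragma: no cover - defensive, roots are exact
        raise ArithmeticError(
            f"approximate stopping time failed its residual check: |E~(T)|={residual:g}"
        )
    return float(root)


def classify_survival(T: float | None, b: float) -> str:
    """Survival verdict: ``dies_early`` iff a finite T precedes b.

    T = b counts as survival: the larva stops feeding exactly when
    development completes.  T = None (energy never depleted) is survival.
    """
    if b <= 0:
        raise ValueError("b must be strictly positive")
    if T is not None and T < b:
        return DIES_EARLY
    return SURVIVES


SWEEP_AXES = ("kappa", "mu", "delta", "beta", "gamma", "en0", "theta", "alpha", "eta")


def sweep_parameters(
    base: ModelParameters,
    axis: str,
    values,
    horizon: float | None = None,
) -> pd.DataFrame:
    """Recompute T and the survival verdict along one parameter axis.

    Returns a DataFrame with columns ``axis_value, T, residual, survived``
    (T is NaN where energy never reaches zero).  Reproduces the
    early-versus-late depletion contrast: raising the benefit constant κ
    delays the stopping time, raising the cost constants μ, β or δ brings
    it forward.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"invalid sweep axis {axis!r}; choose one of {SWEEP_AXES}")
    rows = []
    for v in values:
        res = find_stopping_time(base.replace(**{axis: float(v)}), horizon=horizon)
        rows.append(
            {
                "axis_value": float(v),
                "T": math.nan if res.T is None else res.T,
                "residual": math.nan if res.residual is None else res.residual,
                "survived": res.survived,
            }
        )
    return pd.DataFrame(rows, columns=["axis_value", "T", "residual", "survived"])
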