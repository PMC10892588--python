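"""Model parameters for the larval net-energy budget.

The model tracks a leaf-chewing larva on a glucosinolate-defended host
plant through five states: cumulative herbivory ``H`` (mg leaf tissue),
cumulative glucosinolate (GLS) ingestion ``G``, free GLS in the gut ``F``,
isothiocyanate (ITC) concentration ``I``, and net energy ``EN``.  All rate
constants below parameterise non-autonomous linear ODEs whose closed-form
solutions live in :mod:`larvenet.model`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "ParameterWarning",
    "REFERENCE_PARAMS",
    "load_parameters",
]

#: Field names accepted in parameter config files, in canonical order.
PARAM_KEYS = (
    "theta", "alpha", "eta", "beta", "gamma", "kappa", "mu", "delta", "en0", "b",
)


class ParameterWarning(UserWarning):
    """Non-fatal inconsistency in a parameter set (model still evaluable)."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and initial conditions of the net-energy model.

    Parameters
    ----------
    theta : float
        Herbivory growth-rate constant, mg·day⁻².  The herbivory *rate*
        is ``θ·t``, so cumulative consumption is ``θt²/2``.
    alpha : float
        GLS ingestion growth-rate constant, toxin-mass·day⁻².  Ingestion
        is proportional to herbivory with ratio ``α/θ``.
    eta : float
        Degradation rate of free gut GLS, day⁻¹.  Must greatly exceed
        ``alpha`` for the quasi-steady-state assumption (``F ≈ 0``) to hold;
        see :func:`larvenet.qss.qss_diagnostic`.
    beta : float
        ITC formation-rate constant, concentration·day⁻².
    gamma : float
        ITC clearance rate (excretion plus glutathione conjugation), day⁻¹.
        Strictly positive: it appears in denominators of the closed forms.
    kappa : float
        Energy-benefit growth constant, energy·day⁻²; the benefit rate is
        ``κ·t``.
    mu : float
        Toxin-cost proportionality constant, energy per unit ITC
        concentration per day.
    delta : float
        Foraging-cost proportionality constant, energy·day⁻³; the cost
        rate is ``δ·t²``.
    en0 : float
        Innate energy at hatching (net energy at t = 0), energy units.
    b : float
        End time of larval development, days.

    Notes
    -----
    Energy and concentration carry arbitrary but internally consistent
    units; only herbivory mass (mg, from the packaged consumption table)
    and time (days) have physical units.

    A :class:`ParameterWarning` is emitted when ``en0 < μβ/γ³``: the net
    energy solution then dips below ``en0 − μβ/γ³ < 0`` arbitrarily close
    to t = 0, which is biologically impossible, so such a set is suspect
    though still evaluable.
    """

    theta: float = 0.3
    alpha: float = 0.4
    eta: float = 40.0
    beta: float = 0.2
    gamma: float = 0.8
    kappa: float = 0.3
    mu: float = 0.1
    delta: float = 0.03
    en0: float = 0.2
    b: float = 14.58

    def __post_init__(self) -> None:
        for name in ("theta", "alpha", "beta", "kappa", "mu", "delta", "en0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.eta <= 0:
            raise ValueError(f"eta must be strictly positive, got {self.eta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be strictly positive, got {self.gamma}")
        if self.b <= 0:
            raise ValueError(f"b must be strictly positive, got {self.b}")
        if self.en0 < self.mu * self.beta / self.gamma**3:
            warnings.warn(
                f"en0={self.en0} < mu*beta/gamma^3={self.mu * self.beta / self.gamma**3:.6g}: "
                "net energy would start below its asymptotic offset, i.e. become negative "
                "immediately after t=0; check parameter consistency",
                ParameterWarning,
                stacklevel=2,
            )

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ModelParameters":
        """Build from a dict with keys drawn from :data:`PARAM_KEYS`.

        Unknown keys are an error; missing keys fall back to the reference
        defaults.
        """
        unknown = set(mapping) - set(PARAM_KEYS)
        if unknown:
            raise ValueError(
                f"unknown parameter key(s) {sorted(unknown)}; allowed: {list(PARAM_KEYS)}"
            )
        return cls(**{k: float(v) for k, v in mapping.items()})


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a parameter set from a YAML or JSON config file.

    The file holds a flat mapping with keys among ``theta, alpha, eta,
    beta, gamma, kappa, mu, delta, en0, b``.  Extension ``.json`` selects
    the JSON parser; anything else is parsed as YAML (a superset of JSON).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of parameter names to numbers")
    return ModelParameters.from_mapping(data)


#: The packaged reference scenario: herbivory/ingestion rates and toxin
#: kinetics from the worked example, development time from the summed
#: per-instar durations of the packaged codling-moth consumption table.
REFERENCE_PARAMS = ModelParameters()
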