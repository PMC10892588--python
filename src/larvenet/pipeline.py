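"""Scenario execution: trajectories, stopping time, sweeps and fit reports.

The pipeline composes the closed forms, the stopping-time search and the
fitters into deterministic, file-producing runs.  CSV/JSON outputs use a
fixed 9-significant-digit float format so identical configurations yield
byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitResult, fit_itc_curve, fit_theta, read_consumption_csv, read_curve_csv
from .model import STATE_LABELS, TimeGrid, Trajectory, evaluate_closed_forms
from .parameters import ModelParameters
from .stopping import StoppingResult, classify_survival, find_stopping_time, sweep_parameters

__all__ = ["ScenarioConfig", "run_scenario", "run_fit", "write_trajectory_csv",
           "EXPOSURE_SCENARIO", "REFERENCE_SCENARIO"]

logger = logging.getLogger("larvenet")

FLOAT_FORMAT = "%.9g"


@dataclass(frozen=True)
class ScenarioConfig:
    """A reproducible simulation request.

    ``t_stop`` may not exceed 10·b (runaway-horizon guard); ``outputs``
    selects which state series are evaluated and written.
    """

    params: ModelParameters = field(default_factory=ModelParameters)
    t_start: float = 0.0
    t_stop: float | None = None  # defaults to b
    t_step: float = 0.01
    outputs: tuple[str, ...] = STATE_LABELS
    sweep: tuple[str, tuple[float, ...]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")
        stop = self.resolved_stop
        if stop > 10.0 * self.params.b:
            raise ValueError("t_stop must not exceed 10*b")
        if self.t_start < 0 or stop <= self.t_start:
            raise ValueError("need 0 <= t_start < t_stop")
        if not self.outputs:
            raise ValueError("outputs must name at least one state series")
        bad = set(self.outputs) - set(STATE_LABELS)
        if bad:
            raise ValueError(f"unknown output series {sorted(bad)}; allowed: {STATE_LABELS}")

    @property
    def resolved_stop(self) -> float:
        return self.params.b if self.t_stop is None else self.t_stop

    def grid(self) -> TimeGrid:
        return TimeGrid.regular(self.t_start, self.resolved_stop, self.t_step)


#: Packaged reference scenarios: the herbivory/ingestion/toxin-exposure
#: curves and the full net-energy run with the worked-example parameters.
EXPOSURE_SCENARIO = ScenarioConfig(outputs=("H", "G", "I"))
REFERENCE_SCENARIO = ScenarioConfig(outputs=("H", "G", "F", "I", "EN"))


def _fmt(value: float) -> float:
    return float(FLOAT_FORMAT % value)


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    """Write ``t,<series...>`` CSV (UTF-8, '.' decimal, 9 sig. digits)."""
    frame = trajectory.to_frame()
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_scenario(
    config: ScenarioConfig, out_dir: str | Path | None = None
) -> tuple[Trajectory, StoppingResult]:
    """Evaluate the closed forms on the grid and locate the stopping time.

    Optionally writes ``trajectory.csv`` (plus ``sweep.csv`` when a sweep
    is configured) and a ``run_report.json`` capturing the resolved
    parameters, T, the survival verdict and the tool version.
    Deterministic for a fixed configuration.
    """
    p = config.params
    if p.en0 < p.mu * p.beta / p.gamma**3:
        logger.info("parameter warning: en0 < mu*beta/gamma^3 for this scenario")
    trajectory = evaluate_closed_forms(p, config.grid(), config.outputs)
    stopping = find_stopping_time(p)
    verdict = classify_survival(stopping.T, p.b)
    logger.info(
        "scenario: T=%s verdict=%s horizon=%g", stopping.T, verdict, stopping.horizon
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trajectory_csv(trajectory, out_dir / "trajectory.csv")
        if config.sweep is not None:
            axis, values = config.sweep
            table = sweep_parameters(p, axis, values)
            table.to_csv(out_dir / "sweep.csv", index=False, float_format=FLOAT_FORMAT)
        report = {
            "version": __version__,
            "params": {k: _fmt(v) for k, v in p.to_dict().items()},
            "grid": {
                "t_start": _fmt(config.t_start),
                "t_stop": _fmt(config.resolved_stop),
                "t_step": _fmt(config.t_step),
            },
            "outputs": list(config.outputs),
            "T": None if stopping.T is None else _fmt(stopping.T),
            "residual": None if stopping.residual is None else _fmt(stopping.residual),
            "survived": stopping.survived,
            "verdict": verdict,
            "horizon": _fmt(stopping.horizon),
            "degenerate": stopping.degenerate,
            "seed": config.seed,
        }
        (out_dir / "run_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return trajectory, stopping


def run_fit(input_path: str | Path, mode: str, out_path: str | Path | None = None) -> FitResult:
    """Fit a data file and optionally write the JSON report.

    ``mode='consumption'`` expects the per-instar dialect
    (``instar,duration_days,cumulative_mg``) and estimates θ;
    ``mode='itc'`` expects ``t_days,value`` and estimates (β, γ).
    """
    if mode == "consumption":
        table = read_consumption_csv(input_path)
        result = fit_theta(table.end_times, table.cumulative_mg)
    elif mode == "itc":
        curve = read_curve_csv(input_path)
        result = fit_itc_curve(curve["t_days"].to_numpy(), curve["value"].to_numpy())
    else:
        raise ValueError(f"unknown fit mode {mode!r}; choose 'consumption' or 'itc'")
    if out_path is not None:
        payload = {"version": __version__, "mode": mode, "input": str(input_path)}
        payload.update(result.to_dict())
        payload["estimates"] = {k: (None if np.isnan(v) else _fmt(v))
                                for k, v in payload["estimates"].items()}
        Path(out_path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return result
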