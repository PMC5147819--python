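"""Run configuration, serialization and the report entry points.

A run is described by a flat YAML config: model-parameter keys at the top
level (missing keys fall back to the baseline defaults and are logged), plus
``mode``, ``duration``, ``seed`` and an optional ``forcing`` list.  The
reports are the equilibrium/time-constant table over transmural pressures
and the simulate-then-summarise pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import yaml

from .analysis import detect_cycles, phase_portrait
from .mechanics import (ConfigurationError, ModelParameters,
                        equilibrium_radius, time_constants)
from .shear_no import classify_stability
from .simulate import ForcingSpec, simulate
from .stretch_ca import predicted_period

logger = logging.getLogger("lymphangion")

__all__ = ["RunConfig", "run_table2", "format_table", "run_simulation",
           "round_sig", "round_dec"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_RUN_KEYS = {"mode", "duration", "seed", "forcing", "output_prefix", "stride"}


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    mode: str = "coupled"
    forcing: tuple = ()
    duration: float = 100.0
    seed: int = 0
    stride: int = 10
    output_prefix: str = "run"

    def to_dict(self) -> dict:
        d = dict(self.parameters.to_dict())
        d.update(mode=self.mode, duration=self.duration, seed=self.seed,
                 stride=self.stride, output_prefix=self.output_prefix,
                 forcing=[f.to_dict() for f in self.forcing])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _PARAM_KEYS - _RUN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        params = ModelParameters.from_dict(
            {k: v for k, v in d.items() if k in _PARAM_KEYS})
        forcing = tuple(ForcingSpec.from_dict(f) for f in d.get("forcing", []))
        return cls(parameters=params,
                   mode=d.get("mode", "coupled"),
                   forcing=forcing,
                   duration=float(d.get("duration", 100.0)),
                   seed=int(d.get("seed", 0)),
                   stride=int(d.get("stride", 10)),
                   output_prefix=str(d.get("output_prefix", "run")))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


def round_sig(x: float, n: int) -> float:
    """Round to ``n`` significant figures, half away from zero (the rounding
    used when quoting values at printed precision)."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = n - 1 - d.adjusted()
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def round_dec(x: float, places: int) -> float:
    """Round to ``places`` decimal places, half away from zero."""
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-places),
                                           rounding=ROUND_HALF_UP))


def run_table2(params: ModelParameters | None = None,
               p_m_values=(100.0, 500.0)) -> list:
    """Equilibrium and time-constant report over transmural pressures.

    For each pressure: equilibrium radius R1, linearized stiffness E1, the
    time constants t_mech, t_Ca, t_NO, t_FNO and the overall shear-NO return
    time t_c = t_mech + t_NO + t_FNO, plus the dilation-phase stability
    verdict.  Infeasible rows are reported with an ``error`` field and the
    run continues.
    """
    params = params or ModelParameters()
    rows = []
    for p_m in p_m_values:
        row = {"p_m": float(p_m)}
        try:
            p = params.replace(p_m=float(p_m))
            eq = equilibrium_radius(p)
            tc = time_constants(eq, p)
            rep = classify_stability(eq.R1, "dilation", eq, p)
            row.update(R1=eq.R1, E1=eq.E1, t_mech=tc.t_mech, t_Ca=tc.t_Ca,
                       t_NO=tc.t_NO, t_FNO=tc.t_FNO, t_c=tc.t_c_no,
                       dilation_stable=rep.b > 0, regime=rep.regime)
        except (ConfigurationError, ValueError) as err:
            row["error"] = str(err)
        rows.append(row)
    return rows


def format_table(rows: list) -> str:
    """Aligned plain-text rendering of :func:`run_table2` output."""
    cols = ["p_m", "R1", "E1", "t_mech", "t_Ca", "t_NO", "t_FNO", "t_c",
            "dilation"]
    lines = ["  ".join(f"{c:>12}" for c in cols)]
    for row in rows:
        if "error" in row:
            lines.append(f"{row['p_m']:>12g}  [infeasible: {row['error']}]")
            continue
        vals = [f"{row['p_m']:>12g}",
                f"{round_sig(row['R1'], 3):>12.3e}",
                f"{round_sig(row['E1'], 3):>12.3e}",
                f"{round_dec(row['t_mech'], 2):>12.2f}",
                f"{row['t_Ca']:>12.2f}",
                f"{row['t_NO']:>12.2f}",
                f"{round_dec(row['t_FNO'], 2):>12.2f}",
                f"{round_dec(row['t_c'], 2):>12.2f}",
                f"{'stable' if row['dilation_stable'] else 'unstable':>12}"]
        lines.append("  ".join(vals))
    return "\n".join(lines)


def run_simulation(config: RunConfig, out_dir=".") -> dict:
    """Execute a configured run and write trajectory, events and summary.

    Writes ``<prefix>.tsv``, ``<prefix>.events.tsv``, ``<prefix>.json``
    (trajectory sidecar) and ``<prefix>.summary.json``; returns the summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = str(out / config.output_prefix)
    traj = simulate(config.parameters, config.mode, config.forcing,
                    duration=config.duration, seed=config.seed,
                    stride=config.stride)
    traj.save(prefix)
    stats = detect_cycles(traj, "radius")
    p = config.parameters
    eq = equilibrium_radius(p)
    tc = time_constants(eq, p)
    rep = classify_stability(eq.R1, "dilation", eq, p)
    if config.mode == "no_only":
        t_c, sigma = tc.t_c_no, traj.meta["sigma_no_effective"]
    else:
        t_c, sigma = tc.t_c_ca, traj.meta["sigma_ca_effective"]
    predicted = float("nan")
    if stats.defined and sigma > 0 and stats.C_max > sigma:
        predicted = predicted_period(t_c, stats.C_max, sigma)
    x, y = phase_portrait(traj, ("R", "dRdt"))
    import numpy as np
    np.savetxt(f"{prefix}.portrait.tsv", np.column_stack([x, y]),
               delimiter="\t", header="R\tdRdt", comments="")
    summary = {
        "mode": config.mode,
        "seed": config.seed,
        "n_cycles": int(stats.n_cycles),
        "mean_period": None if not stats.defined else stats.mean_period,
        "period_cv": None if not stats.defined else stats.period_cv,
        "mean_amplitude": None if not stats.defined else float(stats.amplitudes.mean()),
        "C_max": None if not stats.defined else stats.C_max,
        "predicted_period": None if predicted != predicted else predicted,
        "R1": eq.R1,
        "E1": eq.E1,
        "dilation_regime": rep.regime,
    }
    with open(f"{prefix}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    logger.info("run written to %s.*", prefix)
    return summary
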