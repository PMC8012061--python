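"""File formats, configuration, and pipeline orchestration.

Traces travel as 2-column delimited text with a header naming the units
(``time_s,cm_fF`` for capacitance, ``time_s,i_pA`` for amperometry), with an
optional JSON sidecar of ground-truth generator parameters.  Results are
JSON with units in the field names; configuration is YAML.  Every output
records the seed, a hash of the configuration, and the software version, so
a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import CapacitanceTrace, analyze_flash, readouts
from .spikes import AmperometryTrace
from .stereology import StereologyInput, analyze_stereology

__all__ = ["read_trace", "write_trace", "RunConfig", "run_pipeline", "to_jsonable"]

log = logging.getLogger("poolkin")

_COLUMNS = {"capacitance": ("time_s", "cm_fF"), "amperometry": ("time_s", "i_pA")}


def read_trace(path, kind: Literal["capacitance", "amperometry"]):
    """Read a delimited-text trace, validating columns, units and time axis."""
    tcol, vcol = _COLUMNS[kind]
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (tcol, vcol):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r} (found {list(df.columns)}); "
                f"a {kind} trace needs columns {tcol!r}, {vcol!r}")
    t = df[tcol].to_numpy(dtype=float)
    v = df[vcol].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if kind == "capacitance":
        return CapacitanceTrace(t=t, cm=v)
    dt = np.diff(t)
    if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: amperometry requires uniform sampling")
    fs = 1.0 / dt[0] if t.size > 1 else 1.0
    return AmperometryTrace(t=t, i=v, fs=fs)


def write_trace(trace, path, sidecar: dict | None = None) -> None:
    """Write a trace as 2-column delimited text, optionally with a JSON
    sidecar (``<path>.json``) of ground-truth parameters."""
    path = Path(path)
    if isinstance(trace, CapacitanceTrace):
        df = pd.DataFrame({"time_s": trace.t, "cm_fF": trace.cm})
    else:
        df = pd.DataFrame({"time_s": trace.t, "i_pA": trace.i})
    # %.17g preserves doubles bit-exactly through the text round trip
    df.to_csv(path, index=False, float_format="%.17g")
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(to_jsonable(sidecar), indent=2, sort_keys=True))


def to_jsonable(obj):
    """Recursively convert dataclasses/arrays to JSON-serialisable values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    stages: list = field(default_factory=lambda: ["simulate", "fit"])
    seed: int = 0
    out_dir: str = "poolkin_out"
    trace_path: str | None = None  # existing trace to fit instead of simulating
    model: str = "auto"
    srp_upper: float = 1.0
    occupancy: float = 0.9
    stereology: dict | None = None  # field name -> value, per genotype

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        # the output location does not affect the computation
        fields = {k: v for k, v in dataclasses.asdict(self).items()
                  if k != "out_dir"}
        blob = json.dumps(to_jsonable(fields), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {"seed": cfg.seed, "config_sha256": cfg.digest(),
            "poolkin_version": __version__}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages and write JSON results.

    Stage failures abort the run; results of completed stages are preserved
    on disk and the report marks the failed stage.
    """
    from .synthgen import NoiseSpec, TimeGrid, generate_flash_trace
    from .kinetics import FlashKinetics

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(cfg), "stages": {}}

    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[poolkin:%(stage)s] %(message)s"))

    trace = None
    for stage in cfg.stages:
        log.info("stage %s start", stage)
        try:
            if stage == "simulate":
                kin = FlashKinetics(A1=50.0, tau1=0.015, A2=30.0, tau2=0.3, A3=20.0)
                trace = generate_flash_trace(kin, TimeGrid(),
                                             NoiseSpec(seed=cfg.seed))
                write_trace(trace, out_dir / "trace.csv",
                            sidecar={"truth": kin, **_provenance(cfg)})
                report["stages"]["simulate"] = {"truth": to_jsonable(kin)}
            elif stage == "fit":
                if trace is None:
                    if cfg.trace_path is None:
                        raise ValueError("fit stage needs a simulated or loaded trace")
                    trace = read_trace(cfg.trace_path, "capacitance")
                fit = analyze_flash(trace, model=cfg.model, srp_upper=cfg.srp_upper)
                result = {
                    "model_id": fit.model_id,
                    "params": to_jsonable(fit.params),
                    "rss_fF2": fit.rss,
                    "converged": fit.converged,
                    "assignment": to_jsonable(fit.assignment),
                    "readouts_fF": {str(k): v for k, v in readouts(trace).items()},
                }
                report["stages"]["fit"] = result
            elif stage == "stereology":
                if not cfg.stereology:
                    raise ValueError("stereology stage needs input values")
                result = {}
                for name, fields in cfg.stereology.items():
                    res = analyze_stereology(StereologyInput(**fields))
                    result[name] = to_jsonable(res)
                report["stages"]["stereology"] = result
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            report["stages"][stage] = {"error": str(exc)}
            report["failed_stage"] = stage
            _write_report(report, out_dir)
            raise
        log.info("stage %s done", stage)
    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(
        json.dumps(to_jsonable(report), indent=2, sort_keys=True))
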