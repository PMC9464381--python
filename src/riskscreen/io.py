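"""Configuration parsing and tabular serialization shared by the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
import json
from pathlib import Path

import yaml

from . import __version__
from .errors import InvalidParameterError
from .experiment import (
    DEFAULT_CVMR,
    DEFAULT_DP,
    DEFAULT_R,
    DEFAULT_TDR,
    ScenarioGridResult,
)


@dataclass
class RunConfig:
    """Validated run configuration with defaults matching the study grid."""

    dp: tuple = DEFAULT_DP
    cvmr: tuple = DEFAULT_CVMR
    r: tuple = DEFAULT_R
    tdr: tuple = (0.9,)
    n_patients: int = 5000
    reps: int = 100
    seed: int = 0
    sigma_scale: float = 0.01
    ra_mode: str = "with_replacement"
    ra_inner: int = 5
    sensitivity: float = 1.0
    tol: float = 1e-8
    out_dir: str = "results"


_KNOWN = {f.name for f in fields(RunConfig)}


def parse_config(overrides: dict | None = None, config_file=None) -> RunConfig:
    """Merge defaults, an optional YAML file, and explicit overrides.

    All numeric fields are validated against their documented ranges; every
    invalid field is reported, not just the first.
    """
    merged: dict = {}
    if config_file is not None:
        with open(config_file) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise InvalidParameterError("config file must contain a mapping")
        merged.update(loaded)
    merged.update({k: v for k, v in (overrides or {}).items() if v is not None})

    errs = [f"unknown config key {k!r}" for k in merged if k not in _KNOWN]
    cfg = RunConfig(**{k: v for k, v in merged.items() if k in _KNOWN})

    for name in ("dp", "cvmr", "r", "tdr"):
        vals = getattr(cfg, name)
        if isinstance(vals, (int, float)):
            vals = (vals,)
        vals = tuple(float(v) for v in vals)
        setattr(cfg, name, vals)
        if not vals:
            errs.append(f"{name}: list must be non-empty")
    for v in cfg.dp:
        if not (0.0 < v <= 1.0):
            errs.append(f"dp: value {v} outside (0, 1]")
    for v in cfg.cvmr:
        if v < 0.0:
            errs.append(f"cvmr: value {v} must be >= 0")
    for v in cfg.r:
        if not (0.0 <= v < 1.0):
            errs.append(f"r: value {v} outside [0, 1)")
    for v in cfg.tdr:
        if not (0.0 < v < 1.0):
            errs.append(f"tdr: value {v} outside (0, 1)")
    if cfg.n_patients < 1:
        errs.append("n_patients: must be >= 1")
    if cfg.reps < 1:
        errs.append("reps: must be >= 1")
    if cfg.sigma_scale < 0.0:
        errs.append("sigma_scale: must be >= 0")
    if cfg.ra_mode not in ("with_replacement", "without_replacement"):
        errs.append(f"ra_mode: unknown mode {cfg.ra_mode!r}")
    if cfg.ra_inner < 1:
        errs.append("ra_inner: must be >= 1")
    if not (0.0 < cfg.sensitivity <= 1.0):
        errs.append("sensitivity: must be in (0, 1]")
    if cfg.tol <= 0.0:
        errs.append("tol: must be > 0")
    if errs:
        raise InvalidParameterError("; ".join(errs))
    return cfg


def write_grid_results(result: ScenarioGridResult, out_dir) -> dict[str, Path]:
    """Write grid_results.csv, the three marginal CSVs, and manifest.json.

    Column order is deterministic and floats use '.' decimals, so re-runs
    with the same seed are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    table = result.table.sort_values(["tdr_target", "scenario_id"]).reset_index(drop=True)
    lead = ["scenario_id", "tdr_target", "dp", "cvmr", "r", "reps"]
    cols = lead + [c for c in table.columns if c not in lead]
    paths["grid_results"] = out / "grid_results.csv"
    table[cols].to_csv(paths["grid_results"], index=False)

    for param, marg in result.marginals.items():
        p = out / f"marginals_{param}.csv"
        marg.to_csv(p, index=False)
        paths[f"marginals_{param}"] = p

    manifest = {"version": __version__, **result.manifest}
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def write_cohort_results(result, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "strategies": out / "cohort_strategies.csv",
        "quintile_exams": out / "cohort_quintile_exams.csv",
        "quintile_detections": out / "cohort_quintile_detections.csv",
        "manifest": out / "cohort_manifest.json",
    }
    result.strategies.to_csv(paths["strategies"], index=False)
    result.quintile_exams.to_csv(paths["quintile_exams"], index=False)
    result.quintile_detections.to_csv(paths["quintile_detections"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "version": __version__,
                "n_events": result.n_events,
                "n_max_risk_based": result.n_max_risk_based,
                **result.settings,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
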