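"""Run configuration, validation, provenance and report generation.

Configuration is plain JSON with units spelled out in key names (the
source tables mix N/mm, MPa and 1e-15 m^4/Ns); validation cross-checks
values against the shipped reference tables and parametric ranges,
warning (not failing) outside them.  Reports are deterministic CSV/JSON
bundles whose manifest records the seed and a hash of the configuration,
so every artifact is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from .tables import load_parameter_ranges

__all__ = ["RunConfig", "ConfigError", "validate_config", "write_report", "get_logger"]

logger = logging.getLogger("ligmech")


def get_logger(logfile: str | None = None) -> logging.Logger:
    """Logger writing ISO-timestamped records to stderr (and optionally a file)."""
    if not logger.handlers:
        fmt = logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s", "%Y-%m-%dT%H:%M:%S"
        )
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(fmt)
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    if logfile:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logger.handlers[0].formatter)
        logger.addHandler(fh)
    return logger


class ConfigError(ValueError):
    """Hard configuration error (missing file, nonphysical parameter)."""


@dataclass
class RunConfig:
    """Validated run configuration.

    Default parameter values come from the shipped tables; any entry in
    ``overrides`` replaces them (keys like ``Ef_MPa``, ``Em_MPa``,
    ``k0_1e-15_m4_per_Ns``, ``M``, per ligament or global).
    """

    model_kind: str = "frphe"
    block: str = "adjusted"
    seed: int = 0
    n_steps: int = 25
    resolution: int = 1
    drainage: str = "sealed"
    body_mass_kg: float = 80.0
    material_file: str | None = None
    geometry_file: str | None = None
    output_dir: str = "results"
    overrides: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "warnings"}
        return json.dumps(d, sort_keys=True, indent=1)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


_RANGE_KEYS = {
    "Ef_MPa": "Ef_MPa",
    "Em_MPa": "Em_MPa",
    "k0_1e-15_m4_per_Ns": "k0_1e-15_m4_per_Ns",
    "M": "M",
}


def validate_config(cfg: dict | str | Path) -> RunConfig:
    """Validate a configuration mapping or JSON file.

    Hard errors (raised): unknown model kind, non-positive moduli or
    stiffnesses, referenced files that do not exist.  Out-of-range but
    physical values (outside the parametric-analysis table) produce
    warnings collected on the returned config.
    """
    if not isinstance(cfg, dict):
        path = Path(cfg)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        cfg = json.loads(path.read_text())

    known = {f.name for f in RunConfig.__dataclass_fields__.values()} - {"warnings"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    rc = RunConfig(**{k: v for k, v in cfg.items() if k in known})

    if rc.model_kind not in ("spring", "linear", "neohookean", "poro", "frphe"):
        raise ConfigError(f"unknown model kind {rc.model_kind!r}")
    if rc.block not in ("initial", "adjusted"):
        raise ConfigError(f"unknown parameter block {rc.block!r}")
    if rc.drainage not in ("sealed", "free"):
        raise ConfigError(f"drainage must be sealed|free, got {rc.drainage!r}")
    if rc.n_steps < 2:
        raise ConfigError("n_steps must be >= 2")
    if rc.body_mass_kg <= 0:
        raise ConfigError("body mass must be positive")
    for name in ("material_file", "geometry_file"):
        p = getattr(rc, name)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{name} does not exist: {p}")

    ranges = load_parameter_ranges()
    for key, value in rc.overrides.items():
        base_key = key.split(":")[0]  # allow "Ef_MPa:ACL"
        vals = value.values() if isinstance(value, dict) else [value]
        for v in vals:
            if base_key in _RANGE_KEYS or base_key in ("E_MPa", "k_N_per_mm"):
                if v <= 0:
                    raise ConfigError(f"{key} must be positive, got {v}")
            if base_key in _RANGE_KEYS:
                lo, hi = ranges[_RANGE_KEYS[base_key]]
                if not (lo <= v <= hi):
                    rc.warnings.append(
                        f"{key} = {v} outside the parametric range [{lo}, {hi}]"
                    )
    return rc


def write_report(results: dict, outdir: str | Path, config: RunConfig | None = None, plots: bool = False) -> dict:
    """Write a deterministic CSV/JSON bundle and return the manifest.

    ``results`` maps names to pandas DataFrames (written as CSV), dicts /
    scalars (collected into ``summary.json``), or matplotlib figures
    (written as PNG when ``plots``).  Raises on empty input.
    """
    import pandas as pd

    if not results:
        raise ValueError("refusing to write an empty report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": [], "config_digest": None, "seed": None}
    if config is not None:
        manifest["config_digest"] = config.digest()
        manifest["seed"] = config.seed
        (outdir / "config.json").write_text(config.to_json())
        manifest["files"].append("config.json")
    summary = {}
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.csv"
            obj.to_csv(outdir / fname, index=False, float_format="%.10g")
            manifest["files"].append(fname)
        elif hasattr(obj, "savefig"):
            if plots:
                fname = f"{name}.png"
                obj.savefig(outdir / fname, dpi=120)
                manifest["files"].append(fname)
        else:
            summary[name] = obj
    if summary:
        (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1, default=float))
        manifest["files"].append("summary.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
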