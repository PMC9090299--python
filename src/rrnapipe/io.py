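"""Typed CSV round-tripping, YAML configuration and provenance records.

CSV dialect: comma-separated, UTF-8, "." decimal, mandatory header row.
Numbers are written with 12 significant digits so that read(write(x)) is
value-exact for every table the pipeline produces.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import DataError, SchemaError
from .kinetics import RateParameters, RegimeSchedule

#: schema name -> (required columns, numeric columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "timecourse": (
        ("time_h", "species", "probe", "replicate", "value"),
        ("time_h", "value"),
    ),
    "band": (
        (
            "lane",
            "condition",
            "time_h",
            "probe",
            "species",
            "intensity",
            "control_intensity",
        ),
        ("time_h", "intensity", "control_intensity"),
    ),
    "trace": (("position", "a254_percent"), ("position", "a254_percent")),
    "counts": (("group", "category", "count"), ("count",)),
    "spectra": (("protein", "fraction", "count"), ("count",)),
    "annotation": (("protein", "rp_class"), ()),
    "recovery_report": (
        (
            "regime",
            "parameter",
            "truth",
            "mean_estimate",
            "bias",
            "rmse",
            "median_rel_error",
        ),
        ("truth", "mean_estimate", "bias", "rmse", "median_rel_error"),
    ),
}

FLOAT_FORMAT = "%.12g"


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a typed CSV table.

    Raises :class:`SchemaError` for a missing column ("schema mismatch: X"),
    a non-numeric cell ("parse error at row N") or an empty file.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"schema mismatch: unknown schema {schema!r}")
    required, numeric = SCHEMAS[schema]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError("empty table") from None
    if df.empty:
        raise DataError("empty table")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"schema mismatch: {col}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(f"parse error at row {int(bad.idxmax())}")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class PipelineConfig:
    """Run configuration shared by the CLI commands."""

    seed: int = 0
    out_dir: str = "."
    schedule: list = field(default_factory=list)  # [{start_h, end_h, regime}]
    params_by_regime: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)  # forwarded to FitOptions
    detection: dict = field(default_factory=dict)  # forwarded to analyze_profile
    pools: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # named input paths

    def regime_schedule(self) -> RegimeSchedule:
        from .synthetic import default_schedule

        if not self.schedule:
            return default_schedule()
        return RegimeSchedule.from_dicts(self.schedule)

    def rate_params(self) -> dict[str, RateParameters]:
        from .synthetic import default_true_params

        if not self.params_by_regime:
            return default_true_params()
        return {
            r: RateParameters.from_dict(d) for r, d in self.params_by_regime.items()
        }

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "schedule": self.schedule,
            "params_by_regime": self.params_by_regime,
            "design": self.design,
            "noise": self.noise,
            "fit": self.fit,
            "detection": self.detection,
            "pools": self.pools,
            "inputs": self.inputs,
        }


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise DataError("parse error at row 0: config must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"schema mismatch: {sorted(unknown)[0]}")
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def provenance_record(config: PipelineConfig, command: str) -> dict:
    return {
        "tool": "rrnapipe",
        "version": __version__,
        "command": command,
        "seed": config.seed,
        "config_hash": config_hash(config),
    }


def write_provenance(config: PipelineConfig, command: str, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "provenance.json"
    with open(path, "w") as fh:
        json.dump(provenance_record(config, command), fh, indent=2, sort_keys=True)
    return path
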