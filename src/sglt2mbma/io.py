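"""CSV dataset readers/writers, parameter config loading, run manifests.

Three CSV schemas (concentrations, uge, endpoints) carry the summary-level
meta-data; a nested YAML config mirrors the published parameter tables
(one block per drug for PK, shared biomarker and endpoint blocks).  All
files are UTF-8 with '.' decimal points; missing values are empty cells;
treatment-type labels are ASCII-normalized on read.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .parameters import (
    BiomarkerParameters,
    EndpointParameters,
    PKParameters,
    SimulationTruth,
    TreatmentType,
    default_truth,
)

__all__ = ["SCHEMAS", "read_dataset", "write_dataset", "load_parameters",
           "dump_parameters", "RunManifest"]

# required columns and the subset that must be numeric / positive
SCHEMAS: dict[str, dict] = {
    "concentrations": {
        "columns": ["study_id", "drug", "dose_mg", "fed", "time_h",
                    "conc_ng_ml", "n"],
        "numeric": ["dose_mg", "fed", "time_h", "conc_ng_ml", "n"],
        "optional_numeric": [],
    },
    "uge": {
        "columns": ["study_id", "drug", "dose_mg", "n", "uge24_g",
                    "uge24_baseline_g", "fpg_baseline_mg_dl", "population"],
        "numeric": ["dose_mg", "n", "uge24_g", "uge24_baseline_g",
                    "fpg_baseline_mg_dl"],
        "optional_numeric": [],
    },
    "endpoints": {
        "columns": ["study_id", "arm_id", "drug", "treatment_type", "dose_mg",
                    "n", "time_week", "fpg_mg_dl", "hba1c_pct",
                    "fpg_baseline_mg_dl", "hba1c_baseline_pct"],
        "numeric": ["dose_mg", "n", "time_week", "fpg_baseline_mg_dl",
                    "hba1c_baseline_pct"],
        "optional_numeric": ["fpg_mg_dl", "hba1c_pct"],
    },
}


def read_dataset(path, schema: str) -> pd.DataFrame:
    """Read and validate a dataset CSV against one of the three schemas.

    Unknown columns raise a warning, missing required columns a
    :class:`SchemaError`; non-numeric or invalid cells are collected and
    reported together with their 1-based file line numbers.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in spec["columns"]]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}")
        df = df.drop(columns=unknown)

    errors: list[str] = []
    out = df.copy()
    for col in spec["numeric"] + spec["optional_numeric"]:
        optional = col in spec["optional_numeric"]
        vals = []
        for i, cell in enumerate(df[col]):
            line = i + 2  # header is line 1
            cell = cell.strip()
            if cell == "":
                if optional:
                    vals.append(np.nan)
                else:
                    errors.append(f"line {line}: empty value in column {col!r}")
                    vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                errors.append(f"line {line}: non-numeric value {cell!r} "
                              f"in column {col!r}")
                vals.append(np.nan)
        out[col] = vals
    if "n" in out.columns:
        bad = out.index[(out["n"] < 1) | (out["n"] % 1 != 0)]
        errors.extend(f"line {i + 2}: arm size n must be a positive integer"
                      for i in bad)
    if "treatment_type" in out.columns:
        normalized = []
        for i, lab in enumerate(out["treatment_type"]):
            try:
                normalized.append(TreatmentType.parse(lab).value)
            except Exception:
                errors.append(f"line {i + 2}: unknown treatment type {lab!r}")
                normalized.append(lab)
        out["treatment_type"] = normalized
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s):\n  "
                          + "\n  ".join(errors[:50]))
    if "n" in out.columns:
        out["n"] = out["n"].astype(int)
    return out


def write_dataset(df: pd.DataFrame, path, schema: str) -> None:
    """Write a dataset CSV (12-significant-digit round-trip fidelity)."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    cols = [c for c in SCHEMAS[schema]["columns"] if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# parameter config

def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _truth_to_dict(truth: SimulationTruth) -> dict:
    cfg = {
        "pk": {name: {k: v for k, v in asdict(p).items()
                      if k != "drug_name"}
               for name, p in truth.pk.items()},
        "biomarker": asdict(truth.biomarker),
        "endpoints": asdict(truth.endpoints),
    }
    return cfg


def load_parameters(path=None) -> SimulationTruth:
    """Load a SimulationTruth from a nested YAML config.

    Values present in the file override the packaged defaults (the
    published estimates); an empty or absent file yields the defaults
    unchanged.  Structural invariants are validated on construction and a
    violated one raises a :class:`ConfigurationError` naming it.
    """
    cfg = _truth_to_dict(default_truth())
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        _deep_update(cfg, user)
    pk = {name: PKParameters(drug_name=name, **blk)
          for name, blk in cfg["pk"].items()}
    biomarker = BiomarkerParameters(**cfg["biomarker"])
    endpoints = EndpointParameters(**cfg["endpoints"])
    return SimulationTruth(pk=pk, biomarker=biomarker, endpoints=endpoints)


def packaged_default_config() -> str:
    """Text of the packaged default parameter config."""
    return (resources.files("sglt2mbma") / "data" /
            "default_parameters.yaml").read_text(encoding="utf-8")


def dump_parameters(truth: SimulationTruth, path) -> None:
    """Write a truth object as a YAML config readable by load_parameters."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_truth_to_dict(truth), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# reproducibility manifest

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Record of one CLI run: command, seed, config hash, input digests."""

    command: str
    seed: int | None
    config_hash: str | None
    input_digests: dict[str, str]
    package_version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, seed: int | None = None,
               config_path=None, inputs=()) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            seed=seed,
            config_hash=_sha256(config_path) if config_path else None,
            input_digests={str(p): _sha256(p) for p in inputs},
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2),
                              encoding="utf-8")
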