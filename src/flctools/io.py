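"""Shared table/config readers-writers, schema validation and run manifests."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sim import CellCycleModel, EmissionParams, SimulationConfig, SwitchingParams

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "load_table",
    "load_sim_config",
    "write_manifest",
    "check_overwrite",
]

# canonical column schemas: name -> required columns and numeric columns
SCHEMAS = {
    "cells": {
        "required": ["genotype", "time_d", "intensity"],
        "numeric": ["time_d", "intensity"],
    },
    "counts": {
        "required": ["genotype", "cell_id", "count"],
        "numeric": ["cell_id", "count"],
    },
    "qpcr": {
        "required": ["genotype", "time_h", "abundance", "pp2a", "ubc"],
        "numeric": ["time_h", "abundance", "pp2a", "ubc"],
    },
    "qpcr_trend": {
        "required": ["genotype", "time_d", "rel_expr"],
        "numeric": ["time_d", "rel_expr"],
    },
    "markers": {
        "required": ["z", "y", "x", "visibility"],
        "numeric": ["z", "y", "x"],
    },
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def load_table(
    path, schema: str, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Load and validate a CSV table against a named schema.

    ``column_map`` renames source columns to the canonical names first
    (tolerating deposited-file header variants). Raises :class:`SchemaError`
    naming the offending column or row on failure.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; available: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: empty table")
    if column_map:
        df = df.rename(columns=column_map)
    spec = SCHEMAS[schema]
    for col in spec["required"]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in spec["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = int(np.argmax(coerced.isna().to_numpy()))
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at row {bad}")
        df[col] = coerced
    return df


def load_sim_config(path) -> tuple[SimulationConfig, SwitchingParams, EmissionParams, CellCycleModel]:
    """Read simulator configuration from a YAML file.

    Sections ``simulation``, ``switching``, ``emission`` and ``cell_cycle``
    map onto the corresponding parameter objects; missing keys take the
    package defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    config = SimulationConfig(**{
        **raw.get("simulation", {}),
        **(
            {"output_times": tuple(raw["simulation"]["output_times"])}
            if "output_times" in raw.get("simulation", {})
            else {}
        ),
    })
    sw = SwitchingParams(**raw.get("switching", {"p_off": 0.01, "p_on": 0.0005}))
    em = EmissionParams(**raw.get("emission", {"mu_on": 0.0, "sigma_on": 0.5, "mu_off": -1.5, "sigma_off": 0.4}))
    cyc = CellCycleModel(**raw.get("cell_cycle", {}))
    return config, sw, em, cyc


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir, stage: str, inputs: list, params: dict, seed: int | None, status: str = "ok"
) -> Path:
    """Write a JSON run manifest (hashed inputs, parameters, seed, version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "status": status,
        "seed": seed,
        "params": params,
        "inputs": {str(p): _hash_file(Path(p)) for p in inputs if Path(p).exists()},
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def check_overwrite(path, force: bool) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass --force to overwrite")
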