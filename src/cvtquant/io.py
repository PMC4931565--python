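"""CSV/JSON table plumbing with schema checks and lossless round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table", "write_json", "read_json"]

SPOT_SCHEMA = ["spot_id", "channel", "x", "y", "brightest_frame",
               "intensity_brightest", "intensity_integrated", "edge_flag", "coloc_flag"]
PARTICLE_SCHEMA = ["micrograph_id", "particle_id", "x_nm", "y_nm"]
SITE_SCHEMA = ["site_id", "category", "x_nm", "y_nm", "membrane_width_nm"]
TRUTH_SCHEMA = ["spot_id", "cell_id", "channel", "x", "y", "z", "true_molecules"]


class SchemaError(ValueError):
    """A table is missing a required column."""


def read_table(path, schema: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking that every schema column is present."""
    df = pd.read_csv(path, encoding="utf-8")
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def write_table(df: pd.DataFrame, path, schema: list[str] | None = None) -> None:
    """Write a CSV table with full float precision (repr round-trip)."""
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(obj), fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
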