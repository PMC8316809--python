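"""Tidy CSV schemas, deterministic writers and config loading.

All tables travel as plain CSV in fixed column order with a stable
float format, so a pipeline run with a fixed seed is byte-identical
across invocations. Every written table gets a JSON metadata sidecar
(``<name>.meta.json``) carrying the seed, package version and the
generating parameters — never timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a tidy CSV deterministically, with an optional sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    if metadata is not None:
        write_metadata(path, metadata)
    return path


def write_metadata(table_path: str | Path, metadata: dict) -> Path:
    table_path = Path(table_path)
    side = table_path.with_suffix(table_path.suffix + ".meta.json")
    side.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return side


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a tidy CSV, checking that required columns are present."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    return read_table(
        path,
        required=("well_id", "focal", "scenario", "env", "bio_rep",
                  "tech_rep", "day", "density"),
    )


def read_growth(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("well_id", "focal", "scenario", "env", "mu"))


def read_events(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("well_id", "fsc", "fl3", "green"))


def read_photophys(path: str | Path) -> pd.DataFrame:
    return read_table(
        path, required=("well_id", "np_o2_umol_cell_h", "carbon_quota_ugC")
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML key-value config (designs, gates, presets)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
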