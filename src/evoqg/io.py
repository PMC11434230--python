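"""Schema-validated file I/O for the pipeline's tabular formats.

Tracks are TSV (track_id, plate_id, time_s, state); phenotype and fitness
tables are CSV with headers.  One canonical trait order — the six log
transition rates (SF, SB, FS, FB, BS, BF) — is enforced at every boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import STATES, TRAIT_COLUMNS

TRACK_COLUMNS = ("track_id", "plate_id", "time_s", "state")
PHENOTYPE_COLUMNS = ("line_id", "population", "block_id", "T", "H", "D") + TRAIT_COLUMNS
FITNESS_COLUMNS = ("line_id", "fitness")

FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """Raised for malformed input tables, naming the offending row/column."""


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"track_id": str, "plate_id": str})
    _require_columns(df, TRACK_COLUMNS, f"track file {path}")
    bad = ~df["state"].isin(STATES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: unknown state {df['state'].iloc[row]!r} at data row {row}"
        )
    if not np.all(np.isfinite(df["time_s"].to_numpy(dtype=float))):
        raise SchemaError(f"{path}: non-finite time_s value")
    return df[list(TRACK_COLUMNS)]


def write_tracks(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, TRACK_COLUMNS, "track table")
    df[list(TRACK_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str, "block_id": str, "population": str})
    _require_columns(df, PHENOTYPE_COLUMNS, f"phenotype file {path}")
    numeric = ("T", "H", "D") + TRAIT_COLUMNS
    for c in numeric:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SchemaError(f"{path}: non-numeric value in {c!r} at data row {row}")
        df[c] = vals
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, PHENOTYPE_COLUMNS, "phenotype table")
    cols = [c for c in df.columns if c in PHENOTYPE_COLUMNS or c == "year"]
    df[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fitness(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str})
    _require_columns(df, FITNESS_COLUMNS, f"fitness file {path}")
    vals = pd.to_numeric(df["fitness"], errors="coerce")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise SchemaError(f"{path}: non-numeric fitness at data row {row}")
    if (vals < 0).any():
        row = int(np.flatnonzero((vals < 0).to_numpy())[0])
        raise SchemaError(f"{path}: negative relative fitness at data row {row}")
    df["fitness"] = vals
    return df[list(FITNESS_COLUMNS)]


def write_fitness(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, FITNESS_COLUMNS, "fitness table")
    df[list(FITNESS_COLUMNS)].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_matrix_csv(m: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(m, index=list(TRAIT_COLUMNS), columns=list(TRAIT_COLUMNS)).to_csv(
        path, float_format=FLOAT_FORMAT
    )


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
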