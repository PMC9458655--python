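"""Tabular I/O with deterministic formatting.

All tables are plain TSV; floats are written with a fixed general format so
that identical runs produce byte-identical files.  mCA calls use BED-like
coordinates (0-based half-open) on output while the library works 1-based
inclusive internally.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.8g"


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_signal(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"sample_id", "chrom", "pos", "baf", "lrr", "gt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: signal table missing columns {sorted(missing)}")
    return df


def read_reads(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"sample_id", "read_id", "a1", "a2", "a3", "v617f"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: read table missing columns {sorted(missing)}")
    return df


def write_json(payload: dict, path: str | Path) -> Path:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
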