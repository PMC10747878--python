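"""File readers and writers binding the pipeline stages together.

Time series are plain delimited text (T rows x R columns, no header), one
file per subject, subject id = filename stem; the delimiter (whitespace or
comma) is sniffed per file.  Phenotypes are a headered CSV keyed by subject
id.  Checkpoints are a single JSON container holding every parameter tensor,
the fitted phenotype schema, and the config hash they were produced from.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import MultimodalGraphClassifier
from .phenotypes import PhenotypeSchema

__all__ = [
    "read_timeseries_file",
    "read_timeseries_dir",
    "read_phenotypes",
    "config_hash",
    "save_checkpoint",
    "load_checkpoint",
]

_TS_SUFFIXES = {".txt", ".tsv", ".csv", ".dat", ".1d"}

REQUIRED_PHENOTYPE_COLUMNS = [
    "site", "sex", "age", "fiq", "viq", "piq", "eye_at_scan", "handedness_category",
]


def read_timeseries_file(path: str | Path) -> np.ndarray:
    """Parse one subject's T x R table, sniffing comma vs whitespace."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path.name}: empty file")
    delim = "," if "," in lines[0] else None
    rows = []
    width = None
    for lineno, ln in enumerate(lines, start=1):
        parts = ln.split(delim) if delim else ln.split()
        try:
            row = [float(v) for v in parts]
        except ValueError as exc:
            raise ValueError(f"{path.name}, line {lineno}: non-numeric cell ({exc})") from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(
                f"{path.name}, line {lineno}: ragged row ({len(row)} columns, expected {width})"
            )
        rows.append(row)
    return np.asarray(rows, dtype=float)


def read_timeseries_dir(path: str | Path) -> dict[str, np.ndarray]:
    """Read every time-series file in a directory, keyed by filename stem.

    All subjects must share the same region count; offenders are listed.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TS_SUFFIXES)
    if not files:
        raise ValueError(f"no time-series files found in {path}")
    out: dict[str, np.ndarray] = {}
    widths: dict[str, int] = {}
    for p in files:
        ts = read_timeseries_file(p)
        out[p.stem] = ts
        widths[p.stem] = ts.shape[1]
    counts = pd.Series(widths)
    if counts.nunique() > 1:
        majority = counts.mode().iloc[0]
        offenders = counts[counts != majority]
        raise ValueError(
            "inconsistent region counts across subjects: "
            + ", ".join(f"{s}={w}" for s, w in offenders.items())
            + f" (majority {majority})"
        )
    return out


def read_phenotypes(
    path: str | Path,
    label_column: str = "label",
    id_column: str = "subject_id",
    required_columns: list[str] | None = None,
    drop_incomplete: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Read the phenotype CSV, keyed by subject id.

    Returns ``(table indexed by subject id, n_dropped)``.  Rows with missing
    values are dropped by default (incomplete records are excluded from the
    analysis); with ``drop_incomplete=False`` they are kept for downstream
    imputation.  The label column must be binary.
    """
    required = required_columns if required_columns is not None else REQUIRED_PHENOTYPE_COLUMNS
    df = pd.read_csv(path)
    missing = [c for c in [id_column, label_column] + required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing required columns: {missing}")
    if df[id_column].duplicated().any():
        dups = df.loc[df[id_column].duplicated(), id_column].unique().tolist()
        raise ValueError(f"duplicate subject ids: {dups}")
    values = set(df[label_column].dropna().unique().tolist())
    if not values <= {0, 1}:
        raise ValueError(f"label column must be binary 0/1, found values {sorted(values)}")
    n_before = len(df)
    if drop_incomplete:
        df = df.dropna(subset=[label_column] + required)
    n_dropped = n_before - len(df)
    df = df.set_index(id_column)
    df[label_column] = df[label_column].astype(int)
    return df, n_dropped


def config_hash(config: dict) -> str:
    """Stable short hash of a fully-serializable config mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_checkpoint(
    path: str | Path,
    model: MultimodalGraphClassifier,
    schema: PhenotypeSchema | None,
    config: dict | None = None,
) -> None:
    """Write a single-file JSON checkpoint: parameters + schema + config hash."""
    payload = {
        "format": "connectofuse-checkpoint-v1",
        "model": model.state_dict(),
        "schema": schema.to_dict() if schema is not None else None,
        "config": config,
        "config_hash": config_hash(config) if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns ``(model, schema_or_None, config_or_None)``."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "connectofuse-checkpoint-v1":
        raise ValueError("unrecognized checkpoint format")
    model = MultimodalGraphClassifier.from_state_dict(payload["model"])
    schema = PhenotypeSchema.from_dict(payload["schema"]) if payload["schema"] else None
    return model, schema, payload.get("config")
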