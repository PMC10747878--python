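"""Phenotype encoding: one-hot categoricals plus min-max scaled numerics.

The per-subject phenotype vector is O(p_cat) concatenated with S(p_num):
categorical columns (site, sex, eye status at scan, handedness category) are
one-hot encoded against vocabularies fitted on the training split; numeric
columns (age, FIQ, VIQ, PIQ) are mapped to [0, 1] by min-max using training
extrema and clipped.  Fitting on the training split only keeps the test set
leakage-free; an unseen test category encodes as an all-zeros block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhenotypeSchema", "encode_phenotypes"]

DEFAULT_CATEGORICAL = ["site", "sex", "eye_at_scan", "handedness_category"]
DEFAULT_NUMERIC = ["age", "fiq", "viq", "piq"]


@dataclass
class PhenotypeSchema:
    categorical_columns: list[str] = field(default_factory=lambda: list(DEFAULT_CATEGORICAL))
    numerical_columns: list[str] = field(default_factory=lambda: list(DEFAULT_NUMERIC))
    vocabularies: dict[str, list[str]] = field(default_factory=dict)
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    fitted: bool = False

    @property
    def dim(self) -> int:
        if not self.fitted:
            raise RuntimeError("schema is not fitted")
        return sum(len(self.vocabularies[c]) for c in self.categorical_columns) + len(
            self.numerical_columns
        )

    def fit(self, table: pd.DataFrame) -> "PhenotypeSchema":
        """Fit vocabularies and min/max on (training) rows."""
        self._check_columns(table)
        for c in self.categorical_columns:
            self.vocabularies[c] = sorted(table[c].astype(str).unique())
        for c in self.numerical_columns:
            vals = pd.to_numeric(table[c], errors="raise").to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing values in numeric column {c!r}")
            self.ranges[c] = (float(vals.min()), float(vals.max()))
        self.fitted = True
        return self

    def _check_columns(self, table: pd.DataFrame) -> None:
        missing = [
            c for c in self.categorical_columns + self.numerical_columns if c not in table.columns
        ]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")

    def to_dict(self) -> dict:
        return {
            "categorical_columns": self.categorical_columns,
            "numerical_columns": self.numerical_columns,
            "vocabularies": self.vocabularies,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "fitted": self.fitted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypeSchema":
        return cls(
            categorical_columns=list(d["categorical_columns"]),
            numerical_columns=list(d["numerical_columns"]),
            vocabularies={k: list(v) for k, v in d["vocabularies"].items()},
            ranges={k: (float(v[0]), float(v[1])) for k, v in d["ranges"].items()},
            fitted=bool(d["fitted"]),
        )


def encode_phenotypes(
    table: pd.DataFrame, schema: PhenotypeSchema, impute: bool = False
) -> np.ndarray:
    """Encode phenotype rows to the fixed-layout vector P (one row per subject).

    Missing values are an error by default (subjects with incomplete phenotype
    records are expected to be excluded upstream); ``impute=True`` instead
    fills numerics with the fitted midpoint and leaves unseen/missing
    categoricals as zero blocks.
    """
    if not schema.fitted:
        raise RuntimeError("schema must be fitted before encoding")
    schema._check_columns(table)

    blocks: list[np.ndarray] = []
    for c in schema.categorical_columns:
        vocab = schema.vocabularies[c]
        idx = {v: k for k, v in enumerate(vocab)}
        block = np.zeros((len(table), len(vocab)))
        for r, v in enumerate(table[c]):
            if pd.isna(v):
                if not impute:
                    raise ValueError(f"missing value in categorical column {c!r} (row {r})")
                continue
            k = idx.get(str(v))
            if k is not None:  # unseen category -> all-zeros block
                block[r, k] = 1.0
        blocks.append(block)

    num = np.zeros((len(table), len(schema.numerical_columns)))
    for ci, c in enumerate(schema.numerical_columns):
        lo, hi = schema.ranges[c]
        vals = pd.to_numeric(table[c], errors="coerce").to_numpy(dtype=float)
        if np.isnan(vals).any():
            if not impute:
                rows = np.flatnonzero(np.isnan(vals)).tolist()
                raise ValueError(f"missing values in numeric column {c!r} (rows {rows})")
            vals = np.where(np.isnan(vals), (lo + hi) / 2.0, vals)
        span = hi - lo
        scaled = (vals - lo) / span if span > 0 else np.zeros_like(vals)
        num[:, ci] = np.clip(scaled, 0.0, 1.0)
    blocks.append(num)
    return np.hstack(blocks)
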