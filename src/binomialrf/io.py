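"""Tabular input/output and the reproducibility run-report.

Feature matrices arrive as CSV/TSV with sample IDs in the first column and
feature names in the header; labels either live in a named column of the
matrix or in a separate two-column table (sample ID, class) joined on ID
with the matrix row order preserved.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import Dataset
from .errors import ValidationError

__all__ = ["read_dataset", "write_results", "RunReport"]


def _read_table(path: str) -> pd.DataFrame:
    try:
        # header read separately: read_csv silently renames duplicate columns
        raw_header = pd.read_csv(path, sep=None, engine="python", header=None, nrows=1)
        names = [str(v) for v in raw_header.iloc[0, 1:]]
        dupes = pd.Index(names)[pd.Index(names).duplicated()].unique()
        if len(dupes):
            raise ValidationError(
                f"duplicate feature names: {', '.join(map(str, dupes[:5]))}"
            )
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    except FileNotFoundError:
        raise ValidationError(f"input file not found: {path}")


def read_dataset(
    matrix_path: str,
    labels_path: Optional[str] = None,
    label_column: Optional[str] = None,
) -> Dataset:
    """Load a samples-by-features matrix plus binary labels into a Dataset."""
    if (labels_path is None) == (label_column is None):
        raise ValidationError("provide exactly one of labels_path or label_column")
    matrix = _read_table(matrix_path)
    if label_column is not None:
        if label_column not in matrix.columns:
            raise ValidationError(f"label column {label_column!r} not in matrix header")
        labels = matrix[label_column]
        matrix = matrix.drop(columns=[label_column])
    else:
        table = _read_table(labels_path)
        if table.shape[1] != 1:
            raise ValidationError("labels file must have exactly two columns: sample ID, class")
        missing = matrix.index.difference(table.index)
        if len(missing):
            raise ValidationError(
                f"labels missing for sample ID(s): {', '.join(map(str, missing[:5]))}"
            )
        labels = table.iloc[:, 0].loc[matrix.index]  # preserve matrix row order
    if matrix.shape[1] < 1:
        raise ValidationError("matrix has no feature columns")
    values = matrix.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = matrix.columns[np.isnan(values).any(axis=0)]
        raise ValidationError(f"non-numeric or missing values in: {', '.join(map(str, bad[:5]))}")
    classes = pd.unique(labels.dropna())
    if labels.isna().any() or len(classes) != 2:
        raise ValidationError(
            f"labels must be binary without missing values; found classes {list(classes)!r}"
        )
    return Dataset(values, labels.to_numpy(), list(map(str, matrix.columns)))


def write_results(results: pd.DataFrame, path: str, sep: str = "\t") -> None:
    """Write a ranked result table (TSV by default)."""
    out = results.copy()
    for col in ("features", "names"):
        if col in out.columns:  # tuples -> "a|b" so the TSV round-trips as text
            out[col] = ["|".join(map(str, t)) for t in out[col]]
    out.to_csv(path, sep=sep, index=False)


def file_sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunReport:
    """Everything needed to re-run an analysis bit-identically."""

    command: str
    params: dict
    seed: Optional[int] = None
    realized: dict = field(default_factory=dict)  # V, m, n, rho as used
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = __version__
    started: float = field(default_factory=time.time)

    def add_input(self, path: str) -> None:
        self.inputs[str(path)] = file_sha256(path)

    def write(self, path: str) -> None:
        payload = {
            "command": self.command,
            "version": self.version,
            "seed": self.seed,
            "params": self.params,
            "realized": self.realized,
            "inputs": self.inputs,
            "elapsed_seconds": round(time.time() - self.started, 3),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
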