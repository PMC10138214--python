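"""Readers and writers for feature matrices and run artifacts.

Feature matrices come as CSV/TSV (items x features, header row, first
column = item ids) or MatrixMarket MTX with companion row/column name
files (one name per line).  Label tables are CSV/TSV with one column per
partition (column 0 = reference).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "write_manifest"]


def read_matrix(path, rownames=None, colnames=None) -> tuple[np.ndarray, list[str]]:
    """Read a features matrix; returns (X, item_names)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"view file not found: {path}")
    if path.suffix == ".mtx":
        from scipy.io import mmread

        X = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense") else mmread(path))
        X = np.asarray(mmread(path).toarray()) if X.ndim != 2 else X
        names = [ln.strip() for ln in open(rownames)] if rownames else [str(i) for i in range(X.shape[0])]
        return X.astype(float), names
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_matrix(path, X: np.ndarray, item_names=None) -> None:
    path = Path(path)
    if item_names is None:
        item_names = [f"item_{i}" for i in range(X.shape[0])]
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    pd.DataFrame(X, index=item_names).to_csv(path, sep=sep, float_format="%.8g")


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
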