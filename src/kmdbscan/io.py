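"""Reading and writing point tables (CSV/TSV via pandas)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import PointSet

__all__ = ["load_table", "save_table"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def load_table(path, label_col: str | None = None) -> PointSet:
    """Load an n x d feature table, optionally splitting off a label column.

    Delimiter is inferred from the extension (.tsv/.tab -> tab, else comma).
    Row order is preserved.  Non-numeric feature cells raise a parse error
    naming the offending column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    labels = None
    if label_col is not None:
        if label_col not in df.columns:
            raise ValueError(
                f"label column {label_col!r} not in header {list(df.columns)}"
            )
        labels = df[label_col].to_numpy()
        df = df.drop(columns=[label_col])
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].map(
                lambda v: not isinstance(v, (int, float, np.number))
            )
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else 0
            raise ValueError(
                f"non-numeric feature value in column {col!r}, row {row}"
            )
    return PointSet(df.to_numpy(dtype=float), labels)


def save_table(X: PointSet, path) -> None:
    """Write a PointSet as f0..f{d-1} columns plus a label column if present."""
    path = Path(path)
    df = pd.DataFrame(X.points, columns=[f"f{i}" for i in range(X.d)])
    if X.labels is not None:
        df["label"] = X.labels
    # 17 significant digits: binary64 round-trips exactly
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
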