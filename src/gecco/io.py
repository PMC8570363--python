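"""Delimited-text readers/writers and run configuration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RunConfig", "read_view", "write_labels", "write_features",
           "write_summary"]


@dataclass
class RunConfig:
    """End-to-end run settings (rows are samples, columns features; views
    aligned by row order)."""

    view_paths: list[str]
    losses: list[str]
    scheme: str = "gaussian"
    kappa: int = 5
    phi: float | None = None
    gamma: float | None = None
    alpha: float = 0.0
    n_clusters: int | None = None
    n_features: int | None = None
    rho: float = 1.0
    tol: float = 1e-5
    max_iter: int = 10000
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)


def read_view(path, delimiter: str = ",", header: bool = True):
    """Read a numeric samples-by-features matrix from delimited text.

    Returns ``(matrix, row_names, col_names)``.  Missing cells are rejected:
    there is no missing-data support.
    """
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None,
                     index_col=None)
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        cell = f"row {rows[0] + 1}, column {df.columns[cols[0]]!r}"
        raise ValueError(f"missing value (NA) at {cell} in {path}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric column(s) {non_numeric} in {path}")
    names = [str(c) for c in df.columns]
    return df.to_numpy(dtype=float), list(map(str, range(len(df)))), names


def write_labels(path, labels, sample_ids=None) -> None:
    ids = sample_ids if sample_ids is not None else range(len(labels))
    pd.DataFrame({"sample_id": list(ids), "label": np.asarray(labels)}).to_csv(
        path, index=False
    )


def write_features(path, selected: list[np.ndarray], names=None) -> None:
    rows = []
    for k, mask in enumerate(selected):
        nm = names[k] if names else [str(j) for j in range(len(mask))]
        for j, sel in enumerate(mask):
            rows.append({"view": k, "feature": nm[j], "selected": bool(sel)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary(path, summary: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(summary, indent=2, default=_default))
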