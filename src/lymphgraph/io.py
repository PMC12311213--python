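"""Interchange formats: feature CSV, bbox CSV, edge TSV, JSON reports.

The feature table convention everywhere: a CSV with an ``id`` column,
``fNNNN`` feature columns, and a binary ``label`` column. Round trips are
exact for integers and to full float precision (values written with repr).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def read_feature_csv(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read (ids, features, labels) from the feature-table CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: feature CSV must have 'id' and 'label' columns")
    ids = df["id"].astype(str).tolist()
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate patient id {dup.iloc[0]!r}")
    feat_cols = [c for c in df.columns if c not in ("id", "label")]
    X = df[feat_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = feat_cols[int(np.argwhere(np.isnan(X))[0][1])]
        raise ValueError(f"{path}: NaN feature value in column {bad!r}")
    y = df["label"].to_numpy(dtype=int)
    return ids, X, y


def write_feature_csv(path: str | Path, ids, X, y) -> Path:
    path = Path(path)
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    width = max(4, len(str(max(d - 1, 0))))
    df = pd.DataFrame({"id": list(ids)})
    for j in range(d):
        df[f"f{j:0{width}d}"] = [repr(float(v)) for v in X[:, j]]
    df["label"] = np.asarray(y, dtype=int)
    df.to_csv(path, index=False)
    return path


def read_bbox_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "x_min", "y_min", "x_max", "y_max", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: bbox CSV missing columns {sorted(missing)}")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate image id {dup.iloc[0]!r}")
    return df


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
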