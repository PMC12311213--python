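"""Small shared helpers: seeding, validation."""

from __future__ import annotations

import zlib

import numpy as np

_SEED_MOD = 2**31 - 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global seed and a stage name.

    Stable across processes and Python versions (crc32, not ``hash``), so any
    stage can be re-run in isolation with the same randomness.
    """
    return (int(global_seed) ^ zlib.crc32(stage.encode("utf-8"))) % _SEED_MOD


def check_finite(arr: np.ndarray, name: str = "array") -> np.ndarray:
    arr = np.asarray(arr)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def as_binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"labels must be binary 0/1, got values {uniq}")
    return y.astype(int)
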