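"""Small shared helpers: seeding and validation."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(base_seed: int, label: str) -> int:
    """Derive a stage-specific seed from a global seed and a stage label.

    Uses a stable cryptographic hash so that every stage of a run gets an
    independent, reproducible stream, and any stage can be rerun in
    isolation. The result is always below 2**31.
    """
    digest = hashlib.sha256(f"{base_seed}:{label}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def check_finite(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    return X


def check_binary_labels(y) -> np.ndarray:
    """Validate a binary 0/1 label vector with both classes present."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    return y.astype(int)
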