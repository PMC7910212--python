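"""Shared helpers: seeded random streams, standardization, design checks."""

from __future__ import annotations

import hashlib
import json

import numpy as np

# Fixed per-stage stream offsets so one global seed expands to independent,
# individually re-runnable generators.
STREAMS = {
    "genotypes": 1,
    "summary_stats": 2,
    "cohort": 3,
    "imaging": 4,
    "spls": 5,
    "permutation": 6,
    "bootstrap": 7,
    "pipeline": 8,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Generator for a named stage derived from one global seed."""
    return np.random.default_rng([STREAMS[stream], int(seed)])


def as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def zscore(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Column z-scores with the population-SD convention (ddof=0)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant column")
    return (x - mu) / sd


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
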