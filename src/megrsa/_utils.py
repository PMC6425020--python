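"""Small shared helpers: deterministic seeding and run-length utilities."""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic 31-bit seed for a named pipeline stage.

    Mixes the global seed with a CRC of the stage name through a
    :class:`numpy.random.SeedSequence`, so every stochastic stage gets an
    independent, reproducible stream.
    """
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))


def max_run_length(mask: np.ndarray) -> np.ndarray:
    """Longest run of consecutive True values along the last axis."""
    mask = np.asarray(mask, dtype=bool)
    best = np.zeros(mask.shape[:-1], dtype=np.int64)
    cur = np.zeros(mask.shape[:-1], dtype=np.int64)
    for t in range(mask.shape[-1]):
        cur = (cur + 1) * mask[..., t]
        best = np.maximum(best, cur)
    return best


def contiguous_runs(mask: np.ndarray) -> list:
    """(start, stop) index pairs (inclusive) of True runs in a 1-D mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 1:
        raise ValueError("contiguous_runs expects a 1-D mask")
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    stops = np.where(d == -1)[0] - 1
    return list(zip(starts.tolist(), stops.tolist()))
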