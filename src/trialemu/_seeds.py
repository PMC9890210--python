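"""Deterministic seed derivation.

A single master seed fans out to per-stage RNGs via a stable label hash, so
any stage can be re-run in isolation with the same stream it saw inside a
full pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(master_seed: int, label: str) -> int:
    """Return a 31-bit child seed for ``label`` derived from ``master_seed``."""
    h = zlib.crc32(label.encode("utf-8"))
    return int((master_seed * 1_000_003 + h) % (2**31 - 1))


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """Return a :class:`numpy.random.Generator` for the stage ``label``."""
    return np.random.default_rng(derive_seed(master_seed, label))
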