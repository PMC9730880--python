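"""Seed plumbing: one config seed expanded into named, reproducible substreams."""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derive_seed(seed: int, name: str) -> int:
    """Derive a deterministic child seed for a named pipeline stage.

    Stable across processes and Python versions (CRC32, not ``hash``),
    and kept below 2**31 so it can be handed to any library RNG.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode())) % _MOD


def substream(seed: int, name: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named substream of ``seed``."""
    return np.random.default_rng(derive_seed(seed, name))
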