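"""Small shared helpers (seed derivation, validation)."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "child_seed_sequence"]


def child_seed_sequence(seed: int, tag: str) -> np.random.SeedSequence:
    """Derive an independent seed stream from a global seed and a stable tag.

    The tag is hashed with CRC32 so that enabling or disabling one consumer
    (e.g. one statistical test) never shifts the randomness of another.
    """
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode()) & 0x7FFFFFFF])


def spawn_rng(seed: int, tag: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` keyed by ``(seed, tag)``."""
    return np.random.default_rng(child_seed_sequence(seed, tag))
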