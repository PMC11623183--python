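"""Deterministic random-stream derivation.

Every stochastic component of the package (mask generation, coefficient
draws, data simulation, train/validation splitting, weight initialization,
mini-batch sampling) draws from a named sub-stream derived from one master
seed.  Streams are independent PCG64 generators keyed by
``SeedSequence([master_seed, crc32(name_1), crc32(name_2), ...])``, so the
same master seed reproduces every stage bit-for-bit while distinct stages
never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_sequence", "substream", "derive_seed"]


def seed_sequence(seed: int, *streams: str) -> np.random.SeedSequence:
    """SeedSequence for the sub-stream named by ``streams`` under ``seed``."""
    keys = [zlib.crc32(s.encode("utf-8")) for s in streams]
    return np.random.SeedSequence([int(seed), *keys])


def substream(seed: int, *streams: str) -> np.random.Generator:
    """A fresh Generator on the named sub-stream of ``seed``."""
    return np.random.default_rng(seed_sequence(seed, *streams))


def derive_seed(seed: int, *streams: str) -> int:
    """Collapse a named sub-stream to a plain integer seed (< 2**31)."""
    return int(seed_sequence(seed, *streams).generate_state(1)[0] % (2**31))
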