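"""Named, reproducible random substreams derived from one master seed.

Every stochastic component (lesion simulation, behavioral simulation,
cross-validation folds, parameter-selection permutations, inference
permutations) draws from its own named substream so components are
independently reproducible and insensitive to each other's draw counts.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, so streams are stable across
    runs and platforms and distinct across names.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def subseed(seed: int, name: str) -> int:
    """A plain integer seed (< 2^31) for APIs that take one."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
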