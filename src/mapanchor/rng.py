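"""Seed-derived named substreams so each stage is independently reproducible."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for stream ``name`` derived from the master seed.

    Streams with different names are statistically independent; the same
    (seed, name) pair always yields the same stream regardless of how many
    other streams were consumed before it.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
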