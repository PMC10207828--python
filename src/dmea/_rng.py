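"""Deterministic, order-independent random streams.

Every stochastic component draws from a generator derived from the user
seed plus a string key naming the stream (a MOA name, a simulation cell, a
replicate).  Streams are therefore reproducible and independent of the
order in which components are evaluated.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(seed, *keys)``.

    Keys are rendered to text and hashed with CRC32, so any hashable,
    printable object (str, int, float) works and the derivation is stable
    across processes and platforms.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        words.append(zlib.crc32(repr(key).encode("utf-8")) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))
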