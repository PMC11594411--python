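"""Seed plumbing: every stochastic stage draws from a named substream.

A single user-facing integer seed is combined with a CRC32 hash of the
stage name, so stages are statistically independent but fully reproducible
and insensitive to the order in which stages run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` derived from the global ``seed``."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])
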