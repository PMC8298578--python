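"""Seed derivation: every stage draws from its own named stream.

A single integer seed plus a stage name deterministically yields an
independent numpy Generator, so pipeline stages are reproducible in
isolation and insensitive to each other's draw counts.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` derived from ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def child_seed(seed: int, name: str) -> int:
    """A 31-bit integer seed for libraries that take ``random_state`` ints."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
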