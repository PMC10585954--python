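"""Deterministic named random streams.

Every stochastic step in the package draws from a generator obtained via
:func:`stream`, keyed by the single pipeline seed plus a short stream name.
Adding a new stage therefore never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_sequence", "stream"]


def child_sequence(seed: int, name: str) -> np.random.SeedSequence:
    """Derive a named child seed sequence from a single integer seed."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))])


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named sub-stream of ``seed``."""
    return np.random.default_rng(child_sequence(seed, name))
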