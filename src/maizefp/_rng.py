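"""Seed plumbing: every module draws from a named substream of one seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``.

    Substreams are independent (distinct spawn keys) and stable across
    runs and platforms, so e.g. the intensity stream can be regenerated
    without re-drawing the locus universe.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
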