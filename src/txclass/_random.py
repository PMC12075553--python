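"""Deterministic per-stage random substreams.

All randomness in the package flows from one integer seed through named
substreams, so changing e.g. the WGAN stream leaves the fold plan intact.
Tags are folded in via CRC32, which is stable across platforms and runs.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *tags: str | int) -> np.random.Generator:
    """Return a Generator for ``seed`` specialized by the given stage tags."""
    words = [int(seed) & 0xFFFFFFFF]
    for tag in tags:
        if isinstance(tag, int):
            words.append(tag & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(tag.encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(words))


def subseed(seed: int, *tags: str | int) -> int:
    """A plain integer seed (< 2**31) derived from the named substream."""
    return int(substream(seed, *tags).integers(0, 2**31 - 1))
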