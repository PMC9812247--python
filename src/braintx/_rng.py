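"""Deterministic per-stage random substreams.

A single user-facing seed drives the whole analysis; each stage derives its
own independent substream by hashing the stage name into the seed sequence,
so any stage can be regenerated in isolation without replaying the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for ``stage`` derived from the global ``seed``.

    The stage name is folded in via CRC-32, so the mapping is stable across
    runs, platforms and Python hash randomization.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])
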