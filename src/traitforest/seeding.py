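"""Named-substream seeding.

One global seed expands into an independent RNG stream per named stage, so
adding a stage (or changing the order stages run in) never perturbs the
random draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _key(label: str) -> int:
    return zlib.crc32(label.encode())


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for stage ``label`` under the global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_key(label),)))


def subseed(seed: int, label: str) -> int:
    """Deterministic integer seed (< 2**31) for stage ``label``."""
    return int(substream(seed, label).integers(2**31))
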