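"""Deterministic, label-addressed random streams.

Every stochastic stage derives its generator from (seed, *labels) so that the
result for one sample or stage never depends on how many random draws another
stage consumed, and cohort generation is byte-identical across runs and
iteration orders.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, *labels) -> np.random.Generator:
    """Return a Generator keyed by an integer seed plus arbitrary labels.

    Labels are hashed with CRC32, which is stable across processes and
    platforms (unlike ``hash``).
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    entropy.extend(zlib.crc32(str(label).encode("utf-8")) for label in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))
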