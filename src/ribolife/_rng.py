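"""Deterministic per-stage random streams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *tokens) -> np.random.Generator:
    """A Generator keyed by (seed, tokens); stable across runs and order.

    String tokens are hashed with CRC32 so stage names can key their own
    stream without depending on execution order.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            ints.append(zlib.crc32(t.encode()))
        else:
            ints.append(int(t) & 0x7FFFFFFF)
    return np.random.default_rng(ints)
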