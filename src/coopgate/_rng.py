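"""Seed plumbing.

Every generator in the package draws from a substream derived from a single
top-level integer seed plus a short stream name, so adding one generator call
to a script never perturbs the random numbers any other call sees.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, folded to 31 bits so derived
    integers stay within the positive int32 range.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
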