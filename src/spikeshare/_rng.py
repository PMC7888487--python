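"""Deterministic seed splitting.

All randomness in the package flows from a single master seed.  Child seeds
are derived by CRC-mixing the master seed with a tuple of string/int keys
naming the consumer (module, operation, frame index, ...), so that every
stage is reproducible in isolation and independent of evaluation order.
Derived seeds are kept below 2**31 so they are valid for every downstream
API (numpy Generators, scikit-learn ``random_state``).
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, *keys) -> int:
    """Derive a deterministic child seed < 2**31 from ``seed`` and ``keys``."""
    payload = repr((int(seed),) + tuple(keys)).encode("utf-8")
    return int(zlib.crc32(payload)) % (2**31 - 1)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, *keys))
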