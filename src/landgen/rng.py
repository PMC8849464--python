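"""Seed management.

A single pipeline seed is expanded into independent per-stage substreams by
hashing a stage label into the entropy pool of a :class:`numpy.random.SeedSequence`.
Stages are therefore independently reproducible: rerunning one stage with the
same global seed draws the same stream regardless of what other stages did.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_entropy(key: str) -> int:
    return zlib.crc32(key.encode("utf-8"))


def substream(seed: int, key: str) -> np.random.Generator:
    """Return the generator for stage `key` under global `seed`."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _key_entropy(key)]))


def child_seed(seed: int, key: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    ss = np.random.SeedSequence([int(seed), _key_entropy(key)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
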