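"""Deterministic seeded substreams.

Every source of randomness in the package is derived from a master seed plus a
stable string key (e.g. ``"particle/17"``).  Keys are hashed, so adding
particles to a population never reshuffles the streams of existing particles.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream_seed", "substream"]

_MOD = 2**31


def substream_seed(master_seed: int, *keys: str) -> int:
    """Return a 31-bit seed derived from ``master_seed`` and string keys."""
    h = hashlib.blake2b("/".join(keys).encode("utf-8"), digest_size=8)
    token = int.from_bytes(h.digest(), "little") % _MOD
    ss = np.random.SeedSequence([int(master_seed) % _MOD, token])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % _MOD


def substream(master_seed: int, *keys: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the keyed substream."""
    return np.random.default_rng(substream_seed(master_seed, *keys))
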