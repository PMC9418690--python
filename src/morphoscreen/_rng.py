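"""Deterministic seed derivation.

Child streams (per plate/well/field, per movie, per track) are seeded from a
stable hash of the parent seed and a key tuple, so regenerating any subset of
a simulated experiment is reproducible without sharing generator state.
The rule (SHA-256 of the repr of the key tuple, truncated to 31 bits) is part
of the package contract and will not change between versions.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_from"]


def derive_seed(parent_seed: int, *keys) -> int:
    """Derive a child seed < 2**31 from a parent seed and hashable keys."""
    payload = repr((int(parent_seed),) + tuple(keys)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_from(parent_seed: int, *keys) -> np.random.Generator:
    """A fresh Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(parent_seed, *keys))
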