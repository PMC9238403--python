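"""Deterministic RNG stream derivation.

Every stochastic routine in the package takes an integer seed and derives
independent numpy Generators from (seed, string tokens) so results do not
depend on iteration order or parallel scheduling.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "token_hash"]


def token_hash(*tokens: str) -> int:
    """Stable 32-bit hash of a tuple of string tokens (order-sensitive)."""
    h = hashlib.blake2b("\x1f".join(tokens).encode("utf-8"), digest_size=4)
    return int.from_bytes(h.digest(), "big")


def derive_rng(seed: int, *tokens: str) -> np.random.Generator:
    """A Generator keyed by a base seed plus arbitrary string tokens.

    The same (seed, tokens) always yields the same stream; distinct token
    tuples yield independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), token_hash(*tokens)]))
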