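"""Shared helpers: seeded RNG spawning and package logging."""
from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("syntropy")


def get_rng(seed) -> np.random.Generator:
    """Return a Generator; passes through an existing Generator unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_rng(seed: int, *tokens: int) -> np.random.Generator:
    """Deterministically derive an independent stream from a master seed.

    Each distinct token tuple yields a distinct, reproducible stream, so
    pipeline stages can be re-run in isolation without perturbing each other.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(t) for t in tokens)))


def child_seed(seed: int, *tokens: int) -> int:
    """A plain integer seed (< 2**31) derived from a master seed and tokens."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(t) for t in tokens))
    return int(ss.generate_state(1)[0] % (2**31 - 1))
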