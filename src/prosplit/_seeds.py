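"""Seed-tree utilities.

Every public function in the package takes a single integer ``seed``.
Internally, independent streams are derived through ``numpy``'s
``SeedSequence`` spawning so that any sub-computation (a bootstrap draw, a
permutation test, one repetition of a replayed study) is re-runnable in
isolation from its own child seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seeds", "seed_to_int", "rng_from"]

_MAX_SEED = 2**31 - 1


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer child seeds (< 2**31) from ``seed``."""
    children = np.random.SeedSequence(int(seed)).spawn(n)
    return [int(c.generate_state(1)[0]) & _MAX_SEED for c in children]


def seed_to_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0]) & _MAX_SEED


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))
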