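"""Seeded random streams.

All stochastic code in the package takes either an integer seed or a
``numpy.random.Generator``.  Identical seeds give bitwise-identical
trajectories on the same platform; per-replica child streams are spawned
from a ``SeedSequence`` so they are mutually independent.
"""

from __future__ import annotations

import numpy as np


def seeded_rng(seed: int | np.random.Generator) -> np.random.Generator:
    """Return a Generator from an integer seed (pass-through for Generators)."""
    if isinstance(seed, np.random.Generator):
        return seed
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    return np.random.default_rng(int(seed))


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent child streams derived from one seed."""
    children = np.random.SeedSequence(int(seed)).spawn(n)
    return [np.random.default_rng(c) for c in children]
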