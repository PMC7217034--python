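"""Deterministic hierarchical random-number streams.

Every stochastic component draws from a numpy ``Generator`` seeded through a
``SeedSequence`` whose ``spawn_key`` encodes the component's position in the
computation (replicate, imputation pass, fold, ...).  Results are therefore
reproducible from a single root seed and independent of execution order and
of any parallelism across datasets or replicates.
"""
from __future__ import annotations

import numpy as np

__all__ = ["seed_sequence", "substream", "generator", "PARTITION_KEY"]

#: spawn-key tag reserved for fold-partition draws (never collides with fold
#: or imputation indices, which are small integers).
PARTITION_KEY = 0x7FFF0001


def seed_sequence(random_state=None) -> np.random.SeedSequence:
    """Coerce ``None``, an int, a ``Generator`` or a ``SeedSequence`` into a
    ``SeedSequence``.  ``None`` yields fresh OS entropy (non-reproducible)."""
    if random_state is None:
        return np.random.SeedSequence()
    if isinstance(random_state, np.random.SeedSequence):
        return random_state
    if isinstance(random_state, np.random.Generator):
        return np.random.SeedSequence(int(random_state.integers(0, 2**31)))
    return np.random.SeedSequence(int(random_state))


def substream(ss: np.random.SeedSequence, *key: int) -> np.random.SeedSequence:
    """A child stream addressed by ``key``, appended to the parent spawn key."""
    return np.random.SeedSequence(
        entropy=ss.entropy,
        spawn_key=tuple(ss.spawn_key) + tuple(int(k) for k in key),
    )


def generator(source=None) -> np.random.Generator:
    """A ``Generator`` for any seed-like source (passes Generators through)."""
    if isinstance(source, np.random.Generator):
        return source
    return np.random.default_rng(seed_sequence(source))
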