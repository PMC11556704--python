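"""Deterministic, platform-stable random streams.

Every stochastic step in the package draws from a counter-based Philox
generator keyed by an integer seed plus an integer path identifying the
stream (e.g. ``(pair_index, output_index, attempt)``).  Two runs with the
same seed therefore produce bit-identical results, and any single output
can be replayed from its recorded seed without re-running the rest of a
batch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_from", "derive_seed"]


def rng_from(seed: int, *path: int) -> np.random.Generator:
    """Return a Philox generator for stream ``path`` under ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(p) for p in path))
    return np.random.Generator(np.random.Philox(ss))


def derive_seed(seed: int, *path: int) -> int:
    """Derive a child integer seed (< 2**31) for stream ``path``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))
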