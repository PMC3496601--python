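"""Named, reproducible random-number streams.

All randomness in a run flows from one root seed.  Each phase (data
synthesis, CE, MCEM, uncertainty) gets its own child stream spawned in a
fixed order, so phases are independently reproducible and re-running any
one of them never perturbs the others.
"""

from __future__ import annotations

import numpy as np

__all__ = ["named_streams", "spawn_seeds"]

PHASES = ("data", "ce", "mcem", "uncertainty")


def named_streams(
    seed: int | np.random.SeedSequence | None, names: tuple[str, ...] = PHASES
) -> dict[str, np.random.Generator]:
    """One independent Generator per name, spawned from ``seed`` in order."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def spawn_seeds(seed: int | None, n: int) -> list[np.random.SeedSequence]:
    """``n`` independent child seed sequences (e.g. one per experiment run)."""
    return np.random.SeedSequence(seed).spawn(n)
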