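"""Shared helpers: deterministic child-seed derivation and small validators."""

from __future__ import annotations

import numpy as np

# Child seeds must stay below 2**31 so they remain valid seeds for any
# downstream generator (and serialize cleanly to JSON/YAML).
_SEED_MOD = 2**31


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` reproducible child seeds from one integer master seed.

    Uses :class:`numpy.random.SeedSequence` so children are statistically
    independent of each other and of the master stream.
    """
    ss = np.random.SeedSequence(int(master_seed))
    state = ss.generate_state(n, dtype=np.uint64)
    return [int(s % _SEED_MOD) for s in state]


def as_float_array(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr
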