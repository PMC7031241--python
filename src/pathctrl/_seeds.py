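"""Deterministic sub-seed derivation.

All stochastic stages take one integer seed; nested stages derive child
seeds from (master seed, counter path) through a SeedSequence so that any
stage can be reproduced in isolation from its recorded seed.
"""

from __future__ import annotations

import numpy as np


def derive_seed(master: int, *path: int) -> int:
    """A child seed determined by the master seed and a counter path."""
    ss = np.random.SeedSequence((int(master),) + tuple(int(p) for p in path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_from(master: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *path))
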