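"""Seed handling and small shared numerics."""

from __future__ import annotations

import numpy as np

# Fixed substream indices so each stage can be regenerated independently of
# the others from the single study seed.
_STAGE_KEYS = {
    "genotypes": 0,
    "reads": 1,
    "expression": 2,
    "permutation_de": 3,
    "permutation_af": 4,
    "diversity": 5,
    "gmm": 6,
    "misc": 7,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage.

    A single user-facing seed is expanded with ``SeedSequence`` spawn keys,
    one per stage, so re-running one stage does not consume another stage's
    random stream.
    """
    if stage not in _STAGE_KEYS:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(_STAGE_KEYS)}")
    ss = np.random.SeedSequence(int(seed), spawn_key=(_STAGE_KEYS[stage],))
    return np.random.default_rng(ss)


def child_seed(seed: int, index: int) -> int:
    """Deterministic 31-bit child seed (for libraries wanting an int seed)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
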