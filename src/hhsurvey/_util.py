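"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np

#: The seven age groups used for stratification, youngest first.
AGE_GROUPS = ("0-2", "3-4", "5-9", "10-14", "15-19", "20-59", "60+")

SEXES = ("M", "F")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Commercial rounding, not banker's rounding: the planning-table
    arithmetic requires 0.5 to round up.
    """
    return int(math.floor(x + 0.5))


def rng_from(seed) -> np.random.Generator:
    """Accept a seed, a SeedSequence or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive n independent child seed sequences from a master seed."""
    return np.random.SeedSequence(seed).spawn(n)
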