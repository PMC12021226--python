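"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as diet tables are printed.

    Python's built-in ``round`` uses banker's rounding (6.25 -> 6.2); field
    tables print 6.25% as 6.3%, so percentages are rounded half-up.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` in ``total``, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a base seed.

    Every stochastic stage of the pipeline pulls its generator through this
    function so that one top-level seed fixes the whole run while stages
    stay statistically independent.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
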