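"""Binned matched sampling shared by MAF matching and GC matching.

Negatives are drawn so that their histogram over fixed-width bins equals
the positives' histogram exactly.  Within each bin the draw is uniform
without replacement under a caller-supplied seed.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

import numpy as np

__all__ = ["DeficientBinsError", "bin_index", "binned_match_indices"]


class DeficientBinsError(ValueError):
    """Raised when some bins hold fewer candidates than positives.

    ``deficient`` maps bin index -> (needed, available).  Callers may
    retry with a coarser bin width.
    """

    def __init__(self, deficient: dict[int, tuple[int, int]], bin_width: float):
        self.deficient = dict(deficient)
        self.bin_width = bin_width
        detail = ", ".join(
            f"bin [{k * bin_width:g}, {(k + 1) * bin_width:g}): "
            f"need {need}, have {have}"
            for k, (need, have) in sorted(deficient.items())
        )
        super().__init__(f"deficient bins at width {bin_width:g}: {detail}")


def bin_index(value: float, bin_width: float) -> int:
    """Index k of the half-open bin [k*w, (k+1)*w) containing value."""
    return int(math.floor(value / bin_width))


def binned_match_indices(
    positive_values: Sequence[float],
    candidate_values: Sequence[float],
    bin_width: float,
    seed: int | np.random.Generator,
) -> list[int]:
    """Indices into ``candidate_values`` matching the positives' histogram.

    Returns exactly ``len(positive_values)`` candidate indices such that
    per-bin counts equal the positives' per-bin counts.
    """
    if len(positive_values) == 0:
        raise ValueError("empty positive set")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    need = Counter(bin_index(v, bin_width) for v in positive_values)
    pools: dict[int, list[int]] = {}
    for i, v in enumerate(candidate_values):
        pools.setdefault(bin_index(v, bin_width), []).append(i)

    deficient = {
        k: (n, len(pools.get(k, [])))
        for k, n in need.items()
        if len(pools.get(k, [])) < n
    }
    if deficient:
        raise DeficientBinsError(deficient, bin_width)

    chosen: list[int] = []
    for k in sorted(need):
        pool = pools[k]
        take = rng.choice(len(pool), size=need[k], replace=False)
        chosen.extend(pool[int(i)] for i in take)
    return chosen
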