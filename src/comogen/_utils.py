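"""Shared numerical helpers: stable log-space arithmetic and set partitions."""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = ["logsumexp", "logdiffexp", "set_partitions", "nonempty_subsets"]


def logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) computed stably; -inf when the difference is <= 0.

    Used for the distinct-causal-variant evidence term, where the sum over
    ordered SNP pairs minus the shared-SNP diagonal can cancel almost exactly.
    """
    if b >= a:
        return -np.inf
    with np.errstate(divide="ignore"):
        return a + np.log1p(-np.exp(b - a))


def set_partitions(items: Sequence) -> Iterator[list[list]]:
    """Yield all partitions of ``items`` into non-empty blocks.

    Order of blocks and of items within blocks follows input order
    (deterministic enumeration; Bell(n) partitions for n items).
    """
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in set_partitions(rest):
        # first joins an existing block, or forms its own
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1 :]
        yield [[first]] + sub


def nonempty_subsets(items: Sequence) -> Iterator[tuple]:
    items = list(items)
    for k in range(1, len(items) + 1):
        yield from combinations(items, k)
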