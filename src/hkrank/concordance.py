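"""Agreement statistics between candidate gene lists.

Used to ask two questions about ranked reference-gene lists: do repeated runs
of the pipeline (different bootstrap seeds, different study selections) agree
(overlap coefficient, reproducibility measure R), and is an observed overlap
larger than chance (one-sided hypergeometric tail)?
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Sequence

from scipy.stats import hypergeom

from .errors import ConfigurationError, EmptyInputError, HkrankError


def overlap_coefficient(a: Sequence[str], b: Sequence[str]) -> float:
    """|A intersect B| / min(|A|, |B|) for two gene lists (duplicates ignored)."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise EmptyInputError("overlap coefficient of an empty list is undefined")
    return len(sa & sb) / min(len(sa), len(sb))


def reproducibility_R(lists: Sequence[Sequence[str]], k: int = 50) -> float:
    """Mean pairwise overlap coefficient of the top-k of each list.

    Each list is truncated to its first k entries before comparison; lists
    shorter than k are used at full length (with a warning).
    """
    if len(lists) < 2:
        raise ConfigurationError("reproducibility R needs at least two lists")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    truncated = []
    for lst in lists:
        if len(lst) < k:
            warnings.warn(f"list of length {len(lst)} shorter than k={k}; using full list",
                          stacklevel=2)
        truncated.append(list(lst)[:k])
    pairs = list(combinations(truncated, 2))
    return sum(overlap_coefficient(a, b) for a, b in pairs) / len(pairs)


def overlap_pvalue(k_overlap: int, n1: int, n2: int, universe: int) -> float:
    """One-sided hypergeometric tail P(X >= k_overlap) for the overlap of two
    fixed-size gene lists drawn from a common universe.

    X ~ Hypergeometric(universe, n1, n2): the overlap expected if one list of
    n1 genes is drawn at random from a universe containing n2 marked genes.
    """
    if not (0 <= k_overlap <= min(n1, n2) <= universe) or min(n1, n2) < 0:
        raise HkrankError(
            f"inconsistent counts: overlap={k_overlap}, n1={n1}, n2={n2}, universe={universe}"
        )
    return float(hypergeom.sf(k_overlap - 1, universe, n1, n2))
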