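"""Independent brute-force oracles used across the test modules.

Deliberately written in plain Python over explicit contingency tables /
literal definitions, sharing no code with the package implementations they
check.
"""

from __future__ import annotations

import math
from collections import Counter


def oracle_entropy(x) -> float:
    """H(X) in bits from an explicit value count."""
    n = len(x)
    counts = Counter(x)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def oracle_conditional_entropy(x, y) -> float:
    """H(X|Y) = sum_y p(y) H(X|Y=y) from the full joint table."""
    n = len(x)
    by_y: dict = {}
    for xi, yi in zip(x, y):
        by_y.setdefault(yi, []).append(xi)
    return sum((len(xs) / n) * oracle_entropy(xs) for xs in by_y.values())


def oracle_su(x, y) -> float:
    hx = oracle_entropy(x)
    hy = oracle_entropy(y)
    if hx + hy == 0:
        return 0.0
    return 2.0 * (hx - oracle_conditional_entropy(x, y)) / (hx + hy)


def oracle_fcbf(su_with_class: dict, su_pairwise: dict) -> list:
    """Literal predominant-feature definition over precomputed SU tables.

    ``su_with_class``: gene -> SU(g, C); ``su_pairwise``: frozenset({g, h})
    -> SU(g, h).  Genes are processed in descending SU(g, C) (ties by
    ascending identifier); a gene is removed if any previously kept gene's
    SU with it meets or exceeds its SU with the class.
    """
    order = sorted(su_with_class, key=lambda g: (-su_with_class[g], g))
    kept: list = []
    for g in order:
        predominant = True
        for h in kept:
            if su_pairwise[frozenset((g, h))] >= su_with_class[g]:
                predominant = False
                break
        if predominant:
            kept.append(g)
    return kept
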