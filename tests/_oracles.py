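"""Independent brute-force oracles used to check the implementation.

Everything here is written as plain scalar loops / exact arithmetic and
deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def mean_oracle(xs: list[float]) -> float:
    total = 0.0
    for x in xs:
        total += x
    return total / len(xs)


def sd_oracle(xs: list[float]) -> float:
    """Sample standard deviation, n-1 denominator, two-pass."""
    m = mean_oracle(xs)
    acc = 0.0
    for x in xs:
        acc += (x - m) ** 2
    return math.sqrt(acc / (len(xs) - 1))


def cv_oracle(xs: list[float]) -> float:
    return sd_oracle(xs) / mean_oracle(xs)


def rank_oracle(values: list[float]) -> list[float]:
    """Ascending ranks with tie-averaging, by sort-then-assign."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0  # positions are 1-based
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def sv_oracle(rank_rows: dict[str, list[float | None]]) -> dict[str, float]:
    """Mean rank per gene over the datasets where it is measured."""
    out = {}
    for gene, row in rank_rows.items():
        seen = [r for r in row if r is not None]
        if seen:
            out[gene] = sum(seen) / len(seen)
    return out


def tails_oracle(sv: dict[str, float], n_tail: int) -> tuple[set, set]:
    """(robust, sensitive) gene sets by full sort with (sv, symbol) keys."""
    order = sorted(sv, key=lambda g: (sv[g], g))
    return set(order[:n_tail]), set(order[-n_tail:])


def round_half_up_oracle(x: float) -> int:
    return math.floor(x + 0.5)


def hypergeom_upper_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k), X ~ Hypergeom(N, K, n), by exact rational PMF summation."""
    total = Fraction(0)
    denom = math.comb(N, K)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(n, j) * math.comb(N - n, K - j), denom)
    return float(total)


def hypergeom_enumeration_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by literally enumerating all C(N, K) tail draws (tiny N only)."""
    group = set(range(n))
    hits = 0
    total = 0
    for tail in itertools.combinations(range(N), K):
        total += 1
        if len(group.intersection(tail)) >= k:
            hits += 1
    return hits / total
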