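"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own probability code: tail
probabilities are obtained by exhaustively enumerating every n-subset of an
N-element urn with exact Fraction arithmetic.
"""

from fractions import Fraction
from itertools import combinations


def enumerate_overlap_distribution(N: int, K: int, n: int) -> dict[int, Fraction]:
    """Exact P(|draw ∩ marked| = k) by enumerating all C(N, n) draws."""
    marked = set(range(K))
    total = 0
    counts: dict[int, int] = {}
    for draw in combinations(range(N), n):
        k = sum(1 for x in draw if x in marked)
        counts[k] = counts.get(k, 0) + 1
        total += 1
    return {k: Fraction(c, total) for k, c in counts.items()}


def enumerated_tail(N: int, K: int, n: int, k: int, direction: str) -> Fraction:
    dist = enumerate_overlap_distribution(N, K, n)
    if direction == "over":
        return sum((p for kk, p in dist.items() if kk >= k), Fraction(0))
    return sum((p for kk, p in dist.items() if kk <= k), Fraction(0))
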