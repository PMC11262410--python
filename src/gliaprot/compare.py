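"""Overlap significance between gene lists and multi-set intersection tables.

The overlap test is the upper hypergeometric tail on |A intersect B| given an
explicit universe — the universe is always a required argument because the
appropriate background differs between analyses and is never inferred.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enrichment import hypergeom_tail

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Significance of the overlap of two gene sets within a universe."""

    overlap: int
    size_a: int
    size_b: int
    universe: int
    expected: float
    p_over: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.size_a, self.size_b):
            raise ValueError("overlap exceeds set sizes")


def overlap_significance(set_a: Iterable[str], set_b: Iterable[str],
                         universe: Iterable[str]) -> OverlapResult:
    """Upper-tail hypergeometric probability of the observed overlap.

    Genes outside the universe are dropped (logged).  Symmetric in A and B.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = frozenset(set_a), frozenset(set_b)
    for label, s in (("A", a), ("B", b)):
        outside = len(s - universe)
        if outside:
            logger.info("overlap_significance: dropped %d genes of set %s outside universe",
                        outside, label)
    a &= universe
    b &= universe
    k = len(a & b)
    N, K, n = len(universe), len(a), len(b)
    expected = K * n / N
    p = hypergeom_tail(k, N, K, n, direction="over")
    return OverlapResult(overlap=k, size_a=K, size_b=n, universe=N,
                         expected=expected, p_over=p)


@dataclass
class MembershipReport:
    """Per-gene membership of an ordered query list in a predicted set."""

    table: pd.DataFrame  # columns: gene, predicted ("Yes"/"No")
    hits: int
    total: int
    percentage: float    # rounded to 2 decimals; 0 with undefined=True for empty query
    undefined: bool = False


def membership_report(query_genes: Sequence[str],
                      predicted: Iterable[str]) -> MembershipReport:
    """Tabulate which query genes fall in the predicted set.

    Returns the per-gene Yes/No table in query order plus (hits, total,
    percentage rounded to two decimals).  An empty query yields percentage 0
    with the ``undefined`` flag set.
    """
    predicted = frozenset(predicted)
    rows = [{"gene": g, "predicted": "Yes" if g in predicted else "No"}
            for g in query_genes]
    table = pd.DataFrame(rows, columns=["gene", "predicted"])
    hits = int((table["predicted"] == "Yes").sum()) if rows else 0
    total = len(rows)
    if total == 0:
        return MembershipReport(table, 0, 0, 0.0, undefined=True)
    return MembershipReport(table, hits, total, round(100.0 * hits / total, 2))


@dataclass
class IntersectionTable:
    """Exclusive-region counts for every non-empty subset of set labels."""

    exclusive_counts: dict[frozenset[str], int]
    jaccard: pd.DataFrame  # labels x labels pairwise Jaccard indices

    def count(self, *labels: str) -> int:
        return self.exclusive_counts.get(frozenset(labels), 0)

    @property
    def total(self) -> int:
        return sum(self.exclusive_counts.values())


def intersect_multi(named_sets: Mapping[str, Iterable[str]]) -> IntersectionTable:
    """Exclusive intersection counts (upset-style) plus pairwise Jaccard indices."""
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    sets = {label: frozenset(genes) for label, genes in named_sets.items()}
    labels = list(sets)
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = frozenset(combo)
            region = frozenset.intersection(*(sets[l] for l in combo))
            for other in labels:
                if other not in inside:
                    region -= sets[other]
            counts[inside] = len(region)
    jac = pd.DataFrame(1.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        union = sets[a] | sets[b]
        j = len(sets[a] & sets[b]) / len(union) if union else 1.0
        jac.loc[a, b] = jac.loc[b, a] = j
    return IntersectionTable(counts, jac)
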