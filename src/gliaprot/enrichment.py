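"""Exact hypergeometric over/under-representation statistics.

The probability machinery is authored here in log-space (log-binomials via
``scipy.special.gammaln``, tails via ``logsumexp``), so p-values are exact,
never NaN, and clamped to [0, 1].  On top of it sit: term enrichment with
Bonferroni (default) or Benjamini-Hochberg correction, the significance
filter (fold change strictly > 1.5, adjusted p strictly < 0.01), Wang
graph-based semantic-similarity simplification of redundant ontology terms,
and a Reactome-style roll-up of terms to top-level and sub-pathways.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import GeneSetCollection, OntologyDAG, Relation

logger = logging.getLogger(__name__)

DEFAULT_MIN_FOLD = 1.5     # strict >
DEFAULT_MAX_P_ADJ = 0.01   # strict <


# ---------------------------------------------------------------------------
# Hypergeometric core
# ---------------------------------------------------------------------------

def _check_args(k: int, N: int, K: int, n: int) -> None:
    for name, v in (("k", k), ("N", N), ("K", K), ("n", n)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if k < 0:
        raise ValueError(f"need k >= 0, got k={k}")


def _log_comb(a: int, b: int) -> float:
    if b < 0 or b > a:
        return -math.inf
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeom(N, K, n): C(K,k) C(N-K,n-k) / C(N,n)."""
    _check_args(k, N, K, n)
    log_p = _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)
    if log_p == -math.inf:
        return 0.0
    return min(1.0, math.exp(log_p))


def hypergeom_tail(k: int, N: int, K: int, n: int, direction: str = "over") -> float:
    """Exact tail probability: P(X >= k) for "over", P(X <= k) for "under"."""
    _check_args(k, N, K, n)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    if direction == "over":
        if k <= lo:
            return 1.0  # tail covers the whole support
        ks = range(max(k, lo), hi + 1)
    elif direction == "under":
        if k >= hi:
            return 1.0
        ks = range(lo, min(k, hi) + 1)
    else:
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    ks = list(ks)
    if not ks:
        # empty tail: k beyond the support on the relevant side
        return 0.0 if (direction == "over" and k > hi) or (direction == "under" and k < lo) else 1.0
    log_terms = [_log_comb(K, j) + _log_comb(N - K, n - j) for j in ks]
    log_p = float(logsumexp(log_terms)) - _log_comb(N, n)
    return float(min(1.0, max(0.0, math.exp(log_p))))


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """One term's over/under-representation statistics."""

    term_id: str
    term_name: str
    k: int            # query genes annotated to the term
    n: int            # query size
    K: int            # background genes annotated to the term
    N: int            # background size
    fold_change: float
    p_raw: float
    p_adj: float
    direction: str

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"{self.term_id}: invalid k={self.k}")
        if not (self.k <= self.n <= self.N and self.K <= self.N):
            raise ValueError(f"{self.term_id}: inconsistent counts")
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError(f"{self.term_id}: p_adj < p_raw")


def enrich(query: Iterable[str], background: Iterable[str],
           annotation: GeneSetCollection, direction: str = "over",
           correction: str = "bonferroni") -> list[EnrichmentResult]:
    """Hypergeometric over/under-representation of every annotated term.

    Query genes outside the background are dropped (with a logged count) and
    term memberships are intersected with the background.  Only terms with
    K >= 1 after intersection are tested, and only those count toward the
    correction factor m.  ``correction`` is "bonferroni" (default, p_adj =
    min(1, m * p)) or "bh" (Benjamini-Hochberg via statsmodels).
    """
    background = frozenset(background)
    if not background:
        raise ValueError("empty background")
    query_all = frozenset(query)
    query_set = query_all & background
    dropped = len(query_all) - len(query_set)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the background", dropped)
    if not query_set:
        raise ValueError("query is empty after intersection with the background")
    n, N = len(query_set), len(background)

    tested: list[tuple[str, str, int, int, float, float]] = []
    for term_id in annotation:
        members = annotation.members(term_id) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        p = hypergeom_tail(k, N, K, n, direction=direction)
        fold = (k / n) / (K / N)
        tested.append((term_id, annotation.description(term_id), k, K, fold, p))
    m = len(tested)
    if m == 0:
        return []
    p_raws = np.array([t[5] for t in tested])
    if correction == "bonferroni":
        p_adjs = np.minimum(1.0, m * p_raws)
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests
        p_adjs = multipletests(p_raws, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    results = [EnrichmentResult(term_id, name, k, n, K, N, fold, p, float(p_adj), direction)
               for (term_id, name, k, K, fold, p), p_adj in zip(tested, p_adjs)]
    return sorted(results, key=lambda r: (r.p_adj, r.p_raw, r.term_id))


def significant(results: Sequence[EnrichmentResult],
                min_fold: float = DEFAULT_MIN_FOLD,
                max_p_adj: float = DEFAULT_MAX_P_ADJ) -> list[EnrichmentResult]:
    """Apply the strict significance filter.

    Over-representation: fold_change strictly > ``min_fold`` AND p_adj
    strictly < ``max_p_adj``.  Under-representation: the fold criterion flips
    to fold_change strictly < 1/``min_fold``.
    """
    out = []
    for r in results:
        if r.p_adj >= max_p_adj:
            continue
        if r.direction == "over" and r.fold_change > min_fold:
            out.append(r)
        elif r.direction == "under" and r.fold_change < 1.0 / min_fold:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Wang semantic similarity and term simplification
# ---------------------------------------------------------------------------

@dataclass
class SimilarityConfig:
    """Wang graph-based similarity settings: edge weights and merge cutoff."""

    method: str = "wang"
    weights: dict[Relation, float] = field(
        default_factory=lambda: {Relation.IS_A: 0.8, Relation.PART_OF: 0.6})
    cutoff: float = 0.7

    def __post_init__(self) -> None:
        if self.method != "wang":
            raise ValueError(f"unknown similarity method {self.method!r}")
        if not all(0 < w < 1 for w in self.weights.values()):
            raise ValueError("edge weights must lie in (0, 1)")
        if not (0 < self.cutoff <= 1):
            raise ValueError("cutoff must lie in (0, 1]")


def _s_values(term: str, dag: OntologyDAG, weights: dict[Relation, float]) -> dict[str, float]:
    """Wang S-values of a term over its ancestor closure.

    S(term) = 1; for an ancestor u, S(u) is the maximum over child edges of
    weight(relation) * S(child), i.e. the best-weighted path from u down to
    the term.
    """
    s = {term: 1.0}
    stack = [term]
    while stack:
        node = stack.pop()
        for parent, rel in dag.parents.get(node, []):
            cand = weights[rel] * s[node]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
                stack.append(parent)
    return s


def wang_similarity(t1: str, t2: str, dag: OntologyDAG,
                    cfg: SimilarityConfig | None = None) -> float:
    """Wang similarity in [0, 1]; 1 for identical terms, 0 with no shared ancestor."""
    cfg = cfg or SimilarityConfig()
    for t in (t1, t2):
        if t not in dag.terms:
            raise KeyError(f"unknown term {t!r}")
    if t1 == t2:
        return 1.0
    s1 = _s_values(t1, dag, cfg.weights)
    s2 = _s_values(t2, dag, cfg.weights)
    shared = set(s1) & set(s2)
    if not shared:
        return 0.0
    sim = sum(s1[u] + s2[u] for u in shared) / (sum(s1.values()) + sum(s2.values()))
    return min(1.0, sim)


def simplify_terms(results: Sequence[EnrichmentResult], dag: OntologyDAG,
                   cfg: SimilarityConfig | None = None) -> list[EnrichmentResult]:
    """Greedy redundancy removal among enriched terms.

    While any retained pair has similarity strictly greater than the cutoff,
    the member with the larger p_adj is dropped (ties: the larger term by K,
    then the lexicographically larger term ID).  The output is a subset of
    the input and no retained pair exceeds the cutoff.
    """
    cfg = cfg or SimilarityConfig()
    retained = {r.term_id: r for r in results}
    ids = sorted(retained)
    sim = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sim[(a, b)] = wang_similarity(a, b, dag, cfg)
    while True:
        offending = [pair for pair, s in sim.items()
                     if s > cfg.cutoff and pair[0] in retained and pair[1] in retained]
        if not offending:
            break
        # resolve pairs in lexicographic order: deterministic and
        # order-invariant regardless of the input result ordering
        a, b = min(offending)
        ra, rb = retained[a], retained[b]
        drop = max((ra, rb), key=lambda r: (r.p_adj, r.K, r.term_id))
        del retained[drop.term_id]
    return [r for r in results if r.term_id in retained]


# ---------------------------------------------------------------------------
# Hierarchy roll-up
# ---------------------------------------------------------------------------

def hierarchy_rollup(results: Sequence[EnrichmentResult], hierarchy: OntologyDAG,
                     ) -> list[tuple[EnrichmentResult, list[tuple[str, str]]]]:
    """Annotate each term with its (top-level pathway, sub-pathway) ancestors.

    The top-level pathway is the depth-0 ancestor (a root); the sub-pathway is
    the depth-1 ancestor on the path to that root.  Root terms map to
    themselves for both; a term with multiple root paths is annotated with
    every distinct pair.
    """
    out = []
    for r in results:
        if r.term_id not in hierarchy.terms:
            raise KeyError(f"term {r.term_id!r} is not in the hierarchy")
        pairs = sorted(_root_paths(r.term_id, hierarchy))
        out.append((r, pairs))
    return out


def _root_paths(term: str, hierarchy: OntologyDAG) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()

    def walk(node: str, path: list[str]) -> None:
        parents = hierarchy.parents.get(node, [])
        if not parents:  # node is a root
            full = path + [node]
            if len(full) == 1:
                pairs.add((node, node))
            else:
                pairs.add((node, full[-2]))  # (root, child-of-root on this path)
            return
        for parent, _ in parents:
            walk(parent, path + [node])

    walk(term, [])
    if not pairs:
        raise ValueError(f"term {term!r} has no path to a root")
    return pairs
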