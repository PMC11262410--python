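"""Single-cell cluster expression filtering.

Candidate genes survive when they are detected (nonzero count) in at least 5%
of the cells of any one of the specified glial clusters — the union-over-
clusters rule with an inclusive fraction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

#: Inclusive minimum fraction of a cluster's cells expressing a gene.
DEFAULT_MIN_FRACTION = 0.05

#: Default target clusters: the glial subtypes whose processes reach the
#: larval neuromuscular junction (ensheathing stands in for wrapping glia).
DEFAULT_TARGET_CLUSTERS = ("perineurial", "subperineurial", "ensheathing")


@dataclass
class ClusterExpressionFraction:
    """Gene x cluster matrix of fraction-of-cells-expressing, plus cluster sizes."""

    matrix: pd.DataFrame  # genes x clusters, values in [0, 1]
    cells_per_cluster: pd.Series  # cluster -> positive int

    def __post_init__(self) -> None:
        if ((self.matrix < 0) | (self.matrix > 1)).values.any():
            raise ValueError("expression fractions must lie in [0, 1]")
        if self.matrix.columns.has_duplicates:
            raise ValueError("duplicate cluster IDs")
        if (self.cells_per_cluster < 1).any():
            raise ValueError("clusters must contain at least one cell")

    @property
    def clusters(self) -> list[str]:
        return list(self.matrix.columns)


def expression_fraction(counts: pd.DataFrame, assignment: pd.Series,
                        min_count: int = 1) -> ClusterExpressionFraction:
    """Per-cluster fraction of cells expressing each gene.

    ``counts`` is a cells x genes non-negative matrix; ``assignment`` maps each
    cell to exactly one cluster.  "Expressed" in a cell means count >=
    ``min_count`` (default 1, i.e. any nonzero count — the standard
    nucleus-seq detection convention).
    """
    missing = [c for c in assignment.index if c not in counts.index]
    if missing:
        raise ValueError(f"cells in assignment missing from count matrix: {missing[:5]}")
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    detected = (counts.loc[assignment.index] >= min_count)
    grouped = detected.groupby(assignment.values).mean().T  # genes x clusters
    sizes = assignment.value_counts()
    sizes = sizes.loc[grouped.columns]
    return ClusterExpressionFraction(grouped, sizes)


def filter_by_cluster_expression(candidates: Iterable[str],
                                 fractions: ClusterExpressionFraction,
                                 clusters: Iterable[str] = DEFAULT_TARGET_CLUSTERS,
                                 min_fraction: float = DEFAULT_MIN_FRACTION,
                                 mode: str = "union") -> frozenset[str]:
    """Keep candidate genes expressed in the target clusters.

    With ``mode="union"`` (default) a gene survives when its expression
    fraction is >= ``min_fraction`` (inclusive) in ANY of the listed clusters;
    ``mode="intersection"`` requires all of them.  Candidate genes absent from
    the fraction matrix count as not expressed.
    """
    clusters = list(clusters)
    unknown = [c for c in clusters if c not in fractions.matrix.columns]
    if unknown:
        raise ValueError(
            f"unknown cluster IDs {unknown}; available: {fractions.clusters}")
    if mode not in {"union", "intersection"}:
        raise ValueError(f"unknown mode {mode!r}")
    candidates = frozenset(candidates)
    present = fractions.matrix.reindex(list(candidates), fill_value=0.0)[clusters]
    ok = (present >= min_fraction)
    keep = ok.any(axis=1) if mode == "union" else ok.all(axis=1)
    return frozenset(keep.index[keep])


def nonlocalized_complement(expressed: Iterable[str],
                            predicted: Iterable[str]) -> frozenset[str]:
    """Genes expressed in the target clusters but not predicted to localize.

    ``predicted`` must be a subset of ``expressed`` (both come from the same
    cluster filter, applied to the candidate list and to the full universe
    respectively).
    """
    expressed = frozenset(expressed)
    predicted = frozenset(predicted)
    stray = predicted - expressed
    if stray:
        raise ValueError(
            f"predicted genes not in the expressed universe: {sorted(stray)[:5]}")
    return expressed - predicted
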