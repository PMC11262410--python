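"""Confidence-scored ortholog mapping between species gene spaces.

Mapping keeps every (source, target) pair whose integer confidence score
meets an inclusive cutoff (>= 8 by default, the conventional high-confidence
DIOPT setting): one-to-many pairs fan out, many-to-one pairs OR-merge, and no
reciprocal-best filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import read_ortholog_tsv
from ._util import normalize_gene_id

#: Inclusive high-confidence ortholog score cutoff.
DEFAULT_MIN_SCORE = 8


@dataclass
class OrthologTable:
    """Scored cross-species gene pairs, deduplicated on (source, target) keeping max score."""

    rows: pd.DataFrame  # columns: source, target, score (int)

    def __post_init__(self) -> None:
        df = self.rows[["source", "target", "score"]].copy()
        df["score"] = df["score"].astype(int)
        if (df["score"] < 0).any():
            raise ValueError("ortholog scores must be non-negative")
        df = (df.sort_values("score", kind="stable")
                .drop_duplicates(["source", "target"], keep="last")
                .sort_index().reset_index(drop=True))
        self.rows = df
        if self.rows.empty:
            raise ValueError("empty ortholog table")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, int]]) -> "OrthologTable":
        df = pd.DataFrame(pairs, columns=["source", "target", "score"])
        df["source"] = df["source"].map(normalize_gene_id)
        df["target"] = df["target"].map(normalize_gene_id)
        return cls(df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologTable":
        return cls(read_ortholog_tsv(path))

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


@dataclass
class MappedSet:
    """Result of mapping a source gene set into the target species."""

    target_genes: frozenset[str]
    provenance: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    dropped_sources: frozenset[str] = frozenset()


def map_orthologs(source_genes: Iterable[str], table: OrthologTable,
                  min_score: int = DEFAULT_MIN_SCORE) -> MappedSet:
    """Map a source-species gene set to target genes via scored ortholog pairs.

    target set = { t : exists (s, t, score) with s in source_genes and
    score >= min_score }.  ``provenance`` records the supporting (source,
    score) pairs per target; ``dropped_sources`` lists source genes with no
    passing pair.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    sources = {normalize_gene_id(g) for g in source_genes}
    passing = table.rows[(table.rows["score"] >= min_score)
                         & table.rows["source"].isin(sources)]
    provenance: dict[str, list[tuple[str, int]]] = {}
    for row in passing.itertuples(index=False):
        provenance.setdefault(row.target, []).append((row.source, int(row.score)))
    mapped_sources = set(passing["source"])
    return MappedSet(target_genes=frozenset(provenance),
                     provenance={t: sorted(v) for t, v in provenance.items()},
                     dropped_sources=frozenset(sources - mapped_sources))


def background_universe(table: OrthologTable,
                        min_score: int = DEFAULT_MIN_SCORE) -> frozenset[str]:
    """All target genes participating in any pair with score >= min_score.

    The natural enrichment background: target-species genes that have a
    high-confidence ortholog at all, independent of any query.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    return frozenset(table.rows.loc[table.rows["score"] >= min_score, "target"])
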