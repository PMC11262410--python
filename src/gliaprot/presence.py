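"""Presence calling, cross-species harmonization, and consensus construction.

A transcript counts as *present* in a library when its expression exceeds a
TPM threshold (strictly greater than 10 by default) in at least one of that
library's localized-side samples.  Presence calls from all localized
libraries are stacked into a boolean gene x library matrix, and the consensus
set keeps genes called present in at least ``min_support`` libraries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import (Assay, Compartment, ExpressionLibrary, LibraryManifest,
                 LOCALIZED_COMPARTMENTS, QuantKind, counts_to_tpm)
from ._util import normalize_gene_id

logger = logging.getLogger(__name__)

#: Default presence cutoff: TPM strictly greater than 10.
DEFAULT_TPM_THRESHOLD = 10.0
#: Default consensus support: present in at least 7 of the localized libraries.
DEFAULT_MIN_SUPPORT = 7
#: Default translation support: present in all 4 TRAP libraries.
DEFAULT_MIN_TRAP = 4


@dataclass(frozen=True)
class SpeciesHomologBridge:
    """One-species-to-another gene pairs (e.g. rat -> mouse), OR-merged."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        pairs = frozenset((normalize_gene_id(s), normalize_gene_id(t)) for s, t in self.pairs)
        for s, t in pairs:
            if s == t:
                raise ValueError(f"bridge contains a self-pair {s!r}")
        object.__setattr__(self, "pairs", pairs)
        if not pairs:
            raise ValueError("empty species bridge")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SpeciesHomologBridge":
        return cls(frozenset(pairs))


def call_presence(library: ExpressionLibrary,
                  threshold: float = DEFAULT_TPM_THRESHOLD,
                  aggregate: str = "max") -> pd.Series:
    """Per-gene boolean presence calls for one library.

    A gene is present iff its aggregate TPM across the library's samples is
    strictly greater than ``threshold``.  The aggregate is the maximum by
    default ("detected in a library" is an existence claim); ``aggregate="mean"``
    is available for sensitivity analyses.
    """
    if library.manifest.quant_kind is QuantKind.COUNTS:
        library = counts_to_tpm(library)
    if library.values.shape[1] == 0:
        raise ValueError(f"library {library.manifest.library_id} has zero samples")
    if aggregate == "max":
        agg = library.values.max(axis=1)
    elif aggregate == "mean":
        agg = library.values.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    calls = agg > threshold
    calls.name = library.manifest.library_id
    return calls


def bridge_species(calls: pd.Series, bridge: SpeciesHomologBridge) -> pd.Series:
    """Convert presence calls from a source species gene space to the target.

    A target gene is present iff ANY mapped source gene is present (OR-merge);
    one-to-many pairs fan out.  Unmapped source genes are dropped and their
    count logged.
    """
    mapped_sources = {s for s, _ in bridge.pairs}
    unmapped = [g for g in calls.index if g not in mapped_sources]
    if unmapped:
        logger.info("bridge_species: dropped %d unmapped source genes", len(unmapped))
    target_calls: dict[str, bool] = {}
    by_source: dict[str, list[str]] = {}
    for s, t in bridge.pairs:
        by_source.setdefault(s, []).append(t)
    for source, present in calls.items():
        for target in by_source.get(source, ()):
            target_calls[target] = target_calls.get(target, False) or bool(present)
    out = pd.Series(target_calls, dtype=bool)
    out.name = calls.name
    return out.sort_index()


@dataclass
class PresenceMatrix:
    """Boolean gene x library presence calls in a harmonized gene space."""

    calls: pd.DataFrame  # genes x libraries, bool
    libraries: list[LibraryManifest]
    threshold_used: float

    def __post_init__(self) -> None:
        if self.threshold_used <= 0:
            raise ValueError("threshold_used must be > 0")
        lib_ids = [m.library_id for m in self.libraries]
        if list(self.calls.columns) != lib_ids:
            raise ValueError("presence matrix columns do not match library manifest order")

    def select(self, *, compartments: frozenset[Compartment] | None = None,
               assays: frozenset[Assay] | None = None) -> "PresenceMatrix":
        keep = [m for m in self.libraries
                if (compartments is None or m.compartment in compartments)
                and (assays is None or m.assay in assays)]
        return PresenceMatrix(self.calls[[m.library_id for m in keep]], keep,
                              self.threshold_used)

    @property
    def n_libraries(self) -> int:
        return len(self.libraries)


def presence_matrix(libraries: Sequence[ExpressionLibrary],
                    threshold: float = DEFAULT_TPM_THRESHOLD,
                    bridges: dict[str, SpeciesHomologBridge] | None = None,
                    aggregate: str = "max") -> PresenceMatrix:
    """Call presence per library and stack into a harmonized boolean matrix.

    ``bridges`` maps library_id -> homolog bridge for libraries whose gene
    space must first be converted to the target species (e.g. the rat study).
    Genes absent from a library's table are recorded as not-present there.
    """
    bridges = bridges or {}
    columns = []
    for lib in libraries:
        calls = call_presence(lib, threshold=threshold, aggregate=aggregate)
        if lib.manifest.library_id in bridges:
            calls = bridge_species(calls, bridges[lib.manifest.library_id])
        columns.append(calls)
    all_genes = sorted(set().union(*(c.index for c in columns)))
    mat = pd.concat([c.reindex(all_genes, fill_value=False) for c in columns], axis=1)
    return PresenceMatrix(mat.astype(bool), [lib.manifest for lib in libraries], threshold)


@dataclass
class ConsensusSet:
    """Per-gene support counts over localized libraries, with a derived member set."""

    support: pd.Series  # gene -> int
    n_libraries: int
    min_support_used: int

    def members(self, min_support: int | None = None) -> frozenset[str]:
        k = self.min_support_used if min_support is None else min_support
        return frozenset(self.support.index[self.support >= k])


def build_consensus(presence: PresenceMatrix,
                    min_support: int = DEFAULT_MIN_SUPPORT,
                    compartments: frozenset[Compartment] = LOCALIZED_COMPARTMENTS,
                    ) -> ConsensusSet:
    """Count per-gene support over localized-side libraries and threshold it.

    Only libraries whose compartment is in ``compartments`` vote; soma columns
    never count toward the consensus.
    """
    localized = presence.select(compartments=compartments)
    if min_support > localized.n_libraries:
        raise ValueError(
            f"min_support={min_support} exceeds the {localized.n_libraries} "
            f"localized libraries available")
    support = localized.calls.sum(axis=1).astype(int)
    support.name = "support"
    return ConsensusSet(support, localized.n_libraries, min_support)


def translated_subset(consensus_members: frozenset[str],
                      trap_presence: PresenceMatrix,
                      min_trap: int = DEFAULT_MIN_TRAP) -> frozenset[str]:
    """Consensus genes with evidence of local translation.

    Keeps consensus members present in at least ``min_trap`` of the TRAP
    (ribosome-bound) libraries.  Both the all-four and the at-least-three
    settings are meaningful; the default is all four.
    """
    trap = trap_presence.select(assays=frozenset({Assay.TRAP}))
    if min_trap > trap.n_libraries:
        raise ValueError(f"min_trap={min_trap} exceeds the {trap.n_libraries} TRAP libraries")
    support = trap.calls.sum(axis=1)
    translated = frozenset(support.index[support >= min_trap])
    return frozenset(consensus_members) & translated


def log2_fold_change(protrusion_tpm: float, soma_tpm: float,
                     pseudocount: float = 1.0) -> float:
    """log2((protrusion + eps) / (soma + eps)) with a pseudocount eps."""
    if protrusion_tpm < 0 or soma_tpm < 0:
        raise ValueError("TPM inputs must be non-negative")
    if pseudocount == 0 and (protrusion_tpm == 0 or soma_tpm == 0):
        raise ValueError("zero TPM with zero pseudocount is undefined")
    return math.log2((protrusion_tpm + pseudocount) / (soma_tpm + pseudocount))
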