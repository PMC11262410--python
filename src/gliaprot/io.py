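"""Readers, writers, and validated domain containers for every external format.

Formats handled: TSV expression / manifest / ortholog / fraction tables, GMT
gene-set collections, OBO ontologies, MTX single-cell matrices, and plain
one-ID-per-line gene lists.  All gene identifiers pass through
:func:`gliaprot._util.normalize_gene_id` on the way in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import obonet
import pandas as pd

from ._util import normalize_gene_id

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Library manifest
# ---------------------------------------------------------------------------

class Species(str, Enum):
    MOUSE = "mouse"
    RAT = "rat"


class Compartment(str, Enum):
    SOMA = "soma"
    PROTRUSION = "protrusion"
    MYELIN = "myelin"
    WHOLE_CELL = "whole_cell"


class Assay(str, Enum):
    TRANSCRIPTOME = "transcriptome"
    TRAP = "TRAP"


class QuantKind(str, Enum):
    TPM = "tpm"
    COUNTS = "counts"


#: Compartments that count as "localized side" (periphery) for consensus voting.
LOCALIZED_COMPARTMENTS = frozenset({Compartment.PROTRUSION, Compartment.MYELIN})


@dataclass(frozen=True)
class LibraryManifest:
    """Metadata for one sequencing library of the meta-analysis."""

    library_id: str
    study_label: str
    species: Species
    compartment: Compartment
    assay: Assay
    quant_kind: QuantKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species(self.species))
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        object.__setattr__(self, "assay", Assay(self.assay))
        object.__setattr__(self, "quant_kind", QuantKind(self.quant_kind))


MANIFEST_COLUMNS = ["library_id", "study_label", "species", "compartment", "assay", "quant_kind"]


def read_manifest(path: str | Path) -> list[LibraryManifest]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} is missing columns: {sorted(missing)}")
    entries = [LibraryManifest(**row[MANIFEST_COLUMNS].to_dict()) for _, row in df.iterrows()]
    ids = [e.library_id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate library_id values in manifest: {dupes}")
    return entries


def write_manifest(entries: Iterable[LibraryManifest], path: str | Path) -> None:
    rows = [{c: getattr(e, c).value if isinstance(getattr(e, c), Enum) else getattr(e, c)
             for c in MANIFEST_COLUMNS} for e in entries]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionLibrary:
    """One library's gene x sample quantification table plus its manifest entry.

    ``values`` is a genes x samples DataFrame of non-negative numbers (TPM or
    raw counts, per ``manifest.quant_kind``).  ``gene_lengths`` (base pairs) is
    required for counts -> TPM conversion.
    """

    manifest: LibraryManifest
    values: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] == 0:
            raise FormatError(f"library {self.manifest.library_id}: no sample columns")
        if (self.values.values < 0).any():
            bad = self.values[(self.values < 0).any(axis=1)].index[0]
            raise FormatError(
                f"library {self.manifest.library_id}: negative value for gene {bad}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(
                f"library {self.manifest.library_id}: duplicate gene IDs {dupes[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def _collapse_duplicates(df: pd.DataFrame, library_id: str) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the row with the maximum mean.

    Duplicates in public tables are usually re-annotations of the same locus,
    so the best-supported (highest-abundance) row is retained rather than
    summing fragments.
    """
    if not df.index.has_duplicates:
        return df
    n_before = len(df)
    means = df.mean(axis=1)
    # stable sort descending by mean, keep the first (= max-mean) row per gene,
    # then restore first-seen gene order
    df2 = df.iloc[means.to_numpy().argsort(kind="stable")[::-1]]
    df2 = df2[~df2.index.duplicated(keep="first")]
    df2 = df2.loc[list(dict.fromkeys(df.index))]
    logger.info("library %s: collapsed %d duplicate gene rows (kept max-mean)",
                library_id, n_before - len(df2))
    return df2


def read_expression_table(path: str | Path, manifest_entry: LibraryManifest,
                          gene_lengths: pd.Series | None = None) -> ExpressionLibrary:
    """Read a TSV with a gene-ID column followed by >=1 numeric sample columns.

    Gene IDs are normalized; duplicate rows are collapsed by keeping the one
    with the maximum mean value (logged).  Negative or non-numeric cells are a
    hard failure naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene-ID column and >=1 sample column")
    gene_col = df.columns[0]
    df[gene_col] = df[gene_col].map(normalize_gene_id)
    df = df.set_index(gene_col)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise FormatError(f"{path}: non-numeric value at gene {row!r}, column {col!r}")
        df[col] = numeric
    neg = df < 0
    if neg.values.any():
        row = df.index[neg.any(axis=1)][0]
        col = df.columns[neg.loc[row].values.nonzero()[0][0]] if neg.loc[row].any() else "?"
        raise FormatError(f"{path}: negative value at gene {row!r}, column {col!r}")
    df = _collapse_duplicates(df, manifest_entry.library_id)
    if gene_lengths is not None:
        gene_lengths = gene_lengths.copy()
        gene_lengths.index = [normalize_gene_id(g) for g in gene_lengths.index]
    return ExpressionLibrary(manifest_entry, df, gene_lengths)


def write_expression_table(library: ExpressionLibrary, path: str | Path,
                           gene_column: str = "gene_id") -> None:
    out = library.values.copy()
    out.index.name = gene_column
    out.to_csv(path, sep="\t")


def counts_to_tpm(library: ExpressionLibrary) -> ExpressionLibrary:
    """Convert a counts-quantified library to TPM.

    tpm_g = (count_g / length_g) / sum_j (count_j / length_j) * 1e6, per
    sample.  Requires a length for every gene.
    """
    if library.manifest.quant_kind is not QuantKind.COUNTS:
        raise ValueError(f"library {library.manifest.library_id} is not counts-quantified")
    if library.gene_lengths is None:
        raise FormatError(
            f"library {library.manifest.library_id}: counts->TPM needs gene lengths")
    lengths = library.gene_lengths.reindex(library.genes)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise FormatError(
            f"library {library.manifest.library_id}: missing lengths for genes "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    if (lengths <= 0).any():
        raise FormatError(f"library {library.manifest.library_id}: non-positive gene length")
    rate = library.values.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    manifest = LibraryManifest(library.manifest.library_id, library.manifest.study_label,
                               library.manifest.species, library.manifest.compartment,
                               library.manifest.assay, QuantKind.TPM)
    return ExpressionLibrary(manifest, tpm, library.gene_lengths)


def counts_to_cpm(library: ExpressionLibrary) -> ExpressionLibrary:
    """Counts-per-million fallback for counts libraries without gene lengths.

    cpm_g = count_g / Σ_j count_j × 10⁶ per sample.  Used with the same
    presence threshold as TPM when lengths are unavailable; callers should
    record the fallback in output provenance.
    """
    if library.manifest.quant_kind is not QuantKind.COUNTS:
        raise ValueError(f"library {library.manifest.library_id} is not counts-quantified")
    cpm = library.values.div(library.values.sum(axis=0), axis=1) * 1e6
    manifest = LibraryManifest(library.manifest.library_id, library.manifest.study_label,
                               library.manifest.species, library.manifest.compartment,
                               library.manifest.assay, QuantKind.TPM)
    return ExpressionLibrary(manifest, cpm, None)


# ---------------------------------------------------------------------------
# Gene sets (GMT) and plain gene lists
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT-shaped)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def add(self, set_id: str, description: str, members: Iterable[str]) -> None:
        members = frozenset(normalize_gene_id(m) for m in members)
        if not members:
            raise FormatError(f"gene set {set_id!r} is empty")
        self.sets[set_id] = (description, members)


def read_gmt(path: str | Path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs id, description, >=1 member")
            coll.add(parts[0], parts[1], parts[2:])
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in collection:
            desc, members = collection.sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a one-ID-per-line gene list; '#' starts a comment."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(normalize_gene_id(line))
    return frozenset(genes)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in sorted(genes)))


# ---------------------------------------------------------------------------
# Ontologies
# ---------------------------------------------------------------------------

class Relation(str, Enum):
    IS_A = "is_a"
    PART_OF = "part_of"


@dataclass
class OntologyDAG:
    """A rooted, acyclic ontology: terms plus child -> parent typed edges."""

    terms: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (name, namespace)
    parents: dict[str, list[tuple[str, Relation]]] = field(default_factory=dict)

    def add_term(self, term_id: str, name: str = "", namespace: str = "") -> None:
        self.terms[term_id] = (name, namespace)
        self.parents.setdefault(term_id, [])

    def add_edge(self, child: str, parent: str, relation: Relation = Relation.IS_A) -> None:
        for t in (child, parent):
            if t not in self.terms:
                raise FormatError(f"ontology edge endpoint {t!r} is not a declared term")
        self.parents.setdefault(child, []).append((parent, Relation(relation)))

    def validate(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"ontology contains a cycle through edge {cycle[0][0]}->{cycle[0][1]}")
        namespaces = {ns for _, ns in self.terms.values()}
        for ns in namespaces:
            if not any(self.is_root(t) for t, (_, t_ns) in self.terms.items() if t_ns == ns):
                raise FormatError(f"ontology namespace {ns!r} has no root term")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for parent, rel in ps:
                g.add_edge(child, parent, relation=rel.value)
        return g

    def is_root(self, term_id: str) -> bool:
        return not self.parents.get(term_id)

    def roots(self) -> list[str]:
        return [t for t in self.terms if self.is_root(t)]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id][1]

    def ancestors(self, term_id: str) -> set[str]:
        """All ancestors of a term, including the term itself."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        seen = {term_id}
        stack = [term_id]
        while stack:
            for parent, _ in self.parents.get(stack.pop(), []):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen


def read_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO file ([Term] stanzas with id/name/namespace/is_a/part_of).

    Cyclic input is rejected with an error naming one cycle edge.
    """
    graph = obonet.read_obo(path)
    dag = OntologyDAG()
    for node, data in graph.nodes(data=True):
        dag.add_term(node, data.get("name", ""), data.get("namespace", ""))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent, Relation.IS_A)
        elif key == "part_of":
            dag.add_edge(child, parent, Relation.PART_OF)
    dag.validate()
    return dag


def write_obo(dag: OntologyDAG, path: str | Path, ontology_name: str = "synthetic") -> None:
    with open(path, "w") as fh:
        fh.write(f"format-version: 1.2\nontology: {ontology_name}\n")
        for term_id in dag.terms:
            name, namespace = dag.terms[term_id]
            fh.write(f"\n[Term]\nid: {term_id}\nname: {name}\n")
            if namespace:
                fh.write(f"namespace: {namespace}\n")
            for parent, rel in dag.parents.get(term_id, []):
                if rel is Relation.IS_A:
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def read_parent_child_table(path: str | Path) -> OntologyDAG:
    """Read a child<TAB>parent[<TAB>relation] hierarchy table (Reactome-style)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                     names=["child", "parent", "relation"])
    dag = OntologyDAG()
    for _, row in df.iterrows():
        for t in (row["child"], row["parent"]):
            if t not in dag.terms:
                dag.add_term(t, t)
    for _, row in df.iterrows():
        rel = Relation(row["relation"]) if isinstance(row["relation"], str) else Relation.IS_A
        dag.add_edge(row["child"], row["parent"], rel)
    dag.validate()
    return dag


# ---------------------------------------------------------------------------
# Single-cell inputs
# ---------------------------------------------------------------------------

def read_mtx_counts(mtx_path: str | Path, genes_path: str | Path,
                    cells_path: str | Path) -> pd.DataFrame:
    """Read an MTX count matrix (genes x cells on disk) into a cells x genes frame."""
    from scipy.io import mmread

    matrix = mmread(str(mtx_path)).tocsr()
    genes = [normalize_gene_id(g) for g in Path(genes_path).read_text().split()]
    cells = Path(cells_path).read_text().split()
    if matrix.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx_path}: matrix shape {matrix.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells")
    return pd.DataFrame(matrix.T.toarray(), index=cells, columns=genes)


def read_cluster_assignment(path: str | Path) -> pd.Series:
    """Read a cell<TAB>cluster assignment table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected cell and cluster columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="cluster")


def read_fraction_table(path: str | Path) -> pd.DataFrame:
    """Read a precomputed gene x cluster expression-fraction table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_gene_id(g) for g in df.index]
    if ((df < 0) | (df > 1)).values.any():
        raise FormatError(f"{path}: fractions must lie in [0, 1]")
    return df


# ---------------------------------------------------------------------------
# Ortholog tables (parsing only; semantics live in gliaprot.orthology)
# ---------------------------------------------------------------------------

def read_ortholog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected source, target, score columns")
    df.columns = ["source", "target", "score", *df.columns[3:]]
    df["source"] = df["source"].map(normalize_gene_id)
    df["target"] = df["target"].map(normalize_gene_id)
    df["score"] = pd.to_numeric(df["score"], errors="raise").astype(int)
    if (df["score"] < 0).any():
        raise FormatError(f"{path}: negative ortholog confidence score")
    return df[["source", "target", "score"]]
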