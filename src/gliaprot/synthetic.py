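"""Seeded generator of a complete benchmark bundle with planted ground truth.

The bundle emulates every input the prediction pipeline consumes: eleven
localized-side expression libraries (seven transcriptome, of which one is in
a shifted "rat" gene space with a homolog bridge and one is counts-quantified
with gene lengths; four TRAP), a scored ortholog table, a single-nucleus MTX
count matrix with cluster assignments, a GMT annotation with an OBO ontology
carrying ten planted enriched terms, and plain gene lists.  TPM magnitudes
are arbitrary — only the >10 presence semantics matter; each library's values
are drawn on the correct side of the threshold for its planted detection
call, so recovery noise comes from the per-library Bernoulli detection
probabilities, not from the value draws.

Ground truth is recorded alongside: the planted core (localized) mouse gene
set, the fly-space predicted set (core genes with a high-confidence ortholog,
planted as expressed in the target glial clusters), and the planted enriched
term IDs.  Fixed seed implies a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .celltype import DEFAULT_TARGET_CLUSTERS
from .io import (Assay, Compartment, GeneSetCollection, LibraryManifest,
                 OntologyDAG, QuantKind, Relation, Species, write_gene_list,
                 write_gmt, write_manifest, write_obo)
from .orthology import OrthologTable, background_universe

DECOY_CLUSTERS = ("astrocyte_like", "cortex")


@dataclass
class SyntheticConfig:
    """Generation parameters for the benchmark bundle."""

    seed: int = 0
    n_genes_source: int = 4000
    n_transcriptome: int = 7
    n_trap: int = 4
    core_fraction: float = 0.15
    p_detect_core: float = 0.95
    p_detect_bg: float = 0.25
    # natural-log-scale lognormal for TPM values, truncated to the planted
    # side of the presence threshold
    tpm_mu_present: float = 4.0
    tpm_mu_absent: float = 1.0
    tpm_sigma: float = 0.8
    # orthology
    fraction_with_ortholog: float = 0.8
    p_high_score: float = 0.85
    high_score_range: tuple[int, int] = (8, 15)
    low_score_range: tuple[int, int] = (1, 7)
    fanout_prob: float = 0.1
    # single-cell clusters
    cells_per_cluster: int = 200
    expressed_beta: tuple[float, float] = (8.0, 2.0)
    background_beta: tuple[float, float] = (1.0, 30.0)
    # ontology / annotation
    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 200)
    n_planted_enriched: int = 10
    planted_odds_ratio: float = 5.0
    # noise-free mode: detection is perfect and cluster fractions are
    # deterministic, so the pipeline must recover the planted truth exactly
    noise_free: bool = False

    def __post_init__(self) -> None:
        for name in ("core_fraction", "p_detect_core", "p_detect_bg",
                     "fraction_with_ortholog", "p_high_score", "fanout_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.n_genes_source < 10:
            raise ValueError("n_genes_source too small")
        if self.term_size_range[1] > self.n_genes_source:
            raise ValueError("term sizes exceed the gene universe")
        if self.noise_free:
            self.p_detect_core = 1.0
            self.p_detect_bg = 0.0
            self.tpm_sigma = 0.0


@dataclass
class TruthBundle:
    """Planted ground truth for a generated bundle."""

    planted_core: frozenset[str]
    planted_predicted: frozenset[str]
    planted_enriched_terms: frozenset[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "planted_core": sorted(self.planted_core),
            "planted_predicted": sorted(self.planted_predicted),
            "planted_enriched_terms": sorted(self.planted_enriched_terms),
        }, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        d = json.loads(Path(path).read_text())
        return cls(frozenset(d["planted_core"]), frozenset(d["planted_predicted"]),
                   frozenset(d["planted_enriched_terms"]))


@dataclass
class Bundle:
    """Paths and in-memory handles of a generated benchmark bundle."""

    out_dir: Path
    config: SyntheticConfig
    truth: TruthBundle
    manifest: list[LibraryManifest]
    ortholog_table: OrthologTable
    fly_universe: frozenset[str]
    paths: dict[str, Path] = field(default_factory=dict)


def _draw_side(rng: np.random.Generator, n: int, mu: float, sigma: float,
               above: bool, threshold: float = 10.0) -> np.ndarray:
    """Lognormal draws constrained to one side of the presence threshold."""
    if sigma == 0.0:
        return np.full(n, np.exp(mu))
    vals = rng.lognormal(mu, sigma, size=n)
    for _ in range(40):
        bad = (vals <= threshold) if above else (vals > threshold)
        if not bad.any():
            break
        vals[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    # safety clamp for any draw the rejection loop did not fix
    if above:
        vals = np.maximum(vals, threshold * 1.01)
    else:
        vals = np.minimum(vals, threshold * 0.99)
    return vals


def generate_bundle(cfg: SyntheticConfig, out_dir: str | Path) -> Bundle:
    """Generate the full benchmark bundle on disk; deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- gene spaces and planted core -------------------------------------
    mouse_genes = np.array([f"MMUG{i:05d}" for i in range(cfg.n_genes_source)])
    n_core = int(round(cfg.core_fraction * cfg.n_genes_source))
    core = frozenset(rng.choice(mouse_genes, size=n_core, replace=False))
    rat_of = {m: f"RNOG{i:05d}" for i, m in enumerate(mouse_genes)}

    # --- manifest ----------------------------------------------------------
    manifest: list[LibraryManifest] = []
    for i in range(cfg.n_transcriptome):
        lib_id = f"lib{i + 1:02d}"
        species = Species.RAT if i == 0 else Species.MOUSE
        compartment = Compartment.MYELIN if i == 2 else Compartment.PROTRUSION
        quant = QuantKind.COUNTS if i == 3 else QuantKind.TPM
        manifest.append(LibraryManifest(lib_id, f"study{i + 1}", species,
                                        compartment, Assay.TRANSCRIPTOME, quant))
    for j in range(cfg.n_trap):
        lib_id = f"lib{cfg.n_transcriptome + j + 1:02d}"
        manifest.append(LibraryManifest(lib_id, f"trap_study{j + 1}", Species.MOUSE,
                                        Compartment.PROTRUSION, Assay.TRAP, QuantKind.TPM))
    paths["manifest"] = out_dir / "manifest.tsv"
    write_manifest(manifest, paths["manifest"])

    # --- planted per-library detection calls -------------------------------
    is_core = np.isin(mouse_genes, list(core))
    p = np.where(is_core, cfg.p_detect_core, cfg.p_detect_bg)
    detect = rng.random((cfg.n_genes_source, len(manifest))) < p[:, None]

    # --- expression tables --------------------------------------------------
    for col, entry in enumerate(manifest):
        calls = detect[:, col]
        n_samples = 2
        if entry.quant_kind is QuantKind.COUNTS:
            values = _counts_library(rng, calls, n_samples)
            lengths = pd.Series(rng.integers(500, 5000, size=cfg.n_genes_source),
                                index=mouse_genes, name="length")
            counts = np.rint(values * lengths.to_numpy()[:, None] / 1e3).astype(int)
            df = pd.DataFrame(counts, index=mouse_genes,
                              columns=[f"s{j + 1}" for j in range(n_samples)])
            paths[f"lengths_{entry.library_id}"] = out_dir / f"lengths_{entry.library_id}.tsv"
            lengths.rename_axis("gene_id").to_frame().to_csv(
                paths[f"lengths_{entry.library_id}"], sep="\t")
        else:
            present = _draw_side(rng, calls.sum() * n_samples,
                                 cfg.tpm_mu_present, cfg.tpm_sigma, above=True)
            absent = _draw_side(rng, (~calls).sum() * n_samples,
                                cfg.tpm_mu_absent, cfg.tpm_sigma, above=False)
            values = np.empty((cfg.n_genes_source, n_samples))
            values[calls] = present.reshape(-1, n_samples)
            values[~calls] = absent.reshape(-1, n_samples)
            ids = mouse_genes if entry.species is Species.MOUSE else \
                np.array([rat_of[m] for m in mouse_genes])
            df = pd.DataFrame(np.round(values, 4), index=ids,
                              columns=[f"s{j + 1}" for j in range(n_samples)])
        df.index.name = "gene_id"
        paths[f"expr_{entry.library_id}"] = out_dir / f"expr_{entry.library_id}.tsv"
        df.to_csv(paths[f"expr_{entry.library_id}"], sep="\t")

    # --- rat -> mouse bridge ------------------------------------------------
    bridge_df = pd.DataFrame({"source": [rat_of[m] for m in mouse_genes],
                              "target": mouse_genes})
    paths["bridge"] = out_dir / "bridge_rat_mouse.tsv"
    bridge_df.to_csv(paths["bridge"], sep="\t", index=False)

    # --- ortholog table -----------------------------------------------------
    rows: list[tuple[str, str, int]] = []
    fly_counter = 0
    for m in mouse_genes:
        if rng.random() >= cfg.fraction_with_ortholog:
            continue
        n_targets = 2 if rng.random() < cfg.fanout_prob else 1
        for _ in range(n_targets):
            target = f"FBSYN{fly_counter:05d}"
            fly_counter += 1
            if rng.random() < cfg.p_high_score:
                score = int(rng.integers(cfg.high_score_range[0], cfg.high_score_range[1] + 1))
            else:
                score = int(rng.integers(cfg.low_score_range[0], cfg.low_score_range[1] + 1))
            rows.append((m, target, score))
    ortho = OrthologTable.from_pairs(rows)
    paths["orthologs"] = out_dir / "orthologs.tsv"
    ortho.to_tsv(paths["orthologs"])
    fly_universe = background_universe(ortho, min_score=8)

    # planted predicted set: high-confidence fly targets of core mouse genes
    high = ortho.rows[ortho.rows["score"] >= 8]
    planted_predicted = frozenset(high.loc[high["source"].isin(core), "target"])

    # --- single-cell counts -------------------------------------------------
    fly_genes = sorted({t for _, t, _ in rows})
    clusters = list(DEFAULT_TARGET_CLUSTERS) + list(DECOY_CLUSTERS)
    n_cells = cfg.cells_per_cluster * len(clusters)
    cell_ids = [f"cell{c:05d}" for c in range(n_cells)]
    assignment = np.repeat(clusters, cfg.cells_per_cluster)
    counts = np.zeros((n_cells, len(fly_genes)), dtype=np.int32)
    in_pred = np.isin(fly_genes, list(planted_predicted))
    for ci, cluster in enumerate(clusters):
        rows_slice = slice(ci * cfg.cells_per_cluster, (ci + 1) * cfg.cells_per_cluster)
        planted_here = in_pred & (cluster in DEFAULT_TARGET_CLUSTERS)
        if cfg.noise_free:
            frac = np.where(planted_here, 0.8, 0.0)
            n_expr = np.rint(frac * cfg.cells_per_cluster).astype(int)
            expressed = np.zeros((cfg.cells_per_cluster, len(fly_genes)), dtype=bool)
            for gi, ne in enumerate(n_expr):
                expressed[:ne, gi] = True
        else:
            a_hi, b_hi = cfg.expressed_beta
            a_lo, b_lo = cfg.background_beta
            frac = np.where(planted_here,
                            rng.beta(a_hi, b_hi, size=len(fly_genes)),
                            rng.beta(a_lo, b_lo, size=len(fly_genes)))
            expressed = rng.random((cfg.cells_per_cluster, len(fly_genes))) < frac
        counts[rows_slice][expressed] = rng.poisson(2.0, size=int(expressed.sum())) + 1
    _write_mtx(counts, fly_genes, cell_ids, assignment, out_dir, paths)

    # --- ontology and annotation -------------------------------------------
    annotation, dag, planted_terms = _make_annotation(
        rng, cfg, sorted(fly_universe), planted_predicted)
    paths["annotation"] = out_dir / "annotation.gmt"
    write_gmt(annotation, paths["annotation"])
    paths["ontology"] = out_dir / "ontology.obo"
    write_obo(dag, paths["ontology"])

    # --- comparison gene lists ---------------------------------------------
    universe_list = sorted(fly_universe)
    pred_list = sorted(planted_predicted & fly_universe)
    n_pos = min(200, len(pred_list))
    positive = list(rng.choice(pred_list, size=n_pos, replace=False)) + \
        list(rng.choice(universe_list, size=50, replace=False))
    random_list = list(rng.choice(universe_list, size=min(250, len(universe_list)),
                                  replace=False))
    # fifteen-gene query mirroring the smFISH validation layout: 11 planted, 4 not
    non_pred = sorted(fly_universe - planted_predicted)
    query15 = list(rng.choice(pred_list, size=11, replace=False)) + \
        list(rng.choice(non_pred, size=4, replace=False))
    paths["genelist_positive"] = out_dir / "genelist_positive.txt"
    write_gene_list(set(positive), paths["genelist_positive"])
    paths["genelist_random"] = out_dir / "genelist_random.txt"
    write_gene_list(set(random_list), paths["genelist_random"])
    paths["query15"] = out_dir / "query15.txt"
    Path(paths["query15"]).write_text("".join(g + "\n" for g in query15))

    truth = TruthBundle(core, planted_predicted, planted_terms)
    paths["truth"] = out_dir / "truth.json"
    truth.to_json(paths["truth"])
    return Bundle(out_dir, cfg, truth, manifest, ortho, fly_universe, paths)


def _counts_library(rng: np.random.Generator, calls: np.ndarray,
                    n_samples: int) -> np.ndarray:
    """Per-sample TPM-scale values for the counts-quantified library.

    Values are constructed so each sample sums to ~1e6 while every present
    gene stays well above and every absent gene well below the threshold,
    surviving the round trip through counts -> TPM conversion.
    """
    n = len(calls)
    out = np.empty((n, n_samples))
    for s in range(n_samples):
        lo = rng.uniform(0.5, 5.0, size=n)
        hi = rng.lognormal(np.log(700.0), 0.2, size=n)
        vals = np.where(calls, hi, lo)
        out[:, s] = vals * (1e6 / vals.sum())
    return out


def _write_mtx(counts: np.ndarray, genes: list[str], cells: list[str],
               assignment: np.ndarray, out_dir: Path, paths: dict[str, Path]) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    paths["sc_mtx"] = out_dir / "sc_counts.mtx"
    # stored genes x cells, the market-standard orientation for DGE matrices
    mmwrite(str(paths["sc_mtx"]), csr_matrix(counts.T), field="integer")
    paths["sc_genes"] = out_dir / "sc_genes.txt"
    Path(paths["sc_genes"]).write_text("".join(g + "\n" for g in genes))
    paths["sc_cells"] = out_dir / "sc_cells.txt"
    Path(paths["sc_cells"]).write_text("".join(c + "\n" for c in cells))
    paths["sc_clusters"] = out_dir / "sc_clusters.tsv"
    pd.DataFrame({"cell": cells, "cluster": assignment}).to_csv(
        paths["sc_clusters"], sep="\t", index=False)


def _make_annotation(rng: np.random.Generator, cfg: SyntheticConfig,
                     universe: list[str], planted_predicted: frozenset[str],
                     ) -> tuple[GeneSetCollection, OntologyDAG, frozenset[str]]:
    """Annotation terms over the fly universe, with planted enriched terms.

    Planted terms sample members with ``planted_odds_ratio`` : 1 odds in
    favor of the planted predicted genes; decoy terms sample uniformly.  The
    ontology places all terms under ten branch nodes below a single root so
    that semantic similarity and roll-up have structure to work with.
    """
    dag = OntologyDAG()
    root = "SYN:ROOT"
    dag.add_term(root, "synthetic process root", "synthetic_process")
    branches = []
    for b in range(10):
        bid = f"SYN:B{b:02d}"
        dag.add_term(bid, f"branch {b}", "synthetic_process")
        dag.add_edge(bid, root, Relation.IS_A)
        branches.append(bid)

    in_pred = np.isin(universe, sorted(planted_predicted))
    weights_planted = np.where(in_pred, cfg.planted_odds_ratio, 1.0)
    weights_planted = weights_planted / weights_planted.sum()
    universe_arr = np.array(universe)

    coll = GeneSetCollection()
    planted_ids = []
    for t in range(cfg.n_terms):
        term_id = f"SYN:{t:04d}"
        size = int(rng.integers(cfg.term_size_range[0], cfg.term_size_range[1] + 1))
        planted = t < cfg.n_planted_enriched
        if planted:
            members = rng.choice(universe_arr, size=size, replace=False, p=weights_planted)
            planted_ids.append(term_id)
        else:
            members = rng.choice(universe_arr, size=size, replace=False)
        desc = "planted enriched term" if planted else "decoy term"
        coll.add(term_id, desc, members)
        dag.add_term(term_id, desc, "synthetic_process")
        dag.add_edge(term_id, branches[int(rng.integers(0, len(branches)))], Relation.IS_A)
    dag.validate()
    return coll, dag, frozenset(planted_ids)


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    f1: float
    undefined: bool = False


def evaluate_recovery(predicted: Iterable[str], truth: Iterable[str]) -> RecoveryScore:
    """Precision/recall/F1 of a predicted gene set against the planted truth.

    Empty-denominator cases return 0 for the affected metric with the
    ``undefined`` flag set.
    """
    predicted = frozenset(predicted)
    truth = frozenset(truth)
    tp = len(predicted & truth)
    undefined = not predicted or not truth
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return RecoveryScore(precision, recall, f1, undefined)


def generate_null_annotation(universe: Iterable[str], n_terms: int,
                             term_size_range: tuple[int, int],
                             seed: int) -> GeneSetCollection:
    """Annotation terms drawn uniformly from the universe, with no query association.

    A type-I-error harness: hypergeometric p-values of any query against these
    terms follow their null distribution.
    """
    universe = np.array(sorted(set(universe)))
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValueError(f"term size {hi} exceeds universe of {len(universe)}")
    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        coll.add(f"NULL:{t:05d}", "null term", rng.choice(universe, size=size, replace=False))
    return coll
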