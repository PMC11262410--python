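"""Config-driven orchestration of the full prediction pipeline.

Stages: presence calls -> cross-species harmonization -> consensus set ->
high-confidence ortholog mapping -> single-cell cluster expression filter ->
predicted localized set, followed by the statistics layer (term enrichment
with simplification and roll-up, overlap tests, membership report).  All
outputs are TSV/plain-text with JSON provenance sidecars plus a run manifest;
identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import celltype, compare, enrichment, orthology, presence
from .io import (ExpressionLibrary, FormatError, QuantKind, counts_to_cpm,
                 counts_to_tpm,
                 read_cluster_assignment, read_expression_table,
                 read_fraction_table, read_gene_list, read_gmt, read_manifest,
                 read_mtx_counts, read_obo, read_ortholog_tsv)
from ._util import sha256_file, write_provenance

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their conventional defaults.

    Senses: TPM strictly > threshold; support, ortholog score, and cluster
    fraction inclusive (>=); enrichment fold strictly > and adjusted p
    strictly <.
    """

    tpm_threshold: float = 10.0
    min_support: int = 7
    min_trap: int = 4
    min_ortholog_score: int = 8
    min_cluster_fraction: float = 0.05
    target_clusters: tuple[str, ...] = celltype.DEFAULT_TARGET_CLUSTERS
    cluster_mode: str = "union"
    min_fold: float = 1.5
    max_p_adj: float = 0.01
    correction: str = "bonferroni"
    similarity_cutoff: float = 0.7
    aggregate: str = "max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tpm_threshold <= 0:
            raise ValueError("tpm_threshold must be > 0")
        if self.min_support < 0 or self.min_trap < 0 or self.min_ortholog_score < 0:
            raise ValueError("support/score thresholds must be non-negative")
        if not (0 <= self.min_cluster_fraction <= 1):
            raise ValueError("min_cluster_fraction must lie in [0, 1]")
        self.target_clusters = tuple(self.target_clusters)


def load_config(path: str | Path) -> tuple[PipelineConfig, dict[str, Any]]:
    """Load a YAML run configuration: an ``inputs`` mapping plus ``params``."""
    doc = yaml.safe_load(Path(path).read_text())
    params = doc.get("params", {}) or {}
    cfg = PipelineConfig(**params)
    if "seed" in doc:
        cfg.seed = int(doc["seed"])
    inputs = doc.get("inputs", {}) or {}
    base = Path(path).parent
    return cfg, _resolve_paths(inputs, base)


def _resolve_paths(node: Any, base: Path) -> Any:
    """Resolve every string leaf of the inputs mapping relative to the config file."""
    if isinstance(node, str):
        p = Path(node)
        return p if p.is_absolute() else base / p
    if isinstance(node, Mapping):
        return {k: _resolve_paths(v, base) for k, v in node.items()}
    return node


def _require(inputs: Mapping[str, Any], key: str, stage: str) -> Any:
    if key not in inputs or inputs[key] is None:
        raise PipelineError(f"stage {stage}: required input {key!r} is missing")
    return inputs[key]


def run_pipeline(config: PipelineConfig, inputs: Mapping[str, Any],
                 out_dir: str | Path) -> Path:
    """Run every stage and write all outputs under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    cpm_fallback: list[str] = []

    # ---- stage: load expression libraries --------------------------------
    stage = "expression"
    try:
        manifest = read_manifest(_require(inputs, "manifest", stage))
        expr_paths = _require(inputs, "expression", stage)
        length_paths = inputs.get("gene_lengths", {}) or {}
        libraries: list[ExpressionLibrary] = []
        for entry in manifest:
            path = expr_paths.get(entry.library_id)
            if path is None:
                raise PipelineError(
                    f"stage {stage}: no expression table for library {entry.library_id}")
            lengths = None
            if entry.library_id in length_paths:
                ldf = pd.read_csv(length_paths[entry.library_id], sep="\t", index_col=0)
                lengths = ldf.iloc[:, 0]
            lib = read_expression_table(path, entry, gene_lengths=lengths)
            if entry.quant_kind is QuantKind.COUNTS:
                if lengths is None:
                    # no gene lengths supplied: CPM with the same threshold,
                    # recorded in the run manifest
                    lib = counts_to_cpm(lib)
                    cpm_fallback.append(entry.library_id)
                    logger.warning("library %s: no gene lengths; using CPM fallback",
                                   entry.library_id)
                else:
                    lib = counts_to_tpm(lib)
            libraries.append(lib)
    except (OSError, FormatError, ValueError) as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- stage: presence + consensus -------------------------------------
    stage = "consensus"
    try:
        bridges = {}
        for lib_id, bpath in (inputs.get("bridges", {}) or {}).items():
            pairs = pd.read_csv(bpath, sep="\t")
            bridges[lib_id] = presence.SpeciesHomologBridge.from_pairs(
                zip(pairs.iloc[:, 0], pairs.iloc[:, 1]))
        matrix = presence.presence_matrix(libraries, threshold=config.tpm_threshold,
                                          bridges=bridges, aggregate=config.aggregate)
        consensus = presence.build_consensus(matrix, min_support=config.min_support)
        members = consensus.members()
        counts["consensus"] = len(members)
        support_df = consensus.support.rename_axis("gene_id").to_frame()
        support_df.to_csv(out_dir / "consensus_support.tsv", sep="\t")
        _write_list(members, out_dir / "consensus_members.txt")
        translated = presence.translated_subset(members, matrix, min_trap=config.min_trap)
        counts["translated"] = len(translated)
        _write_list(translated, out_dir / "translated.txt")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- stage: orthology --------------------------------------------------
    stage = "orthology"
    try:
        ortho_path = _require(inputs, "orthologs", stage)
        table = orthology.OrthologTable(read_ortholog_tsv(ortho_path))
        mapped = orthology.map_orthologs(members, table,
                                         min_score=config.min_ortholog_score)
        universe = orthology.background_universe(table,
                                                 min_score=config.min_ortholog_score)
        counts["mapped_orthologs"] = len(mapped.target_genes)
        counts["background_universe"] = len(universe)
        rows = [{"target": t,
                 "sources": ";".join(s for s, _ in mapped.provenance[t]),
                 "scores": ";".join(str(sc) for _, sc in mapped.provenance[t])}
                for t in sorted(mapped.target_genes)]
        pd.DataFrame(rows, columns=["target", "sources", "scores"]).to_csv(
            out_dir / "mapped_orthologs.tsv", sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- stage: cluster filter ----------------------------------------------
    stage = "cluster_filter"
    try:
        sc = _require(inputs, "single_cell", stage)
        if "fractions" in sc:
            frac_df = read_fraction_table(sc["fractions"])
            sizes = pd.Series(1, index=frac_df.columns)
            fractions = celltype.ClusterExpressionFraction(frac_df, sizes)
        else:
            cells = read_mtx_counts(sc["mtx"], sc["genes"], sc["cells"])
            assignment = read_cluster_assignment(sc["clusters"])
            fractions = celltype.expression_fraction(cells, assignment)
        predicted = celltype.filter_by_cluster_expression(
            mapped.target_genes, fractions, clusters=config.target_clusters,
            min_fraction=config.min_cluster_fraction, mode=config.cluster_mode)
        counts["predicted_localized"] = len(predicted)
        _write_list(predicted, out_dir / "predicted_localized.txt")
        expressed_universe = celltype.filter_by_cluster_expression(
            universe, fractions, clusters=config.target_clusters,
            min_fraction=config.min_cluster_fraction, mode=config.cluster_mode)
        nonlocalized = celltype.nonlocalized_complement(
            expressed_universe, predicted & expressed_universe)
        counts["expressed_not_localized"] = len(nonlocalized)
        _write_list(nonlocalized, out_dir / "expressed_not_localized.txt")
        translated_predicted = predicted & orthology.map_orthologs(
            translated, table, min_score=config.min_ortholog_score).target_genes
        counts["translated_predicted"] = len(translated_predicted)
        _write_list(translated_predicted, out_dir / "translated_predicted.txt")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- stage: enrichment ---------------------------------------------------
    stage = "enrichment"
    try:
        if inputs.get("annotation"):
            annotation = read_gmt(inputs["annotation"])
            results = enrichment.enrich(predicted, universe, annotation,
                                        direction="over", correction=config.correction)
            _write_enrichment(results, out_dir / "enrichment_raw.tsv")
            sig = enrichment.significant(results, min_fold=config.min_fold,
                                         max_p_adj=config.max_p_adj)
            _write_enrichment(sig, out_dir / "enrichment_significant.tsv")
            counts["enriched_terms"] = len(sig)
            if inputs.get("ontology"):
                dag = read_obo(inputs["ontology"])
                cfg_sim = enrichment.SimilarityConfig(cutoff=config.similarity_cutoff)
                simplified = enrichment.simplify_terms(sig, dag, cfg_sim)
                _write_enrichment(simplified, out_dir / "enrichment_simplified.tsv")
                counts["simplified_terms"] = len(simplified)
                rolled = enrichment.hierarchy_rollup(sig, dag)
                rows = [{"term_id": r.term_id, "top_level_pathway": top, "sub_pathway": sub}
                        for r, pairs in rolled for top, sub in pairs]
                pd.DataFrame(rows, columns=["term_id", "top_level_pathway", "sub_pathway"]
                             ).to_csv(out_dir / "enrichment_rollup.tsv", sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- stage: comparisons ---------------------------------------------------
    stage = "comparisons"
    try:
        overlap_rows = []
        sets = {}
        for name, lpath in (inputs.get("gene_lists", {}) or {}).items():
            genes = read_gene_list(lpath)
            sets[name] = genes
            ov = compare.overlap_significance(predicted, genes, universe)
            overlap_rows.append({"set": name, "overlap": ov.overlap,
                                 "size_predicted": ov.size_a, "size_set": ov.size_b,
                                 "universe": ov.universe, "expected": round(ov.expected, 4),
                                 "p_over": ov.p_over})
        if overlap_rows:
            pd.DataFrame(overlap_rows).to_csv(out_dir / "overlaps.tsv", sep="\t", index=False)
        if len(sets) >= 1:
            table_sets = {"predicted": frozenset(predicted), **sets}
            inter = compare.intersect_multi(table_sets)
            rows = [{"labels": "&".join(sorted(k)), "exclusive_count": v}
                    for k, v in sorted(inter.exclusive_counts.items(),
                                       key=lambda kv: "&".join(sorted(kv[0])))]
            pd.DataFrame(rows).to_csv(out_dir / "intersections.tsv", sep="\t", index=False)
        if inputs.get("query_list"):
            query = [line.split("#", 1)[0].strip()
                     for line in Path(inputs["query_list"]).read_text().splitlines()]
            query = [q for q in query if q]
            rep = compare.membership_report(query, predicted)
            rep.table.to_csv(out_dir / "membership_query.tsv", sep="\t", index=False)
            counts["query_hits"] = rep.hits
            counts["query_total"] = rep.total
            (out_dir / "membership_summary.json").write_text(json.dumps(
                {"hits": rep.hits, "total": rep.total, "percentage": rep.percentage,
                 "undefined": rep.undefined}, indent=2) + "\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- run manifest ---------------------------------------------------------
    hashes = {}
    def _collect(node: Any, prefix: str = "") -> None:
        if isinstance(node, Mapping):
            for k, v in node.items():
                _collect(v, f"{prefix}{k}.")
        elif node is not None and Path(str(node)).exists():
            hashes[prefix.rstrip(".")] = sha256_file(node)
    _collect(inputs)
    manifest_doc = {"config": asdict(config), "inputs_sha256": hashes,
                    "stage_counts": counts, "seed": config.seed,
                    "cpm_fallback_libraries": cpm_fallback}
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest_doc, indent=2, sort_keys=True, default=str) + "\n")
    thresholds = asdict(config)
    key_inputs = {k: inputs[k] for k in ("orthologs", "annotation")
                  if inputs.get(k) and Path(str(inputs[k])).exists()}
    for name in ("consensus_members.txt", "predicted_localized.txt", "translated.txt"):
        write_provenance(out_dir / name, inputs=key_inputs, params=thresholds,
                         seed=config.seed)
    return out_dir


def _write_list(genes, path: Path) -> None:
    path.write_text("".join(g + "\n" for g in sorted(genes)))


def _write_enrichment(results, path: Path) -> None:
    rows = [{"term_id": r.term_id, "term_name": r.term_name, "k": r.k, "n": r.n,
             "K": r.K, "N": r.N, "fold_change": round(r.fold_change, 6),
             "p_raw": r.p_raw, "p_adj": r.p_adj, "direction": r.direction}
            for r in results]
    pd.DataFrame(rows, columns=["term_id", "term_name", "k", "n", "K", "N",
                                "fold_change", "p_raw", "p_adj", "direction"]
                 ).to_csv(path, sep="\t", index=False)


def report(out_dir: str | Path) -> str:
    """Human-readable summary of a completed run; numbers come from the TSVs."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "run_manifest.json"
    if not manifest_path.exists():
        raise PipelineError("incomplete run: missing run_manifest.json")
    doc = json.loads(manifest_path.read_text())
    lines = ["# Run summary", ""]
    lines.append("## Stage counts")
    for key, value in sorted(doc["stage_counts"].items()):
        lines.append(f"- {key}: {value}")
    sig_path = out_dir / "enrichment_significant.tsv"
    if sig_path.exists():
        sig = pd.read_csv(sig_path, sep="\t")
        lines.append("")
        lines.append(f"## Significant terms: {len(sig)}")
        for _, row in sig.head(10).iterrows():
            lines.append(f"- {row['term_id']} ({row['term_name']}): "
                         f"FC={row['fold_change']:.2f}, p_adj={row['p_adj']:.3g}")
    ov_path = out_dir / "overlaps.tsv"
    if ov_path.exists():
        ov = pd.read_csv(ov_path, sep="\t")
        lines.append("")
        lines.append("## Overlap tests")
        for _, row in ov.iterrows():
            lines.append(f"- {row['set']}: overlap={row['overlap']} "
                         f"(expected {row['expected']:.1f}), p={row['p_over']:.3g}")
    ms_path = out_dir / "membership_summary.json"
    if ms_path.exists():
        ms = json.loads(ms_path.read_text())
        lines.append("")
        lines.append(f"## Query membership: {ms['hits']}/{ms['total']} "
                     f"({ms['percentage']:.2f}%)")
    return "\n".join(lines) + "\n"
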