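import numpy as np
import pandas as pd
import pytest

from gliaprot.io import (Assay, Compartment, ExpressionLibrary, LibraryManifest,
                         OntologyDAG, QuantKind, Relation, Species)


def make_manifest(library_id="libA", species=Species.MOUSE,
                  compartment=Compartment.PROTRUSION,
                  assay=Assay.TRANSCRIPTOME, quant_kind=QuantKind.TPM):
    return LibraryManifest(library_id, "study", species, compartment, assay, quant_kind)


def make_library(values: dict[str, list[float]], **manifest_kwargs) -> ExpressionLibrary:
    """Build a tiny ExpressionLibrary from {gene: [sample values]}."""
    df = pd.DataFrame.from_dict(values, orient="index",
                                columns=[f"s{i+1}" for i in
                                         range(len(next(iter(values.values()))))])
    return ExpressionLibrary(make_manifest(**manifest_kwargs), df.astype(float))


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """R -> P1 -> P2 -> T (edges child->parent, is_a)."""
    dag = OntologyDAG()
    for t in ("R", "P1", "P2", "T"):
        dag.add_term(t, t.lower(), "ns")
    dag.add_edge("P1", "R")
    dag.add_edge("P2", "P1")
    dag.add_edge("T", "P2")
    dag.validate()
    return dag


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240722)
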