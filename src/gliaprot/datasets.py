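"""Packaged example data: the 15-gene smFISH validation query and a
synthetic stand-in for the predicted localized list.

The query table carries the 15 fly genes (with high-confidence mammalian
homologs) whose localization at larval NMJ glial protrusions was tested by
smFISH, together with whether each was predicted as localized.  The
predicted-list fixture is synthetic: it contains the 11 validated FBgn IDs
plus deterministic placeholder IDs padding it to 1,740 lines, standing in for
the real predicted set, which is not distributed with this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_gene_list


def _data_path(name: str):
    return resources.files("gliaprot.data") / name


def load_smfish_query() -> pd.DataFrame:
    """The 15-gene validation query: gene_symbol, fbgn_id, predicted (Yes/No)."""
    with resources.as_file(_data_path("table2_smfish_query.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_predicted_localized_synthetic() -> frozenset[str]:
    """Synthetic stand-in for the 1,740-gene predicted localized set."""
    with resources.as_file(_data_path("predicted_localized_synthetic.txt")) as p:
        return read_gene_list(p)
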