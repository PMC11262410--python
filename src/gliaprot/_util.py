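"""Shared helpers: gene-ID normalization, file hashing, provenance sidecars."""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Any, Iterable

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene_id: str) -> str:
    """Normalize a gene identifier.

    Exact, case-sensitive matching after trimming surrounding whitespace and
    stripping a trailing transcript-version suffix (".<digits>").  FBgn and
    ENSEMBL identifiers are case-sensitive, so no case folding is applied.
    Idempotent: normalizing twice gives the same result.
    """
    return _VERSION_SUFFIX.sub("", gene_id.strip())


def normalize_gene_ids(ids: Iterable[str]) -> list[str]:
    return [normalize_gene_id(g) for g in ids]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_path: str | Path, *, inputs: dict[str, str | Path] | None = None,
                     params: dict[str, Any] | None = None, seed: int | None = None) -> Path:
    """Write a JSON provenance sidecar next to an output file.

    Records SHA-256 hashes of the inputs, the thresholds/parameters used, and
    the seed, so any table can be traced back to what produced it.
    """
    out_path = Path(out_path)
    sidecar = out_path.with_suffix(out_path.suffix + ".prov.json")
    record: dict[str, Any] = {
        "output": out_path.name,
        "inputs": {str(k): sha256_file(v) for k, v in (inputs or {}).items() if Path(v).exists()},
        "params": params or {},
    }
    if seed is not None:
        record["seed"] = int(seed)
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return sidecar
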