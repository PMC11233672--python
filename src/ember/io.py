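"""Readers and writers for the delimited-text formats the tool touches.

Expression matrices are genes-in-rows TSV (CSV optional) with a sample
header; gene sets come as MSigDB-dialect GMT; the stable-gene panel is one
identifier per line; fitted models serialize to a single human-inspectable
JSON document.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .asis import ASISModel
from .datatypes import ExpressionMatrix, GeneSetCollection
from .embedding import EmbeddingModel

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_metadata",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "ember-model"
MODEL_VERSION = 1

_RESPONSE_VOCAB = {"responder", "non-responder"}


def read_expression(path, delimiter: str = "\t", scale_tag: str = "unknown") -> ExpressionMatrix:
    """Read a gene-by-sample matrix: first row samples, first column genes.

    Duplicate gene or sample identifiers and non-numeric cells raise
    informative errors (pandas would silently mangle duplicate columns).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    sample_ids = header[1:]
    dup = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample identifier: {dup[0]!r}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    frame.columns = sample_ids
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifier: {dup[0]!r}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(frame.columns):
            for i, v in enumerate(frame[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {frame.index[i]!r} (row {i + 2}), "
                        f"sample {col!r} (column {j + 2}): {v!r}"
                    ) from None
        raise
    return ExpressionMatrix(
        gene_ids=list(frame.index), sample_ids=sample_ids, values=values,
        scale_tag=scale_tag,
    )


def write_expression(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="gene")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then gene ids, tab-separated.

    The description column is discarded; genes are de-duplicated preserving
    order.  Lines with fewer than 3 fields are rejected with their line
    number.
    """
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields, need at least 3"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} at line {lineno}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_list(path) -> list:
    """One gene identifier per line; blanks skipped, order preserved."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return list(dict.fromkeys(genes))


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_metadata(path, delimiter: str = ",") -> pd.DataFrame:
    """Per-sample metadata table with a unique ``sample_id`` column."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    if "sample_id" not in frame.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    dup = frame["sample_id"][frame["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in metadata: {dup.iloc[0]!r}")
    if "response" in frame.columns:
        bad = set(frame["response"].dropna()) - _RESPONSE_VOCAB
        if bad:
            raise ValueError(
                f"response labels outside {sorted(_RESPONSE_VOCAB)}: {sorted(bad)}"
            )
    return frame.set_index("sample_id")


def _embedding_payload(model: EmbeddingModel) -> dict:
    return {
        "feature_genes": model.feature_genes,
        "stable_genes": model.stable_genes,
        "component_labels": model.component_labels,
        "loadings": [[float(v) for v in row] for row in model.loadings],
        "sign_anchor": [[g, int(s)] for g, s in model.sign_anchor],
        "training_info": model.training_info,
    }


def save_model(model: EmbeddingModel | ASISModel, path) -> None:
    """Serialize a fitted model to a single JSON document.

    Loadings are written with full float precision (repr round-trip), so
    load(save(m)) reproduces projections bit-compatibly.
    """
    if isinstance(model, ASISModel):
        doc = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "kind": "asis",
            "batch_components": list(model.batch_components),
            **_embedding_payload(model.embedding),
        }
    else:
        doc = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "kind": "embedding",
            **_embedding_payload(model),
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> EmbeddingModel | ASISModel:
    """Load a model JSON; errors on version mismatch or truncated/incomplete files."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"truncated or invalid model file {path}: {exc}") from exc
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"not an ember model file: {path}")
    if doc.get("version") != MODEL_VERSION:
        raise ValueError(
            f"model version {doc.get('version')} unsupported (expected {MODEL_VERSION})"
        )
    for key in ("feature_genes", "stable_genes", "loadings", "component_labels"):
        if key not in doc:
            raise ValueError(f"model file missing {key!r} block")
    embedding = EmbeddingModel(
        feature_genes=doc["feature_genes"],
        stable_genes=doc["stable_genes"],
        loadings=np.array(doc["loadings"], dtype=float),
        component_labels=doc["component_labels"],
        sign_anchor=[(g, int(s)) for g, s in doc.get("sign_anchor", [])],
        training_info=doc.get("training_info", {}),
    )
    if doc.get("kind") == "asis":
        return ASISModel(
            embedding=embedding,
            batch_components=tuple(doc.get("batch_components", (1, 2))),
        )
    return embedding
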