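"""Readers and writers: Matrix Market UMI matrices with gene/barcode
sidecars, dense delimited tables, and single-file JSON model serialization.

All delimited tables are tab-separated with a header row and an id column.
Model files are one JSON document with base64-encoded little-endian float64
arrays and a format-version field.
"""

from __future__ import annotations

import base64
import json
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    AtlasModel,
    BiomarkerRanking,
    BulkPanel,
    CountMatrix,
    DrugResponsePanel,
    ParseError,
    StructuralError,
)

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# count matrices

def load_count_matrix(path: str, format: str = "mtx_triplet_with_sidecars") -> CountMatrix:
    """Read a genes x cells UMI count matrix.

    ``mtx_triplet_with_sidecars``: ``path`` is a directory holding
    ``matrix.mtx`` plus ``genes.tsv`` and ``barcodes.tsv`` sidecars
    (one id per line; genes.tsv may carry extra columns).
    ``dense_table``: ``path`` is a TSV with genes as rows, cells as
    columns, first column gene ids.
    """
    if format == "mtx_triplet_with_sidecars":
        mtx = os.path.join(path, "matrix.mtx")
        for f in (mtx, os.path.join(path, "genes.tsv"), os.path.join(path, "barcodes.tsv")):
            if not os.path.exists(f):
                raise ParseError(f"missing input file: {f}")
        try:
            m = scipy.io.mmread(mtx)
        except Exception as exc:  # scipy raises ValueError on bad headers
            raise ParseError(f"{mtx}: {exc}") from exc
        genes = _read_sidecar(os.path.join(path, "genes.tsv"))
        barcodes = _read_sidecar(os.path.join(path, "barcodes.tsv"))
        counts = sp.csr_matrix(m)
        if np.any(counts.data < 0):
            raise ParseError(f"{mtx}: negative count entry")
        if np.any(counts.data != np.round(counts.data)):
            raise ParseError(f"{mtx}: non-integer count entry")
        meta_path = os.path.join(path, "cells.tsv")
        meta = None
        if os.path.exists(meta_path):
            meta = pd.read_csv(meta_path, sep="\t")
        mito = None
        if meta is not None and "mito_fraction" in meta:
            mito = meta["mito_fraction"].to_numpy(dtype=float)
        return CountMatrix(genes, barcodes, counts, cell_meta=meta, mito_fraction=mito)
    if format == "dense_table":
        df = _read_rectangular(path)
        vals = df.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ParseError(f"{path}: missing or non-numeric count entry")
        if np.any(vals < 0) or np.any(vals != np.round(vals)):
            raise ParseError(f"{path}: counts must be non-negative integers")
        return CountMatrix(list(df.index), list(df.columns), sp.csr_matrix(vals))
    raise ValueError(f"unknown count-matrix format {format!r}")


def save_count_matrix(cm: CountMatrix, path: str) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv (+ cells.tsv metadata)."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    _write_sidecar(os.path.join(path, "genes.tsv"), cm.gene_ids)
    _write_sidecar(os.path.join(path, "barcodes.tsv"), cm.cell_ids)
    meta = cm.cell_meta
    if cm.mito_fraction is not None:
        meta = (meta.copy() if meta is not None else pd.DataFrame(index=range(cm.n_cells)))
        meta["mito_fraction"] = cm.mito_fraction
    if meta is not None:
        meta.to_csv(os.path.join(path, "cells.tsv"), sep="\t", index=False)


def _read_sidecar(path: str) -> list:
    ids = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    if not ids:
        raise ParseError(f"{path}: empty sidecar")
    return ids


def _write_sidecar(path: str, ids) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")


def _read_rectangular(path: str, sep: str | None = None) -> pd.DataFrame:
    if sep is None:
        sep = "," if path.endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicated row identifier")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicated column identifier")
    return df


# ---------------------------------------------------------------------------
# panels

def load_table(path: str, orientation: str) -> BulkPanel | DrugResponsePanel:
    """Read a delimited panel.

    orientation ``genes_by_samples`` -> BulkPanel;
    ``drugs_by_samples`` -> DrugResponsePanel (empty cells stay missing).
    """
    df = _read_rectangular(path)
    if orientation == "genes_by_samples":
        return BulkPanel(list(df.index), list(df.columns), df.to_numpy(dtype=float))
    if orientation == "drugs_by_samples":
        return DrugResponsePanel(list(df.index), list(df.columns), df.to_numpy(dtype=float))
    raise ValueError(f"unknown orientation {orientation!r}")


def save_table(panel: BulkPanel | DrugResponsePanel, path: str) -> None:
    panel.to_frame().to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# model serialization

def _enc(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {"shape": list(a.shape),
            "data": base64.b64encode(a.tobytes()).decode("ascii")}


def _dec(d: dict) -> np.ndarray:
    raw = base64.b64decode(d["data"])
    a = np.frombuffer(raw, dtype=np.float64).copy()
    return a.reshape(d["shape"])


def save_model(model: AtlasModel | BiomarkerRanking, path: str) -> None:
    if isinstance(model, AtlasModel):
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "model_type": "atlas",
            "gene_ids": list(model.gene_ids),
            "icf_weights": _enc(model.icf_weights),
            "pc_loadings": _enc(model.pc_loadings),
            "pc_center": _enc(model.pc_center),
            "reference_pc_coords": _enc(model.reference_pc_coords),
            "reference_labels": model.reference_labels.to_dict(orient="list"),
            "label_columns": list(model.reference_labels.columns),
            "knn_k_classify": int(model.knn_k_classify),
            "embedding": None if model.embedding is None else _enc(model.embedding),
        }
    elif isinstance(model, BiomarkerRanking):
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "model_type": "biomarker_ranking",
            "drug_ids": list(model.drug_ids),
            "genes": {d: list(model.genes[d]) for d in model.drug_ids},
            "pcc": {d: _enc(model.pcc[d]) for d in model.drug_ids},
            "meta": model.meta,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> AtlasModel | BiomarkerRanking:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: truncated or invalid model file ({exc})") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ParseError(
            f"{path}: model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    kind = doc.get("model_type")
    if kind == "atlas":
        labels = pd.DataFrame({c: doc["reference_labels"][c] for c in doc["label_columns"]})
        return AtlasModel(
            gene_ids=doc["gene_ids"],
            icf_weights=_dec(doc["icf_weights"]),
            pc_loadings=_dec(doc["pc_loadings"]),
            pc_center=_dec(doc["pc_center"]),
            reference_pc_coords=_dec(doc["reference_pc_coords"]),
            reference_labels=labels,
            knn_k_classify=doc["knn_k_classify"],
            embedding=None if doc["embedding"] is None else _dec(doc["embedding"]),
        )
    if kind == "biomarker_ranking":
        return BiomarkerRanking(
            drug_ids=doc["drug_ids"],
            genes={d: doc["genes"][d] for d in doc["drug_ids"]},
            pcc={d: _dec(doc["pcc"][d]) for d in doc["drug_ids"]},
            meta=doc.get("meta", {}),
        )
    raise ParseError(f"{path}: unknown model type {kind!r}")
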