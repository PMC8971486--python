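"""Quality control and normalization of UMI count matrices.

The path from raw counts to analysis-ready matrices: depth/gene/mito QC,
Tukey depth-outlier removal (putative multiplets), minimum-cell gene
filtering, CPM scaling, GF-ICF normalization and pseudo-bulk aggregation.

GF-ICF (gene frequency - inverse cell frequency) is the single-cell
counterpart of TF-IDF from text mining: a gene's within-cell frequency is
weighted by how rare the gene is across cells, so ubiquitously detected
genes are down-weighted and selectively expressed genes emphasised. Cell
columns are rescaled to unit Euclidean norm afterwards, making cells
directly comparable regardless of depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .types import BulkPanel, CountMatrix, NormalizedMatrix, StructuralError


@dataclass
class QCReport:
    n_input: int
    removed_low_umi: int
    removed_few_genes: int
    removed_high_mito: int
    n_retained: int


def qc_filter_cells(
    counts: CountMatrix,
    min_umi: int = 2500,
    min_genes: int = 1000,
    max_mito: float = 0.5,
    return_report: bool = False,
):
    """Keep high-quality cells: total UMI >= min_umi, detected genes >
    min_genes, mitochondrial read fraction < max_mito.

    Boundaries follow the literal criteria: "at least" 2500 UMI is
    inclusive, "more than" 1000 genes and "less than" 50% mito are strict.
    """
    depths = counts.depths()
    ngenes = counts.genes_per_cell()
    ok_umi = depths >= min_umi
    ok_genes = ngenes > min_genes
    if counts.mito_fraction is not None:
        ok_mito = counts.mito_fraction < max_mito
    else:
        ok_mito = np.ones(counts.n_cells, dtype=bool)
    keep = ok_umi & ok_genes & ok_mito
    report = QCReport(
        n_input=counts.n_cells,
        removed_low_umi=int(np.sum(~ok_umi)),
        removed_few_genes=int(np.sum(~ok_genes)),
        removed_high_mito=int(np.sum(~ok_mito)),
        n_retained=int(np.sum(keep)),
    )
    if report.n_retained == 0:
        warnings.warn("qc_filter_cells removed every cell")
    out = counts.subset_cells(keep)
    return (out, report) if return_report else out


def remove_depth_outliers(counts: CountMatrix, tukey_k: float = 3.0,
                          group_column: str = "label") -> CountMatrix:
    """Drop cells whose total UMI falls outside [Q1 - k*IQR, Q3 + k*IQR].

    Applied per cell-line group when labels are available (multiplet
    depths are only outlying relative to their own line), globally
    otherwise.
    """
    depths = counts.depths()
    labels = counts.labels(group_column)
    keep = np.ones(counts.n_cells, dtype=bool)
    groups = [np.arange(counts.n_cells)] if labels is None else [
        np.flatnonzero(labels == g) for g in np.unique(labels)
    ]
    for idx in groups:
        d = depths[idx]
        q1, q3 = np.percentile(d, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - tukey_k * iqr, q3 + tukey_k * iqr
        keep[idx] = (d >= lo) & (d <= hi)
    return counts.subset_cells(keep)


def filter_genes_min_cell_fraction(counts: CountMatrix, min_fraction: float = 0.05) -> CountMatrix:
    """Keep genes detected in at least ``min_fraction`` of all cells."""
    if counts.n_cells == 0:
        return counts
    frac = np.asarray((counts.counts > 0).sum(axis=1)).ravel() / counts.n_cells
    return counts.subset_genes(frac >= min_fraction)


def cpm(counts: CountMatrix, scale_factors: np.ndarray | None = None) -> sp.csr_matrix:
    """Counts-per-million scaling; each cell column sums to 1e6.

    ``scale_factors`` optionally multiplies each cell's library size
    (e.g. externally computed compositional normalization factors).
    """
    depths = counts.depths().astype(float)
    if np.any(depths == 0):
        raise StructuralError("cpm: zero-depth cell present")
    if scale_factors is not None:
        depths = depths * np.asarray(scale_factors, dtype=float)
    d = sp.diags(1e6 / depths)
    return (counts.counts @ d).tocsr()


def _icf(counts: CountMatrix, variant: str = "log1p_ratio") -> np.ndarray:
    n_expressing = np.asarray((counts.counts > 0).sum(axis=1)).ravel()
    if np.any(n_expressing == 0):
        raise StructuralError(
            "gf_icf: gene expressed in zero cells; apply gene filtering first"
        )
    n = counts.n_cells
    if variant == "log1p_ratio":
        return np.log(1.0 + n / n_expressing)
    if variant == "log_ratio":
        return np.log(n / n_expressing) + 1.0  # smoothed to stay positive
    raise ValueError(f"unknown ICF variant {variant!r}")


def _l2_normalize_columns(m: sp.csr_matrix) -> sp.csr_matrix:
    norms = np.sqrt(np.asarray(m.multiply(m).sum(axis=0)).ravel())
    norms[norms == 0] = 1.0
    return (m @ sp.diags(1.0 / norms)).tocsr()


def gf_icf(counts: CountMatrix, icf_variant: str = "log1p_ratio") -> NormalizedMatrix:
    """GF-ICF normalization.

    value(g, c) = GF(g, c) * ICF(g), where GF is the CPM-scaled count
    fraction of gene g in cell c and ICF(g) = log(1 + N / n_g) with n_g
    the number of cells detecting g. Cell columns are then rescaled to
    unit L2 norm (which absorbs the per-cell CPM constant, so raw count
    fractions would give the identical result).
    """
    gf = cpm(counts)
    icf = _icf(counts, icf_variant)
    values = _l2_normalize_columns((sp.diags(icf) @ gf).tocsr())
    return NormalizedMatrix(counts.gene_ids, counts.cell_ids, values, icf)


def apply_gf_icf(new_counts: CountMatrix, reference_gene_ids: list,
                 icf_weights: np.ndarray) -> NormalizedMatrix:
    """Normalize new cells with ICF weights frozen from a reference.

    The gene universe is the reference's: shared genes keep their counts,
    reference genes absent from the query are imputed as zero. Warns when
    fewer than half the reference genes are found.
    """
    icf_weights = np.asarray(icf_weights, dtype=float)
    ref_index = {g: i for i, g in enumerate(reference_gene_ids)}
    shared = [g for g in new_counts.gene_ids if g in ref_index]
    overlap = len(shared) / max(len(reference_gene_ids), 1)
    if overlap < 0.5:
        warnings.warn(
            f"apply_gf_icf: only {overlap:.1%} of reference genes found in query"
        )
    if not shared:
        raise StructuralError("apply_gf_icf: no reference genes present in query")
    new_pos = {g: i for i, g in enumerate(new_counts.gene_ids)}
    src_rows = np.array([new_pos[g] for g in shared])
    dst_rows = np.array([ref_index[g] for g in shared])
    sub = new_counts.counts[src_rows, :]
    depths = np.asarray(sub.sum(axis=0)).ravel().astype(float)
    if np.any(depths == 0):
        raise StructuralError(
            "apply_gf_icf: query cell with zero counts on the reference gene set"
        )
    gf = (sub @ sp.diags(1e6 / depths)).tocoo()
    reindexed = sp.csr_matrix(
        (gf.data, (dst_rows[gf.row], gf.col)),
        shape=(len(reference_gene_ids), new_counts.n_cells),
    )
    values = _l2_normalize_columns((sp.diags(icf_weights) @ reindexed).tocsr())
    return NormalizedMatrix(list(reference_gene_ids), new_counts.cell_ids, values, icf_weights)


def pseudo_bulk(counts: CountMatrix, group_labels: np.ndarray,
                return_raw: bool = False) -> BulkPanel:
    """Sum counts per group, then CPM and log10(CPM + 1).

    Emulates one bulk RNA-seq sample per group (e.g. per cell line).
    """
    group_labels = np.asarray(group_labels)
    if group_labels.shape != (counts.n_cells,):
        raise StructuralError("pseudo_bulk: one label per cell required")
    groups = [g for g in np.unique(group_labels)]
    sums = np.zeros((counts.n_genes, len(groups)))
    for j, g in enumerate(groups):
        idx = np.flatnonzero(group_labels == g)
        if idx.size == 0:
            warnings.warn(f"pseudo_bulk: empty group {g!r} dropped")
            continue
        sums[:, j] = np.asarray(counts.counts[:, idx].sum(axis=1)).ravel()
    if return_raw:
        return sums, [str(g) for g in groups]
    totals = sums.sum(axis=0)
    totals[totals == 0] = 1.0
    values = np.log10(sums / totals * 1e6 + 1.0)
    return BulkPanel(counts.gene_ids, [str(g) for g in groups], values)
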