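"""Core domain containers shared by every pipeline stage.

All expression matrices are stored genes-as-rows, cells-as-columns, matching
the Matrix Market sidecar convention (genes.tsv / barcodes.tsv).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class StructuralError(ValueError):
    """Dimension mismatch or invariant violation in a domain object."""


class ParseError(ValueError):
    """Malformed input file; message names the offending file (and line)."""


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})[:5]
        raise StructuralError(f"duplicate {what} identifiers: {dup}")
    return ids


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts."""

    gene_ids: list
    cell_ids: list
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame | None = None
    mito_fraction: np.ndarray | None = None

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise StructuralError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise StructuralError("counts must be non-negative integers")
        if self.cell_meta is not None:
            if len(self.cell_meta) != len(self.cell_ids):
                raise StructuralError("cell_meta length does not match cell_ids")
            self.cell_meta = self.cell_meta.reset_index(drop=True)
        if self.mito_fraction is not None:
            mf = np.asarray(self.mito_fraction, dtype=float)
            if mf.shape != (len(self.cell_ids),):
                raise StructuralError("mito_fraction length does not match cells")
            if np.any((mf < 0) | (mf > 1)):
                raise StructuralError("mito_fraction must lie in [0, 1]")
            self.mito_fraction = mf

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def depths(self) -> np.ndarray:
        """Total UMI per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected (count >= 1) genes per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.iloc[idx] if self.cell_meta is not None else None,
            mito_fraction=self.mito_fraction[idx] if self.mito_fraction is not None else None,
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=self.cell_ids,
            counts=self.counts[idx, :],
            cell_meta=self.cell_meta,
            mito_fraction=self.mito_fraction,
        )

    def labels(self, column: str = "label") -> np.ndarray | None:
        if self.cell_meta is not None and column in self.cell_meta:
            return self.cell_meta[column].to_numpy()
        return None


@dataclass
class BulkPanel:
    """Genes x samples log10(CPM+1) expression panel (bulk or pseudo-bulk)."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise StructuralError("values shape does not match gene/sample ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite < 0):
            raise StructuralError("log10(CPM+1) values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DrugResponsePanel:
    """Drugs x samples AUC potency matrix; lower AUC = more sensitive.

    Missing measurements are NaN (never 0: a zero AUC is a real, maximally
    potent value).
    """

    drug_ids: list
    sample_ids: list
    auc: np.ndarray

    def __post_init__(self):
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.auc = np.asarray(self.auc, dtype=float)
        if self.auc.shape != (len(self.drug_ids), len(self.sample_ids)):
            raise StructuralError("auc shape does not match drug/sample ids")
        if np.any(np.isinf(self.auc)):
            raise StructuralError("auc entries must be finite where present")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.auc, index=self.drug_ids, columns=self.sample_ids)


@dataclass
class NormalizedMatrix:
    """GF-ICF normalized genes x cells matrix with unit-L2 cell columns."""

    gene_ids: list
    cell_ids: list
    values: sp.csr_matrix
    icf_weights: np.ndarray

    def __post_init__(self):
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        self.icf_weights = np.asarray(self.icf_weights, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise StructuralError("values shape does not match ids")
        if self.icf_weights.shape != (len(self.gene_ids),):
            raise StructuralError("icf_weights length does not match genes")

    def dense(self) -> np.ndarray:
        return self.values.toarray()


@dataclass
class AtlasModel:
    """Fitted reference atlas: frozen ICF weights, PC loadings and labelled
    reference coordinates for kNN classification of new cells."""

    gene_ids: list
    icf_weights: np.ndarray
    pc_loadings: np.ndarray       # genes x n_pc, orthonormal columns
    pc_center: np.ndarray         # per-gene mean used for centering
    reference_pc_coords: np.ndarray  # cells x n_pc
    reference_labels: pd.DataFrame   # per-cell label columns (line, cluster, ...)
    knn_k_classify: int = 100
    embedding: np.ndarray | None = None

    def __post_init__(self):
        self.icf_weights = np.asarray(self.icf_weights, dtype=float)
        self.pc_loadings = np.asarray(self.pc_loadings, dtype=float)
        self.pc_center = np.asarray(self.pc_center, dtype=float)
        self.reference_pc_coords = np.asarray(self.reference_pc_coords, dtype=float)
        n_genes, n_pc = self.pc_loadings.shape
        if n_pc < 1:
            raise StructuralError("need at least one principal component")
        if n_genes != len(self.gene_ids):
            raise StructuralError("pc_loadings rows do not match gene_ids")
        gram = self.pc_loadings.T @ self.pc_loadings
        if not np.allclose(gram, np.eye(n_pc), atol=1e-6):
            raise StructuralError("pc_loadings columns are not orthonormal")
        if len(self.reference_labels) != self.reference_pc_coords.shape[0]:
            raise StructuralError("every reference cell needs labels")


@dataclass
class MarkerTable:
    """Per (gene, cluster) differential-expression statistics."""

    table: pd.DataFrame  # columns: gene_id, cluster_id, log2_fold_change, p_value, fdr

    REQUIRED = ("gene_id", "cluster_id", "log2_fold_change", "p_value", "fdr")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise StructuralError(f"marker table missing columns {missing}")
        for col in ("p_value", "fdr"):
            v = self.table[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise StructuralError(f"{col} outside [0, 1]")

    def export_filter(self, max_fdr: float = 0.5, min_log2fc: float = 0.25) -> pd.DataFrame:
        """Marker rows passing the deconvolution export thresholds
        (FDR < 0.5 and log2 fold change > 0.25)."""
        t = self.table
        return t[(t["fdr"] < max_fdr) & (t["log2_fold_change"] > min_log2fc)].copy()


@dataclass
class BiomarkerRanking:
    """Per-drug gene lists ordered by Pearson correlation with AUC.

    Positive correlation (top of list) marks resistance, negative
    correlation (bottom) marks sensitivity.
    """

    drug_ids: list
    genes: dict  # drug -> list of gene ids, PCC descending
    pcc: dict    # drug -> np.ndarray of PCC values aligned with genes
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        for d in self.drug_ids:
            if d not in self.genes or d not in self.pcc:
                raise StructuralError(f"missing ranking for drug {d!r}")
            v = np.asarray(self.pcc[d], dtype=float)
            if v.size and (np.nanmax(v) > 1 + 1e-9 or np.nanmin(v) < -1 - 1e-9):
                raise StructuralError("PCC outside [-1, 1]")
            if np.any(np.diff(v) > 1e-12):
                raise StructuralError(f"ranking for {d!r} not sorted by PCC descending")
            self.pcc[d] = v


@dataclass
class GoldenStandard:
    """Binary drug x line sensitivity labels from z-scored AUC percentiles."""

    drug_ids: list
    sample_ids: list
    sensitive: np.ndarray  # bool drugs x samples
    percentile: float = 5.0

    def __post_init__(self):
        self.sensitive = np.asarray(self.sensitive, dtype=bool)
        if self.sensitive.shape != (len(self.drug_ids), len(self.sample_ids)):
            raise StructuralError("sensitivity matrix shape mismatch")


@dataclass
class TwoStateParams:
    """Two-state replicate/interconvert/kill model parameterization.

    Rates are first-order (1/h): net growth g_plus / g_minus, switching
    k_pm (+ -> -) and k_mp (- -> +), and delta, the drug-induced extra
    death rate acting on the plus state only.
    """

    g_plus: float
    g_minus: float
    k_pm: float
    k_mp: float
    delta: float
    n_plus0: float = 0.5
    n_minus0: float = 0.5

    def __post_init__(self):
        for name in ("k_pm", "k_mp", "delta"):
            if getattr(self, name) < 0:
                raise StructuralError(f"{name} must be >= 0")
        if self.n_plus0 < 0 or self.n_minus0 < 0:
            raise StructuralError("initial counts must be >= 0")
        if self.n_plus0 + self.n_minus0 <= 0:
            raise StructuralError("at least one initial count must be positive")


@dataclass
class DoseCombinationAssay:
    """Replicate dose-combination viability grid plus per-replicate DMSO
    control and single-agent margins."""

    doses_a: np.ndarray               # length n_a (drug A concentrations)
    doses_b: np.ndarray               # length n_b
    viability: np.ndarray             # replicates x n_a x n_b, combination wells
    single_a: np.ndarray              # replicates x n_a, drug A alone
    single_b: np.ndarray              # replicates x n_b, drug B alone
    dmso: np.ndarray                  # replicates, untreated control
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        self.single_a = np.asarray(self.single_a, dtype=float)
        self.single_b = np.asarray(self.single_b, dtype=float)
        self.dmso = np.asarray(self.dmso, dtype=float)
        r = self.dmso.shape[0]
        if self.viability.shape != (r, self.doses_a.size, self.doses_b.size):
            raise StructuralError("viability grid incomplete")
        if self.single_a.shape != (r, self.doses_a.size) or self.single_b.shape != (r, self.doses_b.size):
            raise StructuralError("single-agent margins incomplete")
        if np.any(self.viability <= 0) or np.any(self.dmso <= 0):
            raise StructuralError("viability and controls must be positive")

    @property
    def n_replicates(self) -> int:
        return self.dmso.shape[0]


@dataclass
class SynergyResult:
    """Excess-over-Bliss scoring of a dose-combination assay."""

    excess: np.ndarray        # n_a x n_b mean excess, percentage points
    score: float              # mean over the dose grid
    ci_halfwidth: float       # t-based 95% half-width across replicates (NaN if 1 rep)
    classification: str       # antagonistic | additive | synergistic

    def __post_init__(self):
        in_band = -10.0 <= self.score <= 10.0
        if in_band != (self.classification == "additive"):
            raise StructuralError(
                "classification must be 'additive' exactly when the mean "
                "score lies in [-10, +10]"
            )
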