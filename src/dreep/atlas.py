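"""Reference atlas construction and projection.

The atlas summarises a normalized reference population by its leading
principal components, clusters cells on a shared-nearest-neighbour Jaccard
graph with the Louvain algorithm, extracts per-cluster marker genes, and
classifies new cells by majority vote among their k nearest reference
cells after projecting them into the frozen PC space.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .preprocess import apply_gf_icf, filter_genes_min_cell_fraction, gf_icf
from .types import AtlasModel, CountMatrix, MarkerTable, NormalizedMatrix, StructuralError


# ---------------------------------------------------------------------------
# PCA

def fit_pca(norm: NormalizedMatrix, n_pc: int = 10):
    """PCA of cells over genes.

    Returns (loadings, coords): loadings is genes x n_pc with orthonormal
    columns, coords is cells x n_pc = centered data projected on the
    loadings. Component signs are fixed so the largest-magnitude loading
    of each component is positive (determinism across BLAS builds).
    """
    X = np.asarray(norm.values.T.todense(), dtype=float)  # cells x genes
    n_cells, n_genes = X.shape
    if n_pc > min(n_cells, n_genes):
        raise StructuralError(f"n_pc={n_pc} exceeds min(genes, cells)")
    center = X.mean(axis=0)
    Xc = X - center
    # deterministic full SVD; atlas-scale matrices are small enough
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:n_pc].T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_pc)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    coords = Xc @ loadings
    return loadings, coords, center


@dataclass
class CellGraph:
    """Weighted undirected cell graph; weights are Jaccard overlaps of
    kNN neighbourhoods (in [0, 1], no self-loops)."""

    n_nodes: int
    edges: np.ndarray    # m x 2 int, i < j
    weights: np.ndarray  # m floats in (0, 1]

    def to_igraph(self) -> igraph.Graph:
        g = igraph.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(self.weights)
        return g


def build_knn_graph(pc_coords: np.ndarray, k: int = 50, metric: str = "manhattan") -> CellGraph:
    """Shared-nearest-neighbour graph.

    Each cell is connected to its k most similar cells under the L1
    (manhattan) distance; the directed kNN relation is symmetrized and
    each edge weighted by the Jaccard similarity of the two endpoint
    neighbourhoods (proportion of shared neighbours; neighbourhoods
    include the cell itself, so duplicate cells weigh 1). Zero-overlap
    pairs carry no edge. Distance ties break by stable cell index order.
    """
    X = np.asarray(pc_coords, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise StructuralError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(X)
    _, idx = nn.kneighbors(X)
    # drop self; with duplicate coordinates self may not be first (or may
    # be absent from the k+1), so filter then truncate
    neigh = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i][idx[i] != i]
        neigh[i] = row[:k] if row.size >= k else idx[i][:k]
    # adjacency of the directed kNN relation, self-inclusive
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, neigh.ravel())), shape=(n, n))
    A = (A + sp.eye(n)).tocsr()
    A.data[:] = 1.0
    inter = (A @ A.T).tocoo()  # |N(i) & N(j)|
    mask = inter.row < inter.col
    ei, ej, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    if ei.size == 0:
        return CellGraph(n, np.empty((0, 2), dtype=int), np.empty(0))
    # restrict to symmetrized kNN edges
    sym = (A + A.T).tocsr()
    is_knn = np.asarray(sym[ei, ej]).ravel() > 0
    ei, ej, shared = ei[is_knn], ej[is_knn], shared[is_knn]
    union = 2 * (k + 1) - shared
    w = shared / union
    keep = w > 0
    return CellGraph(n, np.column_stack([ei[keep], ej[keep]]), w[keep])


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # int >= 1 per cell
    resolution: float


def louvain_cluster(graph: CellGraph, resolution: float = 0.25, seed: int = 0) -> ClusterAssignment:
    """Louvain community detection at the given resolution (deterministic
    for a fixed seed)."""
    if graph.n_nodes == 0:
        raise StructuralError("empty graph")
    g = graph.to_igraph()
    state = random.getstate()
    random.seed(seed)
    try:
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        random.setstate(state)
    labels = np.asarray(part.membership, dtype=int) + 1
    return ClusterAssignment(labels, resolution)


# ---------------------------------------------------------------------------
# markers

def find_cluster_markers(norm: NormalizedMatrix, clusters: ClusterAssignment) -> MarkerTable:
    """Per-cluster differential expression: two-sided Wilcoxon rank-sum of
    each gene in the cluster versus all other cells, BH FDR across genes
    within each cluster, and log2 fold change of mean normalized
    expression with pseudocount 1."""
    labels = clusters.labels
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise StructuralError("need at least 2 clusters for marker detection")
    X = norm.values.toarray()  # genes x cells
    rows = []
    for cl in uniq:
        inside = labels == cl
        if inside.sum() < 2:
            warnings.warn(f"cluster {cl} has fewer than 2 cells; skipped")
            continue
        a = X[:, inside]
        b = X[:, ~inside]
        res = scipy.stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        lfc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
        fdr = multipletests(res.pvalue, method="fdr_bh")[1]
        rows.append(pd.DataFrame({
            "gene_id": norm.gene_ids,
            "cluster_id": cl,
            "log2_fold_change": lfc,
            "p_value": res.pvalue,
            "fdr": fdr,
        }))
    return MarkerTable(pd.concat(rows, ignore_index=True))


def top_marker_per_cluster(markers: MarkerTable) -> list[tuple]:
    """The most differentially expressed gene of each cluster: smallest
    p-value, ties by largest |log2FC|, then lexicographic gene id."""
    t = markers.table
    if t.empty:
        raise StructuralError("empty marker table")
    out = []
    for cl, sub in t.groupby("cluster_id", sort=True):
        sub = sub.sort_values(
            by=["p_value", "log2_fold_change", "gene_id"],
            key=lambda s: -s.abs() if s.name == "log2_fold_change" else s,
        )
        out.append((cl, sub.iloc[0]["gene_id"]))
    return out


# ---------------------------------------------------------------------------
# atlas fit / classify

def fit_atlas(
    counts: CountMatrix,
    labels: np.ndarray,
    n_pc: int = 10,
    min_gene_fraction: float = 0.05,
    knn_k_graph: int = 50,
    resolution: float = 0.25,
    knn_k_classify: int = 100,
    seed: int = 0,
    embedder=None,
) -> AtlasModel:
    """Build an atlas: gene filter -> GF-ICF -> PCA -> SNN graph ->
    Louvain clustering; stores everything needed to project and classify
    new cells. ``embedder``, when given, is called with the PC coordinates
    and must return a cells x 2 embedding (e.g. a fitted UMAP transform);
    it is visualization-only and never used for classification."""
    labels = np.asarray(labels)
    if labels.shape != (counts.n_cells,):
        raise StructuralError("fit_atlas: one label per cell required")
    filtered = filter_genes_min_cell_fraction(counts, min_gene_fraction)
    norm = gf_icf(filtered)
    loadings, coords, center = fit_pca(norm, n_pc=n_pc)
    k_graph = min(knn_k_graph, coords.shape[0] - 1)
    graph = build_knn_graph(coords, k=k_graph)
    clusters = louvain_cluster(graph, resolution=resolution, seed=seed)
    ref_labels = pd.DataFrame({"label": labels.astype(str), "cluster": clusters.labels})
    emb = None
    if embedder is not None:
        emb = np.asarray(embedder(coords), dtype=float)
    return AtlasModel(
        gene_ids=norm.gene_ids,
        icf_weights=norm.icf_weights,
        pc_loadings=loadings,
        pc_center=center,
        reference_pc_coords=coords,
        reference_labels=ref_labels,
        knn_k_classify=knn_k_classify,
        embedding=emb,
    )


def project_cells(model: AtlasModel, new_counts: CountMatrix) -> np.ndarray:
    """Normalize new cells with the atlas' frozen ICF weights and project
    them onto the atlas' PC loadings. Cells with no counts on the atlas
    gene set yield NaN coordinates."""
    ref_rows = {g: i for i, g in enumerate(model.gene_ids)}
    shared = [g for g in new_counts.gene_ids if g in ref_rows]
    new_pos = {g: i for i, g in enumerate(new_counts.gene_ids)}
    src = np.array([new_pos[g] for g in shared], dtype=int)
    depths = (
        np.asarray(new_counts.counts[src, :].sum(axis=0)).ravel()
        if src.size else np.zeros(new_counts.n_cells)
    )
    degenerate = depths == 0
    coords = np.full((new_counts.n_cells, model.pc_loadings.shape[1]), np.nan)
    live = np.flatnonzero(~degenerate)
    if live.size:
        sub = new_counts.subset_cells(live)
        norm = apply_gf_icf(sub, model.gene_ids, model.icf_weights)
        X = np.asarray(norm.values.T.todense(), dtype=float)
        coords[live] = (X - model.pc_center) @ model.pc_loadings
    return coords


def classify_cells(model: AtlasModel, new_counts: CountMatrix, k: int | None = None,
                   label_column: str = "label", metric: str = "manhattan") -> pd.DataFrame:
    """Label new cells by majority vote among the k nearest reference
    cells in PC space; confidence is the winning vote fraction.

    Vote ties are broken by smaller mean distance to the tied labels'
    neighbours, then lexicographically. Cells with no counts on the atlas
    gene set are labelled "unclassified" with confidence 0.
    """
    k = model.knn_k_classify if k is None else k
    ref = model.reference_pc_coords
    if k > ref.shape[0]:
        raise StructuralError(f"k={k} exceeds reference size {ref.shape[0]}")
    coords = project_cells(model, new_counts)
    ref_labels = model.reference_labels[label_column].to_numpy()
    out_label = np.full(new_counts.n_cells, "unclassified", dtype=object)
    out_conf = np.zeros(new_counts.n_cells)
    live = np.flatnonzero(~np.isnan(coords[:, 0]))
    if live.size:
        nn = NearestNeighbors(n_neighbors=k, metric=metric).fit(ref)
        dist, idx = nn.kneighbors(coords[live])
        for row, (d, nb) in enumerate(zip(dist, idx)):
            votes = ref_labels[nb]
            cand, counts_ = np.unique(votes, return_counts=True)
            best = counts_.max()
            tied = cand[counts_ == best]
            if tied.size > 1:
                means = np.array([d[votes == c].mean() for c in tied])
                tied = tied[means == means.min()]
                winner = sorted(tied)[0]
            else:
                winner = tied[0]
            out_label[live[row]] = winner
            out_conf[live[row]] = best / k
    return pd.DataFrame({
        "cell_id": new_counts.cell_ids,
        "predicted_label": out_label,
        "confidence": out_conf,
    })
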