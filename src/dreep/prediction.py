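"""DREEP: drug response estimation from single-cell expression profiles.

Training crosses a bulk expression panel (genes x cell lines,
log10(CPM+1)) with drug potency measured as the dose-response AUC (low =
sensitive). For each drug, every gene is scored by the Pearson correlation
of its expression with the AUC across lines: positively correlated genes
mark resistance, negatively correlated genes mark sensitivity. Sorting
genes by PCC descending yields one ranked biomarker list per drug.

Prediction compares a cell's most expressed genes against each drug's
ranked list with a preranked GSEA running-sum statistic: a negative
enrichment score (top genes concentrated among the drug's sensitivity
markers) predicts sensitivity. Significance comes from a gene-set
permutation null; per-cell calls take the most negative significant score.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import (
    BiomarkerRanking,
    BulkPanel,
    CountMatrix,
    DrugResponsePanel,
    GoldenStandard,
    StructuralError,
)

UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# training

def _binned_entropy(values: np.ndarray, edges: np.ndarray) -> float:
    """Shannon entropy of a gene's expression histogram across lines.

    Bins are shared panel-wide so near-constant genes concentrate in one
    bin and score ~0."""
    v = values[np.isfinite(values)]
    if v.size == 0 or np.ptp(v) == 0:
        return 0.0
    hist, _ = np.histogram(v, bins=edges)
    p = hist[hist > 0] / v.size
    return float(-np.sum(p * np.log(p)))


def filter_training_panel(
    bulk: BulkPanel,
    response: DrugResponsePanel,
    min_lines: int = 25,
    entropy_pctile: float = 5.0,
    min_mean_expr: float = 0.01,
) -> tuple[BulkPanel, DrugResponsePanel]:
    """Restrict the training inputs to informative drugs and genes.

    Drops drugs measured in fewer than ``min_lines`` shared lines, genes
    with mean log10(CPM+1) <= ``min_mean_expr`` (poorly expressed), and
    genes whose binned across-line expression entropy falls in the lowest
    ``entropy_pctile`` percent (ties by stable gene order).
    """
    shared = [s for s in bulk.sample_ids if s in set(response.sample_ids)]
    if not shared:
        raise StructuralError("no shared cell lines between panels")
    b_idx = [bulk.sample_ids.index(s) for s in shared]
    r_idx = [response.sample_ids.index(s) for s in shared]
    values = bulk.values[:, b_idx]
    auc = response.auc[:, r_idx]

    n_meas = np.sum(np.isfinite(auc), axis=1)
    keep_drugs = n_meas >= min_lines
    auc = auc[keep_drugs]
    drug_ids = [d for d, k in zip(response.drug_ids, keep_drugs) if k]

    expressed = values.mean(axis=1) > min_mean_expr
    finite = values[np.isfinite(values)]
    edges = np.histogram_bin_edges(finite, bins=10)
    ent = np.array([_binned_entropy(values[g], edges) for g in range(values.shape[0])])
    n_drop = int(np.floor(values.shape[0] * entropy_pctile / 100.0))
    low_entropy = np.zeros(values.shape[0], dtype=bool)
    if n_drop > 0:
        low_entropy[np.argsort(ent, kind="stable")[:n_drop]] = True
    keep_genes = expressed & ~low_entropy
    gene_ids = [g for g, k in zip(bulk.gene_ids, keep_genes) if k]
    return (
        BulkPanel(gene_ids, shared, values[keep_genes]),
        DrugResponsePanel(drug_ids, shared, auc),
    )


def rank_drug_biomarkers(bulk: BulkPanel, response: DrugResponsePanel) -> BiomarkerRanking:
    """Per-drug gene rankings by Pearson correlation with AUC.

    Correlations are pairwise-complete over the lines where the drug was
    measured; genes constant across a drug's measured lines are excluded
    from that drug's list. Rankings sort PCC descending, ties by gene id.
    """
    if bulk.sample_ids != response.sample_ids:
        raise StructuralError("panels must share an aligned sample order")
    X = bulk.values  # genes x lines
    genes = np.array(bulk.gene_ids)
    out_genes, out_pcc = {}, {}
    for di, drug in enumerate(response.drug_ids):
        y = response.auc[di]
        ok = np.isfinite(y)
        Xd, yd = X[:, ok], y[ok]
        xm = Xd - Xd.mean(axis=1, keepdims=True)
        ym = yd - yd.mean()
        sx = np.sqrt(np.sum(xm**2, axis=1))
        sy = np.sqrt(np.sum(ym**2))
        valid = (sx > 0) & (sy > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(valid, (xm @ ym) / (sx * sy), np.nan)
        r = np.clip(r, -1.0, 1.0)
        idx = np.flatnonzero(valid)
        order = idx[np.lexsort((genes[idx], -r[idx]))]
        out_genes[drug] = [str(g) for g in genes[order]]
        out_pcc[drug] = r[order]
    meta = {"n_lines": {d: int(np.sum(np.isfinite(response.auc[i])))
                        for i, d in enumerate(response.drug_ids)}}
    return BiomarkerRanking(list(response.drug_ids), out_genes, out_pcc, meta)


# ---------------------------------------------------------------------------
# preranked GSEA

def enrichment_score(ranked_genes, weights, gene_set, alpha: float = 1.0) -> float:
    """Running-sum enrichment score of a gene set against a ranked list.

    Walking the list top to bottom, set members (hits) advance the sum by
    |weight|^alpha normalized over hits, non-members retreat by
    1/(N - n_hits); the score is the signed extremum of largest
    magnitude, in [-1, 1]. Set members outside the list are dropped.
    """
    genes = list(ranked_genes)
    pos = {g: i for i, g in enumerate(genes)}
    hits = sorted(pos[g] for g in set(gene_set) if g in pos)
    if not hits:
        raise StructuralError("gene set has no overlap with the ranked list")
    w = np.abs(np.asarray(weights, dtype=float)) ** alpha
    return float(_es_from_positions(np.array(hits)[None, :], w, len(genes))[0])


def _es_from_positions(positions: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for rows of sorted hit positions (m x k) against a
    ranked list of length n with per-position hit weights w."""
    p = np.sort(positions, axis=1)
    k = p.shape[1]
    if k >= n:
        raise StructuralError("gene set must be smaller than the ranked list")
    wh = w[p]
    tot = wh.sum(axis=1, keepdims=True)
    unit = tot <= 0
    if np.any(unit):  # all-zero weights: fall back to unweighted steps
        wh = np.where(unit, 1.0, wh)
        tot = wh.sum(axis=1, keepdims=True)
    cum = np.cumsum(wh, axis=1) / tot
    miss = 1.0 / (n - k)
    i = np.arange(1, k + 1)
    tops = cum - (p + 1 - i) * miss                      # just after each hit
    bottoms = np.concatenate(
        [np.zeros((p.shape[0], 1)), cum[:, :-1]], axis=1
    ) - (p - (i - 1)) * miss                             # just before each hit
    top = np.maximum(tops.max(axis=1), 0.0)
    bottom = np.minimum(bottoms.min(axis=1), 0.0)
    # exact |top| == |bottom| ties (up to float noise) resolve positive
    return np.where(top >= -bottom - 1e-12, top, bottom)


def _null_es(w: np.ndarray, n: int, k: int, n_perm: int, rng) -> np.ndarray:
    """Null ES distribution over random size-k gene sets; exhaustive when
    every set can be enumerated within the permutation budget."""
    if k >= n:
        raise StructuralError("gene set as large as the ranked list")
    if comb(n, k) <= n_perm:
        sets = np.array(list(combinations(range(n), k)))
        return _es_from_positions(sets, w, n)
    u = rng.random((n_perm, n))
    positions = np.argpartition(u, k, axis=1)[:, :k]
    return _es_from_positions(positions, w, n)


def _perm_p(es: float, null: np.ndarray) -> float:
    same = null >= 0 if es >= 0 else null < 0
    extreme = np.abs(null[same]) >= abs(es) - 1e-12
    return (1.0 + int(extreme.sum())) / (1.0 + int(same.sum()))


def gsea_preranked(ranked_genes, weights, gene_set, n_perm: int = 1000,
                   seed: int = 0, alpha: float = 1.0):
    """Preranked GSEA: enrichment score plus a gene-set permutation
    p-value, (1 + #{|es_null| >= |es|, same sign}) / (1 + #{same sign}).

    Small instances (all same-size sets enumerable within ``n_perm``) are
    scored against the exhaustive null. Deterministic for a fixed seed.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    genes = list(ranked_genes)
    pos = {g: i for i, g in enumerate(genes)}
    hits = sorted(pos[g] for g in set(gene_set) if g in pos)
    if not hits:
        raise StructuralError("gene set has no overlap with the ranked list")
    w = np.abs(np.asarray(weights, dtype=float)) ** alpha
    es = float(_es_from_positions(np.array(hits)[None, :], w, len(genes))[0])
    rng = np.random.default_rng(seed)
    null = _null_es(w, len(genes), len(hits), n_perm, rng)
    return es, _perm_p(es, null)


# ---------------------------------------------------------------------------
# per-cell / per-population prediction

def _top_expressed(expr: np.ndarray, gene_ids, top_n: int):
    nz = np.flatnonzero(expr > 0)
    if nz.size == 0:
        return []
    order = nz[np.argsort(-expr[nz], kind="stable")]
    return [gene_ids[i] for i in order[:top_n]]


def predict_cells(
    expr: CountMatrix | pd.DataFrame,
    rankings: BiomarkerRanking,
    top_n: int = 250,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every cell against every drug ranking.

    The gene set is the cell's ``top_n`` most expressed genes (all
    nonzero genes when fewer are detected; ties by stable gene order) —
    only membership matters, so any monotone transform of the expression
    values gives the same call. Per cell, p-values are BH-corrected
    across drugs and the call is the drug with the most negative
    enrichment score among {fdr < alpha, es < 0}, otherwise
    "unclassified". Null ES distributions are shared across cells per
    (drug, effective set size), so results are deterministic in the seed
    and invariant to cell order.
    """
    if not rankings.drug_ids:
        raise StructuralError("empty biomarker ranking")
    if isinstance(expr, CountMatrix):
        values = expr.counts.toarray().astype(float)
        gene_ids, cell_ids = expr.gene_ids, expr.cell_ids
    else:
        values = expr.to_numpy(dtype=float)
        gene_ids, cell_ids = list(expr.index), list(expr.columns)
    drug_pos = {}
    drug_w = {}
    for d in rankings.drug_ids:
        drug_pos[d] = {g: i for i, g in enumerate(rankings.genes[d])}
        drug_w[d] = np.abs(rankings.pcc[d])
    null_cache: dict = {}
    rows = []
    rng = np.random.default_rng(seed)
    drug_seeds = {d: int(rng.integers(2**31)) for d in rankings.drug_ids}
    for ci, cell in enumerate(cell_ids):
        gene_set = _top_expressed(values[:, ci], gene_ids, top_n)
        if len(gene_set) < top_n:
            warnings.warn(
                f"cell {cell!r}: only {len(gene_set)} nonzero genes used"
            )
        es_list, p_list = [], []
        for d in rankings.drug_ids:
            pos = drug_pos[d]
            in_list = [g for g in gene_set if g in pos]
            # the set must be a strict subset of the ranked list; with a
            # tiny gene universe keep only the most expressed members
            if len(in_list) >= len(pos):
                in_list = in_list[: len(pos) - 1]
            hits = sorted(pos[g] for g in in_list)
            if not hits:
                es_list.append(np.nan)
                p_list.append(np.nan)
                continue
            w = drug_w[d]
            n = len(pos)
            es = float(_es_from_positions(np.array(hits)[None, :], w, n)[0])
            key = (d, len(hits))
            if key not in null_cache:
                null_cache[key] = _null_es(
                    w, n, len(hits), n_perm,
                    np.random.default_rng((drug_seeds[d] + len(hits)) % 2**31),
                )
            es_list.append(es)
            p_list.append(_perm_p(es, null_cache[key]))
        es_arr = np.array(es_list)
        p_arr = np.array(p_list)
        fdr = np.full_like(p_arr, np.nan)
        ok = np.isfinite(p_arr)
        if ok.any():
            fdr[ok] = multipletests(p_arr[ok], method="fdr_bh")[1]
        sig_neg = ok & (fdr < alpha) & (es_arr < 0)
        if sig_neg.any():
            call = rankings.drug_ids[int(np.nanargmin(np.where(sig_neg, es_arr, np.inf)))]
        else:
            call = UNCLASSIFIED
        for di, d in enumerate(rankings.drug_ids):
            rows.append({"cell_id": cell, "drug_id": d, "es": es_arr[di],
                         "p_value": p_arr[di], "fdr": fdr[di],
                         "call": call})
    return pd.DataFrame(rows)


def predict_cell(expr: pd.Series, rankings: BiomarkerRanking, top_n: int = 250,
                 alpha: float = 0.05, n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Single-cell convenience wrapper around :func:`predict_cells`."""
    df = pd.DataFrame({expr.name or "cell": expr})
    return predict_cells(df, rankings, top_n=top_n, alpha=alpha,
                         n_perm=n_perm, seed=seed)


def predict_population(cell_table: pd.DataFrame, alpha: float = 0.05):
    """Aggregate per-cell scores to a population-level call.

    Returns (per-drug DataFrame with the fraction of cells showing a
    significant negative enrichment score, population call). The call is
    the drug effective in the largest fraction of cells; ties go to the
    drug with the more negative median score; "unclassified" when no cell
    is sensitive to anything.
    """
    t = cell_table
    per_drug = []
    for d, sub in t.groupby("drug_id", sort=False):
        sig = (sub["fdr"] < alpha) & (sub["es"] < 0)
        per_drug.append({
            "drug_id": d,
            "sensitive_fraction": float(sig.mean()) if len(sub) else 0.0,
            "median_es": float(sub["es"].median()),
        })
    summary = pd.DataFrame(per_drug)
    if summary.empty or summary["sensitive_fraction"].max() == 0:
        return summary, UNCLASSIFIED
    best = summary["sensitive_fraction"].max()
    tied = summary[summary["sensitive_fraction"] == best]
    call = tied.sort_values(["median_es", "drug_id"]).iloc[0]["drug_id"]
    return summary, call


def differential_sensitivity(
    es_matrix: pd.DataFrame,
    group_labels: np.ndarray,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Compare predicted per-cell drug scores between two subpopulations.

    ``es_matrix`` is cells x drugs of enrichment scores. Per drug: a
    two-sided Mann-Whitney test between the groups, BH-corrected across
    drugs. A drug is group-specific when fdr < alpha_fdr, its median
    score in that group is negative and in the other group positive;
    "shared" when both medians are negative without a significant
    difference (equally effective on both); "none" otherwise.
    """
    groups = np.asarray(group_labels)
    uniq = list(pd.unique(groups))
    if len(uniq) != 2:
        raise StructuralError("exactly two groups required")
    g1, g2 = uniq
    m1, m2 = groups == g1, groups == g2
    if m1.sum() < 3 or m2.sum() < 3:
        raise StructuralError("both groups need at least 3 cells")
    rows = []
    pvals = []
    for d in es_matrix.columns:
        a = es_matrix.loc[m1, d].to_numpy(dtype=float)
        b = es_matrix.loc[m2, d].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(scipy.stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        pvals.append(p)
        rows.append({"drug_id": d, "p_value": p,
                     "median_es_group1": float(np.median(a)),
                     "median_es_group2": float(np.median(b))})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    cls = []
    for _, r in out.iterrows():
        sig = r["fdr"] < alpha_fdr
        if sig and r["median_es_group1"] < 0 and r["median_es_group2"] > 0:
            cls.append("group1-specific")
        elif sig and r["median_es_group2"] < 0 and r["median_es_group1"] > 0:
            cls.append("group2-specific")
        elif (not sig) and r["median_es_group1"] < 0 and r["median_es_group2"] < 0:
            cls.append("shared")
        else:
            cls.append("none")
    out["class"] = cls
    out.attrs["groups"] = (g1, g2)
    return out


# ---------------------------------------------------------------------------
# evaluation against a golden standard

def build_golden_standard(response: DrugResponsePanel, pctile: float = 5.0) -> GoldenStandard:
    """Binary sensitivity labels: per drug, z-score the AUC across lines
    and mark the lowest ``pctile`` percent sensitive (ties by stable line
    order). Z-scoring makes the labels invariant to affine transforms of
    a drug's AUC scale."""
    n_drugs, n_lines = response.auc.shape
    sens = np.zeros((n_drugs, n_lines), dtype=bool)
    for di in range(n_drugs):
        y = response.auc[di]
        ok = np.isfinite(y)
        n = int(ok.sum())
        if n < 20:
            warnings.warn(f"drug {response.drug_ids[di]!r}: fewer than 20 lines")
        yv = y[ok]
        if np.ptp(yv) == 0:
            warnings.warn(f"drug {response.drug_ids[di]!r}: constant AUC, no line sensitive")
            continue
        z = (yv - yv.mean()) / yv.std()
        n_sens = int(np.floor(n * pctile / 100.0))
        if n_sens == 0:
            continue
        order = np.argsort(z, kind="stable")[:n_sens]
        idx = np.flatnonzero(ok)[order]
        sens[di, idx] = True
    return GoldenStandard(list(response.drug_ids), list(response.sample_ids),
                          sens, percentile=pctile)


def evaluate_ppv_recall(
    predicted_fractions: pd.DataFrame,
    golden: GoldenStandard,
    fraction_grid=None,
) -> pd.DataFrame:
    """PPV/recall curve of population-level sensitivity calls.

    ``predicted_fractions`` is drugs x lines of sensitive-cell fractions.
    Sweeping a threshold over the grid, a (drug, line) pair is called
    positive when its fraction is >= the threshold and positive; PPV =
    TP/(TP+FP), recall = TP/(TP+FN) against the golden labels. PPV is NaN
    at thresholds with no positive calls.
    """
    gold = pd.DataFrame(golden.sensitive, index=golden.drug_ids,
                        columns=golden.sample_ids)
    drugs = [d for d in predicted_fractions.index if d in gold.index]
    lines = [s for s in predicted_fractions.columns if s in gold.columns]
    if not drugs or not lines:
        raise StructuralError("no shared drug x line grid with the golden standard")
    pred = predicted_fractions.loc[drugs, lines].to_numpy(dtype=float)
    truth = gold.loc[drugs, lines].to_numpy()
    if fraction_grid is None:
        fraction_grid = np.linspace(0.0, 1.0, 21)
    rows = []
    n_pos_truth = truth.sum()
    for t in fraction_grid:
        called = (pred >= t) & (pred > 0)
        tp = int((called & truth).sum())
        fp = int((called & ~truth).sum())
        ppv = tp / (tp + fp) if (tp + fp) else np.nan
        recall = tp / n_pos_truth if n_pos_truth else np.nan
        rows.append({"threshold": float(t), "ppv": ppv, "recall": recall,
                     "n_called": int(called.sum())})
    return pd.DataFrame(rows)
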