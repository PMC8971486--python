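"""Depth-aware Poisson test for heterogeneous biomarker expression.

A gene whose transcript counts follow a depth-proportional Poisson model
within a homogeneous cell population produces a predictable proportion of
zero counts. An observed zero proportion significantly above that
expectation (zero inflation) indicates that some cells genuinely do not
express the gene, i.e. cell-to-cell heterogeneity rather than sampling
dropout.

For gene x in cell i of a group with per-cell total UMI depth UMI^i:

    lambda_i = <UMI_x> * UMI^i / <UMI>
    P0_i     = exp(-lambda_i)

where <UMI_x> is the gene's mean count across the group's cells and <UMI>
the mean total depth. The observed zero fraction is compared one-sidedly
against an empirical null of zero fractions simulated from independent
Poisson(lambda_i) draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .types import CountMatrix, DrugResponsePanel, StructuralError


@dataclass
class ZeroInflationResult:
    gene_id: str
    group_id: str
    n_cells: int
    observed_zero_fraction: float
    expected_zero_fraction: float
    empirical_p: float
    n_sim: int
    seed: int


def _gene_row(counts: CountMatrix, gene: str) -> np.ndarray:
    try:
        g = counts.gene_ids.index(gene)
    except ValueError:
        raise StructuralError(f"gene {gene!r} not present") from None
    return np.asarray(counts.counts[g, :].todense()).ravel()


def expected_zero_profile(counts: CountMatrix, gene: str):
    """Per-cell expected rate lambda_i and zero probability P0_i for one
    gene under the depth-proportional Poisson model."""
    if counts.n_cells == 0:
        raise StructuralError("empty group")
    x = _gene_row(counts, gene)
    depths = counts.depths().astype(float)
    if np.any(depths == 0):
        raise StructuralError("zero-depth cell present")
    lam = x.mean() * depths / depths.mean()
    return lam, np.exp(-lam)


def zero_inflation_test(counts: CountMatrix, gene: str, n_sim: int = 10000,
                        seed: int = 0, group_id: str = "") -> ZeroInflationResult:
    """One-sided Monte-Carlo test for excess zeros.

    The observed zero fraction is compared against ``n_sim`` zero
    fractions, each simulated as the zero count of N independent
    Poisson(lambda_i) draws; the +1-corrected empirical p-value
    (1 + #{sim >= obs}) / (1 + n_sim) never reaches exactly zero.
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives a very coarse empirical p-value")
    lam, p0 = expected_zero_profile(counts, gene)
    x = _gene_row(counts, gene)
    n = x.size
    obs = np.mean(x == 0)
    rng = np.random.default_rng(seed)
    # only zero/nonzero matters: a Poisson(lambda_i) draw is zero with
    # probability exp(-lambda_i), so simulate Bernoulli indicators directly
    sim_zero_counts = np.zeros(n_sim)
    chunk = max(1, int(5e6 / max(n, 1)))
    for start in range(0, n_sim, chunk):
        stop = min(start + chunk, n_sim)
        u = rng.random((stop - start, n))
        sim_zero_counts[start:stop] = (u < p0).sum(axis=1)
    sim_frac = sim_zero_counts / n
    p = (1.0 + np.sum(sim_frac >= obs - 1e-12)) / (1.0 + n_sim)
    return ZeroInflationResult(
        gene_id=gene, group_id=group_id, n_cells=n,
        observed_zero_fraction=float(obs),
        expected_zero_fraction=float(np.mean(p0)),
        empirical_p=float(p), n_sim=n_sim, seed=seed,
    )


def zero_inflation_table(counts: CountMatrix, genes, group_column: str = "label",
                         n_sim: int = 10000, seed: int = 0,
                         bh_correct: bool = False) -> pd.DataFrame:
    """Run the zero-inflation test for each (gene, group) pair; one row
    per combination, mirroring a per-cell-line biomarker table."""
    labels = counts.labels(group_column)
    if labels is None:
        labels = np.array(["all"] * counts.n_cells)
    rows = []
    for gi, grp in enumerate(np.unique(labels)):
        sub = counts.subset_cells(labels == grp)
        for gj, gene in enumerate(genes):
            res = zero_inflation_test(
                sub, gene, n_sim=n_sim,
                seed=seed + 100003 * gi + gj, group_id=str(grp),
            )
            rows.append(vars(res))
    df = pd.DataFrame(rows)
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests
        df["fdr"] = multipletests(df["empirical_p"], method="fdr_bh")[1]
    return df


def expressing_fraction(counts: CountMatrix, gene: str,
                        group_column: str = "label") -> pd.Series:
    """Fraction of cells per group with at least one UMI for the gene."""
    x = _gene_row(counts, gene)
    labels = counts.labels(group_column)
    if labels is None:
        labels = np.array(["all"] * counts.n_cells)
    out = {}
    for grp in np.unique(labels):
        m = labels == grp
        out[str(grp)] = float(np.mean(x[m] >= 1)) if m.any() else np.nan
    return pd.Series(out, name=gene)


def target_potency_correlation(values: pd.DataFrame, response: DrugResponsePanel,
                               target_map: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each drug's potency (AUC) with the expression of its
    target gene(s) across shared cell lines.

    ``values`` is genes x lines (expressing fractions or bulk expression);
    multi-gene targets are averaged. A negative PCC means lines expressing
    the target are more sensitive (lower AUC). Drugs with p >= alpha are
    flagged non-significant; fewer than 3 shared lines or a constant
    vector yields a missing PCC.
    """
    auc = response.to_frame()
    rows = []
    for drug, genes in target_map.items():
        if drug not in auc.index:
            continue
        genes = [g for g in np.atleast_1d(genes) if g in values.index]
        if not genes:
            rows.append({"drug_id": drug, "pcc": np.nan, "p_value": np.nan,
                         "n_lines": 0, "significant": False})
            continue
        expr = values.loc[genes].mean(axis=0)
        shared = [s for s in expr.index if s in auc.columns]
        x = expr[shared].to_numpy(dtype=float)
        y = auc.loc[drug, shared].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"drug_id": drug, "pcc": np.nan, "p_value": np.nan,
                         "n_lines": int(x.size), "significant": False})
            continue
        r, p = scipy.stats.pearsonr(x, y)
        rows.append({"drug_id": drug, "pcc": float(r), "p_value": float(p),
                     "n_lines": int(x.size), "significant": bool(p < alpha)})
    return pd.DataFrame(rows)
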