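"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the real inputs carry —
a bulk cell-line panel with genes planted to correlate with drug potency,
negative-binomial UMI counts with lognormal sequencing depth and optional
structural zeros, two-subpopulation mixtures with differential drug
signatures, and replicate dose-combination viability grids with a known
Bliss excess — at desk scale, so the full pipeline is exercisable and
scoreable without downloads. Every generator is a pure function of its
spec: the same seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import (
    BiomarkerRanking,
    BulkPanel,
    CountMatrix,
    DoseCombinationAssay,
    DrugResponsePanel,
    StructuralError,
)


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic generators.

    Depth is lognormal in total UMI per cell (median exp(depth_log_mean));
    counts are negative binomial with shared size ``nb_size`` (smaller =
    more overdispersed). ``target_pcc`` is the planted gene-AUC
    correlation magnitude; ``zero_inflation_pi`` the structural-zero
    probability for flagged genes.
    """

    seed: int = 0
    n_genes: int = 2000
    n_lines: int = 40
    n_drugs: int = 30
    n_cells_per_line: int = 200
    depth_log_mean: float = float(np.log(5000.0))
    depth_log_sd: float = 0.25
    nb_size: float = 2.0
    n_sensitivity_genes: int = 50
    n_resistance_genes: int = 50
    n_planted_drugs: int = 3
    target_pcc: float = 0.8
    expr_noise_sd: float = 0.3
    zero_inflation_pi: float = 0.0
    mixing_proportion: float = 0.5
    signature_size: int = 100
    n_differential_drugs: int = 1
    bliss_true_excess: float = 0.0
    bliss_noise_sd: float = 0.02
    n_replicates: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise StructuralError("seed is mandatory")
        if abs(self.target_pcc) > 1:
            raise StructuralError("target |PCC| cannot exceed 1")
        for p in (self.zero_inflation_pi, self.mixing_proportion):
            if not 0 <= p <= 1:
                raise StructuralError("probabilities must lie in [0, 1]")


def _gene_ids(n):
    return [f"G{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# training panel

def make_training_panel(spec: GeneratorSpec):
    """Bulk log10(CPM+1) panel + AUC panel with planted correlations.

    For each of the first ``n_planted_drugs`` drugs, ``n_sensitivity_genes``
    genes are built to correlate -target_pcc with that drug's AUC (high
    expression = sensitive) and ``n_resistance_genes`` at +target_pcc;
    remaining genes are noise. Returns (bulk, response, truth) where truth
    maps drug -> {"sensitivity": [...], "resistance": [...]}.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    lines = [f"LINE{j:03d}" for j in range(spec.n_lines)]
    drugs = [f"DRUG{j:03d}" for j in range(spec.n_drugs)]

    base = rng.uniform(1.0, 3.0, size=spec.n_genes)
    values = base[:, None] + rng.normal(0.0, spec.expr_noise_sd,
                                        size=(spec.n_genes, spec.n_lines))
    auc = rng.normal(10.0, 2.0, size=(spec.n_drugs, spec.n_lines))

    rho = spec.target_pcc
    truth = {}
    n_per_drug = spec.n_sensitivity_genes + spec.n_resistance_genes
    gene_cursor = 0
    for di in range(min(spec.n_planted_drugs, spec.n_drugs)):
        z = (auc[di] - auc[di].mean()) / auc[di].std()
        sens = genes[gene_cursor: gene_cursor + spec.n_sensitivity_genes]
        res = genes[gene_cursor + spec.n_sensitivity_genes: gene_cursor + n_per_drug]
        for sign, members in ((-1.0, sens), (+1.0, res)):
            for g in members:
                gi = genes.index(g)
                eps = rng.normal(size=spec.n_lines)
                x = sign * rho * z + np.sqrt(1 - rho**2) * eps
                # amplitude ~0.8 on the log10(CPM+1) scale: the dynamic
                # range of a variable biomarker, so sensitivity markers
                # reach the top-expressed set of sensitive lines' cells
                values[gi] = 2.0 + 0.8 * x
        truth[drugs[di]] = {"sensitivity": list(sens), "resistance": list(res)}
        gene_cursor += n_per_drug
    values = np.clip(values, 0.0, None)
    return (
        BulkPanel(genes, lines, values),
        DrugResponsePanel(drugs, lines, auc),
        truth,
    )


# ---------------------------------------------------------------------------
# single cells

def _nb_counts(rng, mean: np.ndarray, size: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def make_line_profiles(spec: GeneratorSpec, distinctness: float = 1.0,
                       seed_offset: int = 2) -> np.ndarray:
    """Distinct relative expression profiles, one column per line.

    A shared base profile jittered per line by lognormal factors of
    log-sd ``distinctness``; larger values separate lines more strongly
    (1.0 gives clearly separable but overlapping transcriptomes).
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    base = rng.uniform(0.2, 1.0, size=spec.n_genes)
    prof = base[:, None] * rng.lognormal(0.0, distinctness,
                                         size=(spec.n_genes, spec.n_lines))
    return prof / prof.sum(axis=0)


def line_profiles_from_panel(bulk: BulkPanel) -> np.ndarray:
    """Relative expression profiles (columns sum to 1) from a
    log10(CPM+1) panel."""
    cpm = np.maximum(10.0 ** bulk.values - 1.0, 0.0)
    tot = cpm.sum(axis=0)
    tot[tot == 0] = 1.0
    return cpm / tot


def make_single_cells(spec: GeneratorSpec, line_profiles: np.ndarray,
                      line_ids=None, zero_inflated_genes=None,
                      seed_offset: int = 1) -> CountMatrix:
    """Per-line negative-binomial UMI counts with lognormal depth.

    ``line_profiles`` is genes x lines with columns summing to 1.
    ``zero_inflated_genes`` (gene row indices) receive structural zeros
    with probability ``zero_inflation_pi`` per cell, independent of
    sampling dropout. Cell labels go in the ``label`` metadata column.
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    n_genes, n_lines = line_profiles.shape
    if line_ids is None:
        line_ids = [f"LINE{j:03d}" for j in range(n_lines)]
    genes = _gene_ids(n_genes)
    cols, cell_ids, labels = [], [], []
    zi = np.asarray(zero_inflated_genes, dtype=int) if zero_inflated_genes is not None else None
    for li in range(n_lines):
        prof = line_profiles[:, li]
        depths = rng.lognormal(spec.depth_log_mean, spec.depth_log_sd,
                               size=spec.n_cells_per_line)
        for ci in range(spec.n_cells_per_line):
            mu = prof * depths[ci]
            x = _nb_counts(rng, mu, spec.nb_size)
            if zi is not None and spec.zero_inflation_pi > 0:
                off = rng.random(zi.size) < spec.zero_inflation_pi
                x[zi[off]] = 0
            cols.append(x)
            cell_ids.append(f"{line_ids[li]}_C{ci:04d}")
            labels.append(line_ids[li])
    counts = sp.csr_matrix(np.column_stack(cols))
    meta = pd.DataFrame({"label": labels})
    return CountMatrix(genes, cell_ids, counts, cell_meta=meta)


# ---------------------------------------------------------------------------
# two-population mixture

def make_two_population_mixture(spec: GeneratorSpec):
    """Mixture of two subpopulations with planted differential drugs.

    Both subpopulations share a base profile; each gets a disjoint
    up-regulated signature of ``signature_size`` genes. A synthetic
    biomarker ranking is built per drug: the first
    ``n_differential_drugs`` drugs carry subpopulation A's signature in
    their sensitivity tail (most negative PCC), so group A should show
    negative enrichment for them; the rest are null rankings.

    Returns (counts, subpop_labels, rankings, truth_flags) with
    truth_flags a per-drug bool Series (True = group-A-specific).
    """
    rng = np.random.default_rng(spec.seed + 7)
    n_genes = spec.n_genes
    genes = _gene_ids(n_genes)
    k = spec.signature_size
    sig_a = np.arange(0, k)
    sig_b = np.arange(k, 2 * k)
    base = rng.uniform(0.2, 1.0, size=n_genes)
    prof_a, prof_b = base.copy(), base.copy()
    prof_a[sig_a] *= 20.0
    prof_b[sig_b] *= 20.0
    profiles = np.column_stack([prof_a / prof_a.sum(), prof_b / prof_b.sum()])

    n_a = int(round(spec.n_cells_per_line * spec.mixing_proportion))
    n_b = spec.n_cells_per_line - n_a
    cols, cell_ids, labels = [], [], []
    depths = rng.lognormal(spec.depth_log_mean, spec.depth_log_sd,
                           size=spec.n_cells_per_line)
    for ci in range(spec.n_cells_per_line):
        which = 0 if ci < n_a else 1
        x = _nb_counts(rng, profiles[:, which] * depths[ci], spec.nb_size)
        cols.append(x)
        cell_ids.append(f"MIX_C{ci:04d}")
        labels.append("A" if which == 0 else "B")
    counts = CountMatrix(genes, cell_ids, sp.csr_matrix(np.column_stack(cols)),
                         cell_meta=pd.DataFrame({"subpopulation": labels}))

    drugs = [f"DRUG{j:03d}" for j in range(spec.n_drugs)]
    r_genes, r_pcc = {}, {}
    flags = {}
    gene_arr = np.array(genes)
    sig_union = np.concatenate([sig_a, sig_b])
    for di, d in enumerate(drugs):
        pcc = np.sort(rng.uniform(-1.0, 1.0, size=n_genes))[::-1]
        if di < spec.n_differential_drugs:
            # plant A's signature into the sensitivity (bottom) tail
            perm = rng.permutation(n_genes)
            others = perm[~np.isin(perm, sig_a)]
            order = np.concatenate([others, rng.permutation(sig_a)])
            flags[d] = True
        else:
            # null drug: treat the phenotypes exchangeably — signature
            # genes of A and B occupy matched ranks (paired adjacent
            # slots, random within-pair order), so neither group is
            # systematically enriched and the class rule stays calibrated
            rest = rng.permutation(np.setdiff1d(np.arange(n_genes), sig_union))
            slots = np.sort(rng.choice(n_genes, size=2 * k, replace=False))
            order = np.empty(n_genes, dtype=int)
            a_perm, b_perm = rng.permutation(sig_a), rng.permutation(sig_b)
            paired = np.empty(2 * k, dtype=int)
            for j in range(k):
                if rng.random() < 0.5:
                    paired[2 * j], paired[2 * j + 1] = a_perm[j], b_perm[j]
                else:
                    paired[2 * j], paired[2 * j + 1] = b_perm[j], a_perm[j]
            order[slots] = paired
            order[np.setdiff1d(np.arange(n_genes), slots)] = rest
            flags[d] = False
        r_genes[d] = [str(g) for g in gene_arr[order]]
        r_pcc[d] = pcc
    rankings = BiomarkerRanking(drugs, r_genes, r_pcc)
    return counts, np.array(labels), rankings, pd.Series(flags)


# ---------------------------------------------------------------------------
# dose-combination assays

def make_combination_assay(spec: GeneratorSpec, n_doses_a: int = 4,
                           n_doses_b: int = 5):
    """Replicate Hill-margin dose grid with a known Bliss excess.

    Single-agent viabilities follow Hill curves; combination inhibition
    is the Bliss expectation plus ``bliss_true_excess`` percentage points
    (clamped into [0, 1]), with multiplicative Gaussian noise of sd
    ``bliss_noise_sd`` on every well. Returns (assay, realized true mean
    excess) — the realized value accounts for clamping at extreme doses.
    """
    rng = np.random.default_rng(spec.seed + 13)
    doses_a = np.geomspace(0.1, 10.0, n_doses_a)
    doses_b = np.geomspace(0.05, 50.0, n_doses_b)

    def hill(d, ec50, h=1.0):
        return 1.0 / (1.0 + (d / ec50) ** h)

    va = hill(doses_a, 1.0)
    vb = hill(doses_b, 2.0)
    ia, ib = 1.0 - va, 1.0 - vb
    i_bliss = ia[:, None] + ib[None, :] - ia[:, None] * ib[None, :]
    i_true = np.clip(i_bliss + spec.bliss_true_excess / 100.0, 0.0, 1.0)
    true_excess = float((100.0 * (i_true - i_bliss)).mean())

    r = spec.n_replicates
    if r < 2:
        import warnings
        warnings.warn("single replicate: downstream CI will be undefined")

    def noisy(v, shape):
        return np.maximum(v * (1.0 + rng.normal(0.0, spec.bliss_noise_sd, shape)), 1e-6)

    assay = DoseCombinationAssay(
        doses_a=doses_a,
        doses_b=doses_b,
        viability=noisy(1.0 - i_true, (r, n_doses_a, n_doses_b)),
        single_a=noisy(va, (r, n_doses_a)),
        single_b=noisy(vb, (r, n_doses_b)),
        dmso=noisy(1.0, (r,)),
        drug_a="afatinib-like",
        drug_b="etoposide-like",
    )
    return assay, true_excess
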