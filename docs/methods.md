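# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want written down.

## Normalization (GF-ICF)

Counts are CPM-scaled per cell and weighted by the inverse cell frequency
ICF(g) = log(1 + N/n_g), where n_g is the number of cells detecting gene
g; each cell column is then rescaled to unit L2 norm. The L2 step absorbs
any per-cell constant, so raw count fractions and CPM give identical
output. The log(1 + N/n) smoothing keeps every weight strictly positive
(a gene detected in all cells still carries log 2); `log_ratio` is
available as a config variant. Genes detected in fewer than 5% of cells
are removed before normalization; a gene detected in zero cells is an
error rather than a silent infinity.

Mapping new cells onto a reference freezes the reference ICF weights and
gene universe: query genes missing from the reference are dropped,
reference genes missing from the query are imputed as zero, and a warning
reports the overlap when under 50%. Freezing matters — refitting ICF on a
shifted population changes the weights (tested explicitly) and would move
the reference embedding under the query's feet.

## Quality control

Cells are kept when total UMI ≥ 2500, detected genes > 1000 and
mitochondrial fraction < 0.5 (boundaries read literally: "at least" is
inclusive, "more than"/"less than" strict). Putative multiplets are
removed as Tukey depth outliers (k = 3) computed per cell line when
labels exist, since a doublet's depth is only outlying relative to its
own line; the global distribution is the fallback.

## Atlas construction and classification

Normalized cells are summarized by their first 10 principal components
(deterministic full SVD; component signs fixed by making each component's
largest-magnitude loading positive so refits are bit-identical). The cell
graph connects each cell to its 50 nearest neighbours under the L1
distance; edges are weighted by the Jaccard overlap of the two
*self-inclusive* kNN neighbourhoods — self-inclusion makes duplicate
cells maximally similar (weight 1) instead of accidentally disjoint, the
convention shared-nearest-neighbour implementations use. Louvain
clustering runs once at resolution 0.25 with an exposed seed (no
consensus). Markers come from a two-sided Wilcoxon rank-sum of each gene
in a cluster versus the rest, BH-corrected within cluster, with log2 fold
change of mean normalized expression using pseudocount 1 (the pseudocount
and the use of normalized means are our convention; exports for
deconvolution tools apply the FDR < 0.5, log2FC > 0.25 filter).

New cells are classified by majority vote among the k = 100 nearest
reference cells in the frozen PC space. A nonlinear 2-D embedder (UMAP or
similar) can be plugged in for visualization, but classification
deliberately stays in PC space: it is deterministic, dependency-free and
reproducible. Vote ties break by smaller mean distance, then
lexicographic label; a query cell with no counts on the atlas gene set is
`unclassified`.

## Zero-inflation test

The null model is depth-proportional Poisson sampling:
λᵢ = ⟨UMIₓ⟩·UMIⁱ/⟨UMI⟩ per cell, P⁰ᵢ = exp(−λᵢ), with ⟨UMIₓ⟩ estimated on
the group's (cell line's) own cells. The observed zero fraction is
compared one-sidedly to `n_sim` simulated zero fractions (default
10,000); since only zero/nonzero matters, the simulation draws Bernoulli
indicators with probability P⁰ᵢ directly, which is exactly equivalent to
drawing Poisson counts and much faster. The p-value uses the standard +1
Monte-Carlo correction, so it is never exactly zero and is bounded below
by 1/(n_sim+1).

A property worth knowing: because ⟨UMIₓ⟩ is estimated from the same cells
whose zero fraction is tested, the plug-in null is slightly conservative —
measured type-I error at the 0.05 level is ≈ 0.01–0.04 depending on the
gene's mean expression, never above nominal. This is inherent to the
plug-in procedure (the estimated mean is negatively correlated with the
observed zero count) and is the protective direction: reported
heterogeneity calls are not inflated. Power against 50% structural zeros
at mean rate 2 with 500 cells is ≈ 1. No multiple-testing correction is
applied by default across biomarker × line grids (raw p < 0.05 is the
reporting convention); a BH option exists.

## DREEP

Training filters: drugs measured in < 25 lines are dropped; genes with
mean log₁₀(CPM+1) ≤ 0.01 ("poorly expressed" — no published cutoff
exists, so this conservative floor is exposed as config) and genes in the
lowest 5% of expression entropy are removed. Entropy is the Shannon
entropy of each gene's across-line expression histogram on 10 panel-wide
bins — panel-wide bins make a near-constant gene score ~0 (uninformative)
regardless of its absolute level; per-gene bins would do the opposite.

Correlations are pairwise-complete over measured AUCs; genes constant
across a drug's lines are excluded from that drug's list; ranking ties
break by gene id.

GSEA uses weight exponent α = 1 on |PCC| (the classic weighted
statistic); α = 0 gives the unweighted Kolmogorov–Smirnov-like walk. The
permutation null draws random same-size gene sets (n_perm = 1000
default), switching to exhaustive enumeration whenever C(N, k) ≤ n_perm,
so small instances are exact. The p-value is one-sided within the sign of
the observed score with the +1 correction. When |max| and |min| of the
walk tie to within 1e-12 the positive extremum wins (a fixed tie-break so
scores are reproducible across BLAS/libm builds).

Per-cell significance for the sensitivity call is BH across drugs within
the cell at α = 0.05 (the source convention is unstated; the threshold is
config). Only the membership of the top-250 set matters, so calls are
invariant to monotone transforms of a cell's expression values. The
population call is the drug sensitive in the largest fraction of cells
(ties: more negative median score). Differential sensitivity between two
subpopulations uses a two-sided Mann–Whitney on per-cell scores per drug,
BH across drugs; "group-specific" additionally requires the group medians
to straddle zero, and "shared" means both medians negative without a
significant difference. The golden standard marks, per drug, the lowest
5% of z-scored AUCs as sensitive (stable-order ties, so exactly ⌊0.05·n⌋
lines), making labels invariant to affine rescaling of a drug's AUC axis.

## Two-state interconversion model

dH⁺/dt = (g₊ − k₊₋ − δ·u(t))·H⁺ + k₋₊·H⁻,
dH⁻/dt = k₊₋·H⁺ + (g₋ − k₋₊)·H⁻, with u(t) an on/off schedule. The system
is linear, so the integrator applies the exact matrix exponential piecewise
between schedule breakpoints — there is no step-size error to tune, and
the test suite checks agreement with an independent adaptive RK solver to
1e-6 relative. Defaults: g₊ = g₋ = ln2/72 h⁻¹ (a ~72 h doubling time);
δ = 0.01 h⁻¹ as a moderate kill rate (treated pure-plus viability ≈ 0.59
at 72 h). The regime structure is: switching much slower than the cell
cycle → strongly sort-dependent drug effect; comparable (k ≈ ln2/72) →
similar effect on either sorted population (within twofold at the default
δ); much faster → the populations are effectively one, minimal
differential effect. Whether the drug term represents death or growth
arrest is not distinguishable at this level; the growth rates are per-state
and configurable, which covers state-dependent cycle lengths.

## Bliss synergy

Per replicate, inhibition I = clamp(1 − V/V_DMSO, 0, 1) (clamping prevents
super-viability noise from producing out-of-range Bliss expectations);
excess = 100·(I_obs − (I_a + I_b − I_a·I_b)) per dose pair; the summary
score averages the replicate-mean grid. The confidence half-width is a
t-based 95% interval across the per-replicate grid means — assay
replicates are the independent unit. Classification applies the ±10
percentage-point additive band strictly to the mean score; a score outside
the band whose CI overlaps it is still labelled non-additive, with the CI
left to the reader (a looser, CI-overlap reading exists in the
literature).

## Synthetic data: what it emulates and what it does not

Generators are pure functions of a seeded spec (same seed → byte-identical
output). Desk-scale defaults: 2,000 genes, 40 lines, 30 drugs, 200
cells/line, lognormal depth (median 5,000 UMI, log-sd 0.25),
negative-binomial counts with size 2, planted gene–AUC correlations of
|PCC| = 0.8 with log-scale amplitude 0.8 (the dynamic range of a variable
biomarker, so sensitivity markers genuinely reach a sensitive cell's
top-expressed set), structural zeros injected independently of sampling
dropout.

Deliberately absent: gene–gene correlation structure, batch effects,
doublets, ambient RNA, and realistic pathway composition. Passing tests
therefore demonstrate that the statistics recover planted structure under
the stated noise model — they do not certify performance on real tumours,
where marker bleed-through and correlated programmes will lower effect
sizes.

Two generator choices worth flagging. (1) In the two-subpopulation
mixture, "null" drugs place the two subpopulations' signature genes at
matched ranks (paired adjacent slots): with a fully random ranking, the
fixed random placement of one signature separates the groups for *every*
drug — a real difference, not a test error — so a false-positive rate is
only meaningful under a phenotype-exchangeable null. (2) The combination
assay applies the requested true excess uniformly before clamping
inhibition into [0, 1], and reports the realized (post-clamp) mean excess
as truth.

## Problem sizes

The test and acceptance runs use reduced sizes chosen to exercise every
code path with comfortable statistical margins: 200 lines × 2,000 genes ×
30 drugs for training recovery, 40 lines × 10 cells for the end-to-end
PPV/recall curve, 1,000 null genes × 500 cells × 2,000 draws for
calibration, 8 lines × 120 cells for atlas mapping. These are the
package's own desk-scale conditions; all scale linearly if enlarged.
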