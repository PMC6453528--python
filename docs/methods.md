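# Methods

## Data model

The unit of input is a directed relation triple *(agent, relation,
theme, article_count)*: one literature assertion that the agent gene
causally acts on the theme gene, supported by `article_count` distinct
documents. Relations come from a catalog of canonical interaction types;
the catalog's only modelling role is directionality — Binding-type
relations are symmetric and contribute their count to both orientations,
every other relation only to (agent, theme). All relation types for a
given ordered pair collapse into one cell, because the factorized object
is a gene × gene matrix, not gene × (gene, relation).

Rows and columns index the *same* gene universe (every symbol observed
anywhere in the triples), so the matrix is square and any gene can be
scored as a downstream or upstream partner of any other. Self-loops are
kept in the matrix (they carry degree information) but never appear in
ranked outputs — a gene is not a biomarker candidate for itself.

The matrix stores integer article counts with a derived binary view.
This reconciles the two natural readings of the input — a binary
"relation exists" matrix versus per-cell article counts — via the
implicit-feedback formulation below, where the binary view supplies the
preference targets and the counts supply confidence weights. A
`use_counts=False` switch binarizes confidences for users who want the
strict 0/1 variant.

## Factorization

Implicit-feedback ALS (Hu–Koren–Volinsky). Preferences
p_ij = 1[counts_ij > 0], confidences c_ij = 1 + α·counts_ij, objective

    J(W, H) = Σ_ij c_ij (p_ij − W_i·H_j)² + λ(‖W‖² + ‖H‖²)

summed over **all** M×N cells: unobserved pairs are weak negative
evidence at unit confidence, observed pairs positive evidence at
confidence c. W is agents × k, H is k × themes, and the score surface
X₂ = W·H conforms with the input matrix; X₂[a, b] is the consistency
score of the directed relation a → b.

Each half-step solves, exactly, the ridge system for one side given the
other; for row u,

    W_u = (HᵀC_uH + λI)⁻¹ Hᵀ C_u p_u,

with HᵀC_uH = HᵀH + H_nzᵀ diag(α·counts_nz) H_nz, so a sweep costs
O(nnz·k² + (M+N)·k³) regardless of matrix size. Because every half-step
is an exact block minimization of the joint objective, the per-sweep
loss trajectory is non-increasing — this is asserted, not assumed, and
the recorded trajectory is part of the results object.

Defaults: rank 20, 20 sweeps, λ = 0.1, α = 0.1, counts as confidence.
α = 0.1 is low by recommender-system standards (where α ≈ 40 is
common); it weights an observed single-article pair only 10% above the
unobserved background, which is appropriate for literature data where a
single supporting sentence is weak evidence, and it produces score
surfaces in the observed 0–0.6 range rather than saturating near 1.

Numerical choices: factors initialize from a seeded uniform
distribution scaled by `init_scale = 0.01` — small enough that the
first ridge solves are dominated by the data rather than the random
start; λ > 0 keeps every normal-equation matrix positive definite, and
the systems are solved with the standard LAPACK dense solver. λ = 0 on
an all-zero matrix is rejected as degenerate. Fits are bitwise
deterministic given (matrix, config, seed).

## Ranking and filtering

Ranking all genes for a directed relation to a target needs only **one**
factorization: candidate pairs are already zero in the preference
matrix, so their reconstructed scores are genuine predictions rather
than memorized entries. Scores sort descending; exact ties (rare, since
scores are dense floats) break lexicographically by symbol so output is
deterministic. `known` flags genes whose directed pair with the target
is nonzero in the observed matrix; they stay ranked in place, with
`novel_only()` as the filtered variant.

`remove_direct` drops every gene with a direct edge to *or* from the
target (both orientations — the conservative reading, since a direct
edge in either direction makes a gene a known, proximal partner rather
than a novel indirect hypothesis), then re-ranks survivors 1..m
preserving order.

The leave-one-out `consistency_score` of an *existing* relationship
zeroes its cell, refits, and compares the reconstructed score against
the same procedure applied to a background sample of other existing
relationships (default 200 cells, uniformly sampled with a given seed;
200 bounds the refit cost while giving half-percent resolution). The
returned value is the focal score's percentile within the background
sample. Evaluating an absent relationship is a no-op on the matrix by
construction.

## Evaluation

ROC AUC uses the rank-sum (Mann–Whitney) convention: the probability
that a random positive outranks a random negative, ties counted half.
On a strict total ordering this equals brute-force pair counting and
the trapezoidal area under the stepwise ROC curve; both identities are
property-tested. Tie-aware evaluation (`roc_auc_from_scores`) uses
midranks and is cross-checked against scikit-learn.

`recall_at_percentile` defaults to *nearest-percent* rounding: a gene
whose percentile rounds to the threshold (e.g. 20.41% → 20%) counts as
inside the band. This matches how such tables are read when percentile
columns are displayed as rounded integers; the strict floor-rank mode
is available for transparency. Percentile display follows the same
table convention: nearest integer percent, except values that would
display as 0% get two decimals.

The co-occurrence baseline ranks genes by raw abstract co-occurrence
counts with the target using competition ranking (tied genes share the
rank 1 + number of strictly better genes). Computing the baseline's AUC
from published positive ranks alone requires a tie convention, because
the negatives' tie blocks are unpublished: `litrank.btk` treats the
zero-count block (whose size is derivable from the shared bottom rank)
as fully tied at half credit and nonzero positives as beating all genes
ranked after them. The result (≈0.63) is the conservative end of the
plausible range and is reported as a diagnostic, not asserted — other
defensible conventions shift it by up to ~0.1.

Gold genes missing from the ranked universe are excluded from numerator
and denominator with a logged warning; silently counting them as misses
would deflate AUC by an unverifiable amount.

## Explanation

For a query gene, every other gene is scored on the 2×2 contingency
over the partner universe (all genes except the pair): partner
connected to query × partner connected to the other gene, where
"connected" is the orientation-collapsed binary view — each gene thus
has a single total-connections number. The statistic is the 1-df
chi-squared without continuity correction (a Yates-corrected variant is
available); degenerate tables with an empty margin return (0, p = 1).
Genes whose overlap falls *below* its independence expectation keep
their plain p-value but sort after all enriched genes — a significant
deficit is dissimilarity. `explain_prediction` filters the similar list
to genes that themselves carry the predicted directed relation and
attaches any direct observed edges for the pair, giving the analyst
both the analogy and the primary evidence.

## Synthetic networks

The generator emulates the statistical structure the inference relies
on, not the text-mining process. Each gene loads one dominant latent
factor (its "pathway") on both its agent and theme side — a Gamma(4, 1)
loading over a weak 0.05·Exp(1) background — and edge probabilities are
the factor inner products rescaled to a target density (specs that
would saturate >10% of cells at probability 1 are rejected as
infeasible). Article counts are geometric with mean `count_dispersion`
(default 1.5): most pairs cite 1–2 articles, a few many, as in real
literature networks. The target's true downstream set is the top block
of its theme-affinity vector; the known subset keeps (or gains) its
direct edges, while the held-out subset loses every direct edge with
the target in both orientations — so recovery must come from indirect
structure, mirroring the validation situation where expert biomarkers
are mostly not direct neighbors of the target. A `noise_edge_fraction`
rewires that share of edges uniformly (never reinstating held-out
target edges).

Default fixture: 500 genes, planted rank 2, density 0.10 (mean degree
~50, the scale of a densely studied pathway neighborhood), 20 known +
10 held-out downstream genes. The density matters: at literature-wide
sparsity (~2%) a rank-20 fit on a 500-gene universe has too little data
per gene and fits Bernoulli sampling noise instead of the planted
structure (a rank-2 truncated SVD recovers held-out genes at AUC ≈ 0.98
where a rank-20 one drops to chance), so the benchmark fixture is
deliberately dense enough that the default configuration is in its
operating regime. `benchmark_recovery` reports mean/spread of the
recovery AUC over independent generator+fit seeds, plus the
co-occurrence baseline on the same draws — which by construction cannot
rank the held-out genes above the unconnected mass, since their direct
counts are zero.

What passing synthetic benchmarks does **not** show: robustness to the
systematic biases of real literature networks — citation popularity
confounding, extraction errors correlated by journal or era, relation
types of very different reliability, and gene-symbol ambiguity. The
generator's rewiring noise is uniform, which is the easiest noise to
average away.

## Problem sizes

The bundled benchmarks run on 120–600-gene universes with 5-seed
replication, sizes at which every stage (including the leave-one-out
refits) completes in seconds while leaving the planted-structure
recovery well away from its thresholds; the same code paths run
unchanged on full-literature matrices (~13,600 genes), where one
rank-20 fit is minutes of CPU.

## Known limitations

- One factorization serves all candidate pairs for a target; the
  leave-one-out protocol is only applied to existing relationships.
- The chi-squared independence test treats partners as i.i.d., which
  degree heterogeneity violates; p-values are rankings aids, not
  calibrated error rates.
- The co-occurrence baseline AUC depends on unpublished tie structure
  (see above) and is reported, not asserted.
- No species, disease-context, or confidence filtering of edges; all
  triples are ingested identically whether their relation was stated
  directly or through an intermediate process phrase.
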