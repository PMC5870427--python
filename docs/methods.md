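# Methods

## Signatures

Compound signatures are purely fold-change-ranked: no variance model or
per-gene p-value is computed, because the pipeline's similarity statistics
operate on ranked gene sets, not on effect estimates. Two forms are used:

* **top-k** (default k = 200 per direction): the k genes with the largest and
  the k with the smallest log2 fold change. This fixed 2k size makes the Dice
  denominator a constant (2k = 400 genes), so similarity is a pure overlap
  count. It requires at least 2k measured genes.
* **threshold** (used when restricting to a pathway gene set): genes with
  fold-change ratio strictly above 1.5 (up) or strictly below 1/1.5 (down),
  i.e. |log2 FC| > log2 1.5 ≈ 0.585. The threshold is read two-sided on the
  ratio scale; a one-sided reading would leave the down set empty and make
  direction-aware similarity degenerate.

The internal canonical scale is log2, so up- and down-regulation are
symmetric around 0; readers accept raw-ratio input and transform it, and
reject non-positive ratios.

Ties are broken by ascending lexicographic gene id at either top-k boundary.
In the degenerate case where one tie block spans both boundaries (e.g. a
constant profile), the down set is filled from genes not already claimed by
the up set, preserving disjointness; with continuous fold changes this rule
never fires.

## Dice similarity

For top-k signatures, Dice(i,j) = (N_up + N_down) / 2k, where N_up and N_down
count genes shared with matching direction. Cross-direction overlap (up in
one compound, down in the other) contributes nothing and is not penalized.
For threshold signatures, whose sizes vary, the standard generalized Dice
form 2(N_up + N_down)/(|up_i|+|down_i|+|up_j|+|down_j|) is the default; a
fixed denominator (e.g. 800) is available behind a flag for direct
comparability with top-200 analyses, since threshold-mode results cannot
disambiguate which convention an external analysis used. Two empty
signatures score 0 — absence of response is treated as no evidence of
similarity, not as perfect agreement. The diagonal is 1 by definition and is
excluded from all means and all downstream ranking.

## PRank

The PRank score between systems A and B: binarize A's off-diagonal
similarities at a cutoff (strictly greater), use them as labels for B's
similarities, and compute ROC-AUC via the Mann–Whitney rank formulation
(midranks, so each tied positive–negative comparison contributes 1/2). Which
system supplies labels is arbitrary, so both directions are computed and
averaged; the mean is symmetric under swapping the systems and the
per-direction AUCs are always retained. AUC is invariant to any strictly
increasing transform of the scores, so PRank depends only on each system's
ranking of compound pairs.

Cutoff choice: the fixed default is Dice > 0.4. That value is meaningful for
400-gene signatures on liver TGx data, where it sits near the 95th percentile
of pairwise similarities; on data with a different similarity distribution a
fixed cutoff can label every pair negative (or positive), leaving the AUC
undefined. The quantile mode (`quantile=0.95`) binarizes each system at the
95th percentile of its own off-diagonal values and is what the synthetic
recovery analyses use. A direction whose labels are single-class is reported
as undefined and the result flagged partial — never silently dropped.

Compound sets are intersected automatically between the two systems (logged),
mirroring the common-compound restriction any cross-system comparison needs.

## Therapeutic-category stability

For a focal ATC level-2 category, ratio = mean(within-category Dice) /
mean(across-category Dice). Multi-label compounds make "across" ambiguous:
a pair sharing any level-2 code is excluded from the across pool, and the
across pool is restricted to pairs involving exactly one member of the focal
category, with the partner itself annotated (per-category mode, the default).
A global mode (all annotated no-shared-code pairs not involving the category)
is available and the mode used is recorded in every result row. Categories
need at least `min_members = 5` compounds; smaller ones are omitted with a
log note rather than an error in table mode. No significance test is
attached to the ratios; under random label assignment they center at 1, which
the test suite verifies by permutation.

## Pathway enrichment and POP

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) with the measured genes of the matrix as universe; the tested gene
list is the pooled 2k-gene signature (over-representation is
direction-agnostic). BH adjustment is applied across pathways within one
compound — the family induced by one compound's enrichment query. Pathways
are then ranked per system by perturbation frequency: the number of compounds
with adjusted p ≤ 0.05. Frequency ties are broken lexicographically by
pathway id so rankings are deterministic. The adjusted p-value is used both
for the significance call and for the frequency count.

POP(L) = |top-L(A) ∩ top-L(B)| / L over L = 5..60 by default, summarized by
the mean over L. The full curve is always reported because no single L is
canonical. If either ranking is shorter than the requested depths, the range
is truncated to the shorter list (logged); if it is shorter than every
requested depth, the full lists are compared at a single depth.

Gene-set collections keep only sets with strictly more than `min_size = 200`
genes (after optional homology mapping), so that threshold-mode signatures
restricted to a set retain enough genes to be informative. Homology
translation maps each source id to all of its targets, passes ids already in
the target namespace through, and drops ids in neither — making translation
idempotent.

## Synthetic data generator

The generator emulates S assay systems observing noisy versions of shared
per-compound transcriptional effects, with three controllable structures:

* **inter-system concordance**: a correlation matrix R over systems; latent
  signals are mixed through the Cholesky factor of R so the latent profiles
  of systems s, s′ correlate at exactly R_ss′. The dial is latent-signal
  correlation, not raw-value correlation, because signatures depend on the
  rank order of fold changes. A semidefinite-tolerant Cholesky keeps ρ = 1
  (identical systems) representable.
* **therapeutic categories**: compounds of a category draw a fraction α of
  their latent effect from a shared sparse prototype,
  t_c = (α·p_cat + (1−α)·u_c)/√(α²+(1−α)²); the normalization keeps signal
  variance independent of α.
* **planted pathways**: fixed gene sets whose genes receive a consistent
  signed log2 boost in compounds of affected categories; decoy gene sets of
  the same size are always generated so enrichment specificity is testable.

Sparse fields put N(0, effect_sd²) values on a `signal_sparsity` fraction of
genes. Defaults, chosen once as a realistic liver-TGx regime: 5000 genes, 60
compounds, three systems with ρ = 0.9 (single-dose vs. repeat-dose in vivo),
0.7 (in vitro vs. repeat-dose) and 0.55 (in vitro vs. single-dose); four
six-compound categories at α = 0.7/0.6/0.5/0.0; three planted 250-gene
pathways at effect size 2 (log2, i.e. 4-fold) plus ten 250-gene decoys;
`signal_sparsity = 0.1` (a few hundred responsive genes per compound);
`effect_sd = 2.0` log2 units (typical strong-DEG magnitude);
`noise_sd = 0.3` log2 units of additive homoscedastic measurement noise
(typical microarray fold-change noise). Everything is deterministic given
the seed.

What the generator does **not** emulate: probe-level intensities and
normalization artifacts, batch effects, dose–response and time-course
kinetics, heteroscedastic (intensity-dependent) noise, correlated gene–gene
co-expression beyond the planted structures, and realistic pathway overlap
topology. Passing recovery tests therefore show that the statistics recover
the structures they target under an idealized noise model — not that any
particular real-data value will be reproduced.

## Recovery behaviour and statistical power

On default synthetic triads the PRank ordering of the three system pairs
matches the generative ρ ordering in the large majority of seeded replicates
(the acceptance script reports the exact count; on seeds 0–19 it is 17/20).
The misorderings are confined to the two closest pairs (ρ = 0.7 vs. 0.55)
with score margins of ~0.01: with 95th-percentile binarization only ~5% of
the 1770 pairs are positive, and most positives are within-category pairs
that every system ranks highly, so the AUC contrast between the two closest
pairs is of the same order as its sampling noise. The ρ = 0.9 pair is always
ranked first. Category recovery (α ≥ 0.5 ⇒ ratio > 1 in every system) and
pathway recovery (planted sets ahead of all decoys in every system's
frequency ranking at effect size 2) are stable across seeds.

## Numerical and design choices

* AUC by midrank Mann–Whitney (`scipy.stats.rankdata`); hypergeometric tail
  via `scipy.stats.hypergeom.sf`; BH via `statsmodels` `multipletests`;
  Pearson via `scipy.stats.pearsonr`. Each is cross-checked in the test
  suite against an independent brute-force oracle.
* Strict inequalities at every published-style threshold (Dice > cutoff,
  ratio > 1.5, set size > 200), matching their "more than" phrasing.
* Chemical-vs-transcriptomic correlation keeps only pairs with chemical
  similarity strictly above 0.2 and present in both inputs, and requires at
  least three surviving pairs.
* Fold-change TSVs are written with 17 significant digits and read with
  round-trip float parsing, so write→read is bit-exact.
* All randomness in the workflow and generator flows from a single seed.

## Limitations

* PRank is a point score; no confidence interval or DeLong-style test is
  provided.
* The enrichment machinery is a plain Fisher/BH ORA; rank-based (GSEA-style)
  enrichment is out of scope.
* Only Dice similarity is implemented; Jaccard/cosine/connectivity-style
  metrics are extension points.
* Upstream preprocessing (array normalization, probe summarization,
  probe-to-gene collapsing) is assumed done; the package starts from
  per-gene fold changes.
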