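# Methods

## The problem and the model

The package characterizes bladder-cancer samples as basal-like or
luminal-like from a targeted expression panel: ~90 cancer-relevant target
genes plus two housekeeping genes, measured either on public array data
(genes × samples, log scale) or as replicate qPCR Ct values from FFPE
tissue. Three statistical components do the work: a nearest-profile
correlation score (the B/L similarity score), a diagonal linear
discriminant classifier evaluated by cross-validation, and unsupervised
average-linkage clustering with association tests. Everything upstream of
them is normalization and QC.

## Normalization

**ΔCt.** For each sample, a target gene's Ct is averaged over its
non-failed replicates; the reference aggregate is the geometric mean of
the per-housekeeping-gene mean Cts (per-gene means first, then the
geometric mean, so unequal replicate counts after failures do not weight
one housekeeping gene over the other). ΔCt = target mean − reference
aggregate, and relative expression is `base**(-ΔCt)` with base 2 by
default. The base cancels downstream: all scoring operates on
correlations of log expression, and log2(relative expression) = −ΔCt up
to the per-sample reference constant. A sample whose housekeeping genes
all fail has no reference and is set entirely missing with a warning. A
gene with every replicate failed is missing for that sample.

**Median polish.** Tukey's row/column median sweep decomposes a matrix
into overall + gene + sample effects + residuals. Missing cells are
skipped in the medians and never imputed. The stopping rule is the
decomposition's own contract: iterate until the largest absolute
row-median and column-median of the residuals is ≤ `tol` (default 1e−9,
default cap 2000 sweeps — random 90×20 matrices typically converge in a
few hundred). The "normalized" matrix removes the sample (column)
effects, i.e. overall + gene effects + residuals; all components are
returned so either convention (residuals only, or column-effect removal)
is recoverable. The implementation is cross-checked in the tests against
an independently coded sweep and against R's `stats::medpolish`.

**Standardization.** Per-gene z-scores use the n−1 sample SD, matching
common statistical software. Zero-variance genes become all-zero rows
with a warning rather than NaNs, so downstream correlations degrade
gracefully on degenerate synthetic inputs.

## B/L similarity scoring

Reference profiles are per-gene means of z-scored expression over the
labeled basal and luminal samples of a reference cohort. The
standardization population is the whole reference cohort, including any
unlabeled samples (the choice is documented here because it is genuinely
open: profile transfer across platforms relies on Pearson's invariance to
per-gene affine changes, so either choice yields very similar scores; the
inclusive choice uses all available information about gene variance).
Note one consequence: if *every* reference sample is labeled basal or
luminal, z-scoring forces `n_b * basal_profile + n_l * luminal_profile = 0`
gene-wise, so the two profiles are exact negative multiples of each other
and the two correlations are exactly opposed.

A sample is scored by `score = (r_basal - r_luminal) / 2` where each `r`
is the Pearson correlation between the sample's z-scored expression
vector and the profile, computed pairwise-complete over jointly observed
genes (minimum 3; fewer, or zero variance over the overlap, gives a
missing score). The score is bounded in [−1, +1]; the bounds are attained
exactly when the sample equals one profile and the profiles are exact
negations. Calls: basal-like for score > 0, luminal-like for < 0, and
indeterminate at exactly 0 — an explicit tie value rather than a silent
tie-break.

The cohort being scored is z-scored internally, independent of the
reference cohort. Unlabeled samples participate in that standardization.

## Classification

**Welch statistic.** Per gene, `t = (mean_b - mean_l) / sqrt(s2_b/n_b +
s2_l/n_l)`; positive t means higher in basal. Two-sided p-values use the
Welch–Satterthwaite degrees of freedom. Genes with fewer than two
observed values in a group are missing and rank last.

**DLDA.** Class means per gene plus a shared pooled per-gene variance
weighted by (n_c − 1). A sample is assigned to the class minimizing
Σ_g (x_g − μ_cg)² / σ²_g over its observed genes (equal priors; ties go
to the lexicographically first class for reproducibility). Genes with
pooled variance below 1e−12 are dropped to avoid division blow-ups on
degenerate inputs. The tests verify exact equivalence with a brute-force
diagonal-Gaussian maximum-likelihood classifier.

**Cross-validation.** Folds are random but stratified by class — a
deliberate deviation from plain random splits, preventing empty-class
folds at small n — and derived deterministically from a seed after
sorting samples by ID, so the partition is independent of column order.
Gene selection (top n by |t|) happens inside each fold on the training
samples only; the no-leakage property is asserted in the tests by
scrambling held-out values of unselected genes. Reported aggregates are
the mean fold misclassification rate, the SD across folds, and the
standard error SD/√(#folds); both spread measures are emitted because
conventions differ on which to print. Repeated CV over consecutive seeds
is available in the CLI.

## Clustering and association

Sample distances are 1 − Pearson (pairwise-complete; a pair with < 3
informative shared genes is an error before clustering, named by pair).
Agglomeration is UPGMA: inter-cluster distance is the unweighted mean of
all cross-pair distances, with ties broken toward the lexicographically
smallest node-id pair so the merge sequence is platform-deterministic.
Cutting keeps the first n−k merges. For k = 2 the branch with the higher
mean B/L score is labeled basal-like; for k > 2 (e.g. exploring a third
cluster) only indices are returned — no additional subtype semantics are
attached. Mutation/stage enrichment uses the two-sided Fisher exact test
under the probability-mass criterion (sum of hypergeometric probabilities
not exceeding the observed table's), with a cross-product odds ratio and
0.5 continuity correction when a cell is zero. Score differences between
branches default to the exact two-sided Mann–Whitney rank-sum test
because no specific parametric test is canonical here; Welch's t is
available as an option.

## Assay QC

Failure rate = failed reactions / attempted reactions per assay.
Replicate CV = SD/mean, computed by default on the linear expression
scale (`2**-Ct`) — Ct-scale CV is available but not the default, since
"expression measurement" CV is the convention the thresholds assume.
Thresholds default to 15% failure and 5% CV with strict inequality; an
assay exceeding one limit is flagged for review (high-failure / high-cv)
and an assay exceeding both is dropped. This mirrors panel practice: an
assay can fail often yet be accurate when it does report, but one that is
both unreliable and noisy carries no usable information. Run-to-run
concordance is the squared Pearson correlation of paired measurements per
gene and pooled.

## The synthetic-data generator

The generator emulates the statistical structure of a two-subtype FFPE
series: per-gene baselines drawn once from N(0, 1) (giving nontrivial
profile correlations), a chosen number of differentially expressed genes
split between basal-up and luminal-up with a fixed log2 effect
(± effect/2 per group), independent Gaussian noise on the log2 scale, and
two housekeeping genes with no subtype effect. One marker gene ("FGFR3")
always carries the largest luminal-directed shift (1.5× the common
effect) and is mutated with group-specific Bernoulli frequency. Stage
labels (NMIBC/MIBC/MET) are drawn per group from fixed mixtures chosen so
that a balanced cohort reproduces an overall ~45.5/30/26% composition
with NMIBC enriched in the luminal group and metastases in the basal
group. Defaults: 102+102 samples, 90 target genes, 30 DE genes, effect
2.0 log2 units, noise SD 1.0, mutation frequencies 0.80 (luminal) and
0.15 (basal). Everything is deterministic given the spec's seed.

Ct encoding inverts expression with standard qPCR orientation,
`Ct = housekeeping_ct − log2expr + N(0, rep_sd)`, with each replicate
independently failing at its assay's probability. `housekeeping_ct = 20`
and `rep_sd = 0.25` Ct are configuration defaults, not measured values.
Note the CV consequence: replicate noise of s Ct yields an
expression-scale CV of roughly `sqrt(exp((s ln2)^2) - 1)` ≈ 0.7·s, so the
analysis drivers use `rep_sd = 0.05` for working assays to emulate a
panel operating in the sub-5% CV regime, and a deliberately broken assay
with 96% failure probability and inflated replicate noise to exercise the
drop flag.

What the generator does *not* model: FFPE degradation chemistry beyond
the failure probability, gene–gene correlation within pathways,
platform/batch effects between reference and study cohorts, and
heavy-tailed noise. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under idealized Gaussian structure, not
classifier performance on real archival tissue.

## Problem sizes and numerical choices

The test suite and analysis scripts run at deliberately modest scale —
cohorts of 100–204 samples, reference cohorts of 30 (18 basal / 12
luminal, the canonical profile-derivation size), 200 matrices of 90×20
for the median-polish identities, 20-seed null sweeps — sizes at which
every statistical check has comfortable power while the whole suite runs
in well under a minute of compute per module. Correlations clip to
[−1, 1] against rounding; Fisher tables must be integer-valued;
dendrogram heights are checked non-decreasing (guaranteed for UPGMA on a
true distance matrix).

Known limitations: the null-CV band [0.35, 0.65] is a 20-seed average and
can drift outside for adversarial seeds; with very small reference
groups the profile entries are noisy and the marker gene need not top the
luminal profile in any single draw (the ordering is an expectation,
verified at large n); the MIBC stage mix differs between groups only
mildly, so its branch enrichment is not always significant at n = 204
even though the NMIBC and MET enrichments are overwhelming.
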