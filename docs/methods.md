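# Methods

This note records the models, algorithms and numerical choices behind
`tmescore`, and what the synthetic cohorts the test suite runs on do and
do not establish about real data.

## The scoring model

The package derives a per-sample tumor-microenvironment (TME) score from
bulk expression in five stages:

1. **Deconvolution.** Per-sample immune-cell fractions are estimated by
   linear ν-support-vector regression of the standardized mixture column
   on the standardized columns of a cell-type signature matrix (an
   LM22-style genes × cell-types reference). One model is fitted per ν
   in {0.25, 0.5, 0.75}; the ν with the lowest root-mean-square
   reconstruction error wins, ties going to the smallest ν. Negative
   coefficients are clipped to zero and the rest renormalized to sum 1.
   Significance is a permutation test: the observed reconstruction
   correlation is compared with a null built by refitting gene-shuffled
   copies of that sample's own mixture column (add-one smoothed; default
   1000 permutations), which keeps p-values independent across samples
   at the cost of n_perm extra fits per sample. The
   goal is recovery of the underlying fractions, not bit-for-bit
   agreement with any hosted implementation, whose preprocessing is not
   fully public.
2. **Cluster number and consensus clustering.** k-means (Euclidean) is
   run on the sample × cell-type fraction matrix for k in a scan range.
   The gap statistic compares log within-cluster dispersion against
   uniform-bounding-box reference draws (default 50); the chosen k is the
   smallest with gap(k) ≥ gap(k+1) − se(k+1) (the one-standard-error
   rule, the conservative reading of "maximum gap"), with the elbow
   (largest second difference of the dispersion curve) reported
   alongside. Labels come from consensus clustering: k-means on repeated
   80% subsamples (default 1000 repeats), consensus(i,j) = co-cluster /
   co-sample counts, finalized by Ward-linkage agglomeration of
   1 − consensus cut at k.
3. **Marker genes.** Cluster markers are one-vs-rest moderated t tests
   on log2(expr+1): per-gene variances are shrunk toward a pooled prior
   fitted by matching moments of log sample variances (the standard
   empirical-Bayes moderated-t formulation, including the Newton
   trigamma inverse). The filter is BH-adjusted p < 0.05 AND
   |log2FC| > log2(1.5), both strict; a raw-p mode exists behind a flag.
   BH is used for the p cut because the procedure prescribes BH
   adjustment even though the filter line is conventionally printed as
   "P < 0.05".
4. **Pruning and sign split.** A random forest of cluster label on the
   candidate markers supplies out-of-bag permutation importance
   (computed per tree on its out-of-bag samples; individual sklearn
   trees emit class indices, which are mapped through the forest's
   class order). Genes with importance strictly above the mean are
   kept; the kept set is never empty (fallback: top 10). Each surviving
   gene then gets a univariate Cox proportional-hazards fit of overall
   survival on its z-scored log2 expression. Standardization affects the
   coefficient scale, never its sign — and only the sign is consumed:
   coefficient < 0 (hazard-decreasing) → set X, > 0 → set Y. No p-value
   filter is applied at this step; the partition is by sign alone.
5. **Score.** TMEscore(sample) = Σ_{g∈X} log2(expr_g+1) −
   Σ_{g∈Y} log2(expr_g+1), dichotomized at the cohort median with strict
   ">" for "high" (ties fall to "low" — deterministic and documented).
   Because X holds the hazard-decreasing genes, the high-score group is
   constructed to have the better prognosis. Validation applies frozen
   sets to a new cohort with no refitting; only the median split is
   recomputed within the new cohort.

## Mutation spectrum

TMB is the raw count of somatic records per sample, with no
per-megabase normalization — the analyses only consume ranks and
median splits, which normalization by a constant would not change.
SNVs map to 96 categories: the six pyrimidine-strand substitutions ×
4×4 immediate flanks, in COSMIC v2 row order (substitution class, then
5′ flank, then 3′ flank); purine-strand records are
reverse-complemented, and records with ambiguous bases are skipped and
counted. The catalog is factored by non-negative matrix factorization
minimizing generalized Kullback–Leibler divergence with multiplicative
updates (the somatic-signatures convention), best of 20 restarts, with
a per-iteration divergence history that is checked to be non-increasing.
Extracted signatures are column-normalized to probability vectors;
cosine similarity against a user-supplied 96-row reference collection
gives the match table (argmax per signature, ties to the lowest
reference index). No reference collection is bundled; tests use planted
signatures.

**Rank selection.** For each candidate rank, every restart's signatures
are greedily cosine-matched to the best-divergence solution; the
per-restart score is the cosine of the *worst*-matched signature and
stability(R) is its mean over restarts. The selected rank is the largest
with stability ≥ 0.90. The worst-signature form matters: averaging over
all signatures stays high one rank past the truth (the spurious
component hides behind the reproducible ones), while the worst-matched
component collapses there (observed ≈ 1.0 at and below the planted rank
versus ≤ 0.8 above it).

## Association analyses

Spearman score–TMB correlation is exact (full permutation enumeration)
for n ≤ 9 and the t approximation otherwise; strata under 3 pairs are
skipped. Differential mRNA/miRNA use the moderated t on log2(x+1) with
adjusted p < 0.05 and |log2FC| > 1; methylation uses the moderated t on
beta values with adjusted p < 0.05 and |Δβ| > 0.15 (all strict).
Survival screening median-splits each feature and uses a two-group
log-rank test at raw p < 0.05 — raw because the screen is reported as a
count of nominal associations, with a BH mode behind a flag; direction
comes from the sign of observed-minus-expected events in the high arm.
ROC comparison uses the midrank (Mann–Whitney) AUC and paired DeLong
variance; the combined TMB+TME predictor defaults to the sum of
min–max-standardized components (parameter-free and monotone in both),
overridable by a user column. The TIDE-like response score is
dichotomized at its median unless a binary response is supplied.
Rank-sum comparisons are exact for combined n ≤ 20 without ties, else
normal with tie and continuity corrections. Hazard ratios pool by
fixed-effect inverse variance on the log scale.

## Synthetic cohorts

The generators plant exactly the structure each stage is meant to
recover, with defaults chosen to mimic a mid-sized bulk cohort:

* **Expression cohorts** (`simulate_cohort`): balanced cluster labels;
  per-cluster mean fraction vectors are Dirichlet draws selected by a
  maximin rule and sharpened by the separation exponent (default 3 —
  clearly separated but not degenerate); per-sample fractions jitter the
  means (sd 0.02) and renormalize. Expression is signature @ fractionsᵀ
  scaled to a 10⁴ library, plus 10 marker genes per cluster shifted
  2-fold-log2 in their own cluster and log-normal noise (sd 0.3 on the
  natural-log scale, i.e. ~0.43 in log2 units — typical bulk RNA-seq
  replicate noise). Survival is exponential with log hazard
  log(1/365) + β·z, where z standardizes the planted protective-minus-
  risk marker score (β = −1 by default: the protective axis), and
  censoring is independent uniform, calibrated by bisection to a 30%
  censor rate.
* **MAFs** (`simulate_maf`): TMB is negative binomial (dispersion 2)
  floored at 1; exposures are Dirichlet(1); categories draw from the
  exposure-mixed planted signatures and are emitted on a random strand.
  A supplied score can be rank-coupled to TMB at a target Spearman rho
  by an Iman–Conover-style reorder — the analysis only consumes the rank
  correlation, so no joint parametric model is needed. Only missense
  SNVs are emitted by default (the catalog analysis uses SNVs alone),
  with an option to sprinkle frame-shift deletions for summary tests.
* **Omics matrices** (`simulate_omics`): log-normal miRNA with
  alternating-sign planted log2 fold changes; methylation beta values
  clipped to (0,1) with planted group differences whose direction is
  chosen to stay in range.

What passing on these cohorts shows: the estimators invert the models
they assume, at realistic noise, sample size and effect size. What it
does not show: robustness to platform effects, normalization artifacts,
cell types absent from the signature, non-proportional hazards,
subclonal mutation structure, or batch confounding — none of which the
generators emulate.

## Numerical choices and degenerate inputs

* ν-SVR runs at solver tolerance 1e-4 with a 20k iteration cap
  (planted-fraction error impact ~1e-5, far under the 0.05 recovery
  contract). An all-zero coefficient vector yields uniform fractions
  with a warning.
* The permutation null is per sample (each draw shuffles that sample's
  own gene values and refits); fraction estimation itself never needs
  it, so pipeline runs default to n_perm = 0.
* Gap-statistic reference draws are uniform over the observed bounding
  box; identical-sample inputs short-circuit to k = 1 with a warning.
* Consensus entries for never-co-sampled pairs are 0 and flagged;
  agglomeration ties break toward the lowest sample index via the
  deterministic linkage order, and final labels are renumbered in order
  of first appearance so runs are byte-identical under a fixed seed.
* NMF guards divisions with 1e-12 and stops on relative divergence
  change < 1e-6 or 2000 iterations; the rank-1 solution equals the
  normalized row-sum profile, which the tests exploit as a closed form.
* Zero-variance genes/features are excluded from moderated tests with a
  warning; constant genes are unfittable in Cox and excluded; a constant
  score makes the validation HR undefined and it is reported missing,
  never imputed.
* Group means in moderated tests are computed on contiguous arrays so
  pairwise summation keeps exact-boundary fold changes exact; the
  fold-change and Δβ filters are strict inequalities at the boundary.
* Median splits use strict ">" everywhere (score groups, TMB groups,
  survival screens), so ties land in "low".

## Problem sizes used by the checks

The consolidated checks run at desk scale, chosen to finish in minutes
on one CPU while keeping the planted effects comfortably detectable:
cluster-number recovery on 20 cohorts of n = 150 with 50 reference
draws; NMF rank scans over ranks 1–6 with 20 restarts on 20 catalogs of
100 samples at mean TMB 200; the end-to-end derivation on 20 cohorts of
n = 300; null calibrations with 100–200 replicates. Consensus repeats
default to 1000 in the API but the pipeline checks use 100–200, which
already saturate the planted separations.
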