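# tmescore

Scoring the tumor microenvironment (TME) from bulk transcriptomes, and
linking it to mutations, survival and immunotherapy response.

Bulk tumor expression is a mixture over malignant, immune and stromal
cells, and the immune composition of that mixture carries prognostic
information — in breast cancer, cohorts cluster into a small number of
TME infiltration patterns whose members differ in overall survival.
`tmescore` implements that analysis end to end as a tested Python
library: estimate per-sample immune-cell fractions from expression
against an LM22-style signature matrix (ν-SVR deconvolution with
permutation significance), discover TME clusters (gap statistic +
consensus clustering), derive a prognostic gene-set score, and run the
downstream mutation-spectrum and immunotherapy association analyses.
Every stage has a synthetic-cohort generator that plants the structure
it is supposed to recover, so the whole pipeline is testable without
any external download.

The score itself follows the gene-expression-grade-index form. Cluster
marker genes (moderated t, BH-adjusted p < 0.05, fold change > 1.5,
pruned by random-forest importance) are split by the sign of their
univariate Cox coefficient into a hazard-decreasing set X and a
hazard-increasing set Y, and each sample gets

    TMEscore = Σ_{g∈X} log2(x_g + 1) − Σ_{g∈Y} log2(x_g + 1)

with a strict-median split into high/low groups. By construction the
high group carries the better prognosis. The mutation side builds the
96 trinucleotide-context catalog from a MAF (pyrimidine-strand
collapsed), factors it into mutational signatures by KL-divergence NMF
with a stability-based rank scan, and cosine-matches the result against
a COSMIC-style reference. Association tools cover Spearman score–TMB
correlation, differential miRNA/mRNA/methylation between score groups,
median-split survival screening, DeLong comparison of TMB / TME /
combined response predictors, Wilcoxon group tests, fixed-effect
pooling of hazard ratios, and an integrated per-sample landscape table.

Audience: computational oncology / bioinformatics users who want a
reproducible, importable version of this analysis for their own
cohorts, or a harness for methods work on TME scoring.

## Worked example

```python
import numpy as np
from tmescore import (simulate_cohort, synthetic_signature_matrix,
                      derive_tmescore)
from tmescore.cluster import cluster_survival

signature = synthetic_signature_matrix(seed=0)
expr, clinical, truth = simulate_cohort(
    n_samples=200, n_genes=50, k_true=3, signature=signature,
    de_effect_log2fc=2.0, hazard_beta=-1.0, seed=7)

res = derive_tmescore(expr, clinical, signature,
                      k_range=range(1, 8), n_ref=30,
                      consensus_reps=100, seed=7)
print(res.k_selection.k_chosen, len(res.sets.set_X), len(res.sets.set_Y))
groups = res.scores.table.set_index("sample_id")["group"]
surv = cluster_survival(groups.map({"high": 1, "low": 2}), clinical)
print(round(surv["chi2"], 2), surv["p_value"])
```

Output:

```
3 26 37
80.81 2.48435717911242e-19
```

The gap statistic recovers the planted 3 clusters; the derived gene
sets put 26 genes on the hazard-decreasing side and 37 on the
hazard-increasing side; and the high-TMEscore group separates from the
low group at log-rank χ² = 80.8 (p ≈ 2.5e-19), with the high group
surviving longer — the direction the score is constructed to have.
More narrative walkthroughs live in `examples/` (deconvolution,
clustering + scoring, mutational signatures, TMB/response comparisons,
differential omics + landscape); each prints what it computes and what
the numbers mean.

A thin CLI mirrors the library for shell use:
`tmescore simulate | deconvolve | cluster | score | mutsig | associate`
(see `tmescore --help`).

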