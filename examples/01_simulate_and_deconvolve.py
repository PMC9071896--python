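"""Simulate a bulk cohort and recover its immune-cell fractions.

Builds a synthetic signature matrix, mixes known cell fractions into
bulk expression for 60 samples with 3 planted TME clusters, then runs
SVR deconvolution and reports how close the estimates come to the truth.
"""
import numpy as np

from tmescore import (
    estimate_fractions,
    fraction_matrix,
    simulate_cohort,
    synthetic_signature_matrix,
)

signature = synthetic_signature_matrix(n_cell_types=10, seed=0)
expr, clinical, truth = simulate_cohort(
    n_samples=60, n_genes=40, k_true=3, signature=signature,
    cluster_separation=3.0, noise_sd=0.2, seed=1,
)

fractions = estimate_fractions(expr, signature, n_perm=100, seed=1)
est = fraction_matrix(fractions)
mae = np.abs(est.to_numpy() - truth.true_fractions.to_numpy()).mean()

print(f"cohort: {expr.shape[0]} genes x {expr.shape[1]} samples")
print(f"mean absolute error vs true fractions: {mae:.4f}")
print(f"median deconvolution p-value: {fractions['p_value'].median():.4f}")
# A small error (well under 0.05 per cell type) means the mixture was
# inverted correctly; low p-values say the fit beats gene-shuffled nulls.
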