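"""Choose k, consensus-cluster a cohort and derive the TMEscore.

Runs the full derivation chain on a planted 3-cluster cohort whose
survival follows a protective gene axis, then checks that the high-score
group really does live longer.
"""
from tmescore import derive_tmescore, simulate_cohort, synthetic_signature_matrix
from tmescore.cluster import cluster_survival

signature = synthetic_signature_matrix(seed=0)
expr, clinical, truth = simulate_cohort(
    n_samples=200, n_genes=50, k_true=3, signature=signature,
    de_effect_log2fc=2.0, hazard_beta=-1.0, seed=7,
)

res = derive_tmescore(expr, clinical, signature, k_range=range(1, 8),
                      n_ref=30, consensus_reps=100, seed=7)

print(f"chosen k: {res.k_selection.k_chosen} (elbow {res.k_selection.k_elbow})")
print(f"markers passing filters: {res.markers['passes_filter'].sum()}")
print(f"|X| (hazard-decreasing) = {len(res.sets.set_X)}, "
      f"|Y| (hazard-increasing) = {len(res.sets.set_Y)}")

groups = res.scores.table.set_index("sample_id")["group"]
surv = cluster_survival(groups.map({"high": 1, "low": 2}), clinical)
print(f"log-rank high vs low: chi2 = {surv['chi2']:.2f}, p = {surv['p_value']:.2e}")
# k should match the planted 3; a small p with the high group on top of the
# KM curves reproduces the intended score direction: high score, better outcome.
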