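"""End-to-end TMEscore derivation.

Chains deconvolution, consensus clustering, marker discovery, forest
pruning, the Cox sign split and Eq.-style scoring into one call, so a
cohort can go from an expression table plus survival to a scored,
dichotomized sample table.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cluster import ClusterModel, KSelection, consensus_cluster, select_k
from .deconv import estimate_fractions, fraction_matrix
from .scoring import (
    GeneSignatureSets,
    TMEscoreResult,
    cluster_marker_genes,
    compute_tmescore,
    cox_sign_split,
    prune_redundant,
)


@dataclass
class PipelineResult:
    fractions: pd.DataFrame
    k_selection: KSelection | None
    clusters: ClusterModel
    markers: pd.DataFrame
    pruned_genes: list
    sets: GeneSignatureSets
    scores: TMEscoreResult


def derive_tmescore(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    signature: pd.DataFrame,
    k: int | None = None,
    k_range=range(1, 11),
    n_ref: int = 50,
    consensus_reps: int = 200,
    p_item: float = 0.8,
    n_perm: int = 0,
    marker_p: float = 0.05,
    marker_fc: float = 1.5,
    rf_trees: int = 200,
    seed: int = 0,
) -> PipelineResult:
    """Full derivation: deconvolve, cluster, find markers, prune, split, score.

    With ``k=None`` the cluster number is chosen by the gap statistic
    (one-SE rule).  Permutation p-values for the deconvolution are off by
    default here (n_perm=0) since only the fractions feed the pipeline.
    """
    fractions = estimate_fractions(
        expression, signature, n_perm=n_perm, seed=seed
    )
    fmat = fraction_matrix(fractions)
    ksel = None
    if k is None:
        ksel = select_k(fmat, k_range=k_range, n_ref=n_ref, seed=seed)
        k = max(ksel.k_chosen, 2)
    clusters = consensus_cluster(
        fmat, k=k, n_reps=consensus_reps, p_item=p_item, seed=seed
    )
    markers = cluster_marker_genes(
        expression, clusters.labels, p_thresh=marker_p, fc_thresh=marker_fc
    )
    candidates = sorted(markers.loc[markers["passes_filter"], "feature_id"].unique())
    if not candidates:
        raise ValueError("no cluster-marker genes passed the filters")
    pruned = prune_redundant(
        expression, clusters.labels, candidates, n_trees=rf_trees, seed=seed
    )
    sets = cox_sign_split(expression, clinical, pruned)
    scores = compute_tmescore(expression, sets)
    return PipelineResult(
        fractions=fractions,
        k_selection=ksel,
        clusters=clusters,
        markers=markers,
        pruned_genes=pruned,
        sets=sets,
        scores=scores,
    )
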