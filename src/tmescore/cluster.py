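"""TME cluster discovery from cell-fraction profiles.

Chooses the number of clusters by the within-cluster sum of squares
(elbow) and the gap statistic with the one-standard-error rule, assigns
stable labels by consensus clustering (repeated k-means on subsamples,
agglomerated with Ward linkage on 1 - consensus), and tests the
cluster-survival association with a multi-group log-rank test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans


@dataclass
class KSelection:
    k_range: list
    wss: pd.Series
    gap: pd.Series
    gap_se: pd.Series
    k_elbow: int
    k_gap: int
    k_chosen: int


@dataclass
class ClusterModel:
    consensus: pd.DataFrame  # sample x sample in [0, 1]
    labels: pd.Series        # per-sample integer in 1..k
    k: int
    n_reps: int


def _as_matrix(fractions) -> pd.DataFrame:
    df = fractions if isinstance(fractions, pd.DataFrame) else pd.DataFrame(fractions)
    return df.drop(columns=["rmse", "pearson_r", "p_value"], errors="ignore")


def _wss(X: np.ndarray, k: int, n_restarts: int, seed: int) -> float:
    if k >= len(X):
        return 0.0
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def select_k(
    fractions,
    k_range=range(1, 11),
    n_ref: int = 50,
    n_restarts: int = 10,
    seed: int = 0,
) -> KSelection:
    """Choose the cluster number by elbow and gap statistic.

    For each k, the observed within-cluster sum of squares (best of
    ``n_restarts`` k-means runs) is compared with ``n_ref`` reference
    datasets drawn uniformly over the feature bounding box:
    gap(k) = mean(log wss_ref) - log wss_obs, with the standard error
    inflated by sqrt(1 + 1/n_ref).  The primary choice ``k_gap`` is the
    smallest k with gap(k) >= gap(k+1) - se(k+1) (one-SE rule);
    ``k_elbow`` (the largest second difference of wss) is reported
    alongside.
    """
    X = _as_matrix(fractions).to_numpy(dtype=float)
    n, d = X.shape
    k_range = [k for k in k_range if 1 <= k <= max(n - 1, 1)]
    if n_ref < 10:
        raise ValueError("n_ref must be >= 10")
    if np.allclose(X, X[0]):
        warnings.warn("degenerate input: all samples identical; k = 1")
        ones = pd.Series(1.0, index=k_range)
        return KSelection(k_range, ones * 0, ones * 0, ones * 0, 1, 1, 1)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = [lo + rng.uniform(size=(n, d)) * (hi - lo) for _ in range(n_ref)]

    wss_obs, gap, gap_se = {}, {}, {}
    tiny = 1e-300
    for k in k_range:
        w = _wss(X, k, n_restarts, int(rng.integers(2**31)))
        wss_obs[k] = w
        log_ref = np.array(
            [np.log(max(_wss(R, k, n_restarts, int(rng.integers(2**31))), tiny))
             for R in refs]
        )
        gap[k] = float(log_ref.mean() - np.log(max(w, tiny)))
        gap_se[k] = float(log_ref.std(ddof=1) * np.sqrt(1.0 + 1.0 / n_ref))

    ks = list(k_range)
    k_gap = ks[-1]
    for i, k in enumerate(ks[:-1]):
        nxt = ks[i + 1]
        if gap[k] >= gap[nxt] - gap_se[nxt]:
            k_gap = k
            break
    k_elbow = ks[0]
    if len(ks) >= 3:
        w = np.array([wss_obs[k] for k in ks])
        second_diff = w[:-2] - 2 * w[1:-1] + w[2:]
        k_elbow = ks[1 + int(np.argmax(second_diff))]
    return KSelection(
        k_range=ks,
        wss=pd.Series(wss_obs),
        gap=pd.Series(gap),
        gap_se=pd.Series(gap_se),
        k_elbow=int(k_elbow),
        k_gap=int(k_gap),
        k_chosen=int(k_gap),
    )


def consensus_cluster(
    fractions,
    k: int,
    n_reps: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
) -> ClusterModel:
    """Consensus clustering: repeated k-means on subsampled items.

    consensus(i, j) = co-clustering count / co-sampling count over
    ``n_reps`` subsamples of ceil(p_item * n) samples; final labels come
    from Ward-linkage agglomeration of (1 - consensus) cut at k.
    """
    df = _as_matrix(fractions)
    X = df.to_numpy(dtype=float)
    n = len(X)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not 0 < p_item <= 1:
        raise ValueError("p_item must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(p_item * n))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=min(k, m), n_init=3,
                    random_state=int(rng.integers(2**31)))
        lab = km.fit_predict(X[idx])
        same = lab[:, None] == lab[None, :]
        sampled[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    never = (sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(f"{int(never.sum()) // 2} sample pairs never co-sampled")
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # relabel in order of first appearance so labels are deterministic
    remap, nxt = {}, 1
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        out[i] = remap[lab]
    return ClusterModel(
        consensus=pd.DataFrame(consensus, index=df.index, columns=df.index),
        labels=pd.Series(out, index=df.index, name="cluster"),
        k=k,
        n_reps=n_reps,
    )


def cluster_survival(labels: pd.Series, clinical: pd.DataFrame):
    """Multi-group log-rank test and per-group Kaplan-Meier curves.

    Returns a dict with ``chi2``, ``p_value`` and ``km`` (a mapping from
    group label to a step-function DataFrame with columns time/survival).
    Groups with zero members are dropped with a warning.
    """
    clin = clinical.set_index("sample_id").loc[labels.index]
    groups = labels.copy()
    counts = groups.value_counts()
    empty = [g for g in counts.index if counts[g] == 0]
    if empty:
        warnings.warn(f"dropping empty groups {empty}")
    present = counts[counts > 0].index
    keep = groups.isin(present)
    groups, clin = groups[keep], clin[keep.to_numpy()]
    if len(present) < 2:
        raise ValueError("need >= 2 non-empty groups")
    events_per_group = clin.groupby(groups.to_numpy())["os_event"].sum()
    if (events_per_group < 1).any():
        raise ValueError("each group needs >= 1 event")
    res = multivariate_logrank_test(
        clin["os_time"], groups.to_numpy(), clin["os_event"]
    )
    km = {}
    for g in sorted(present):
        mask = (groups == g).to_numpy()
        fitter = KaplanMeierFitter()
        fitter.fit(clin["os_time"][mask], clin["os_event"][mask])
        sf = fitter.survival_function_
        km[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return {"chi2": float(res.test_statistic), "p_value": float(res.p_value), "km": km}
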