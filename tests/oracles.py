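"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's code paths: BH by direct step-up
over sorted p-values, AUC by exhaustive pair counting, the rank-sum null
by full enumeration, Fisher's exact test by hypergeometric enumeration,
non-negative least squares deconvolution, and a textbook multi-group
log-rank statistic.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.optimize import nnls


def bh_stepup(p):
    """Brute-force Benjamini-Hochberg: adj_i = min_{j: p_j >= p_i} p_j*n/rank_j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj_sorted[rank_from_top - 1] = running
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def auc_pair_count(labels, scores):
    """AUC by exhaustive comparison of every positive/negative pair."""
    y = np.asarray(labels, dtype=int)
    x = np.asarray(scores, dtype=float)
    pos = x[y == 1]
    neg = x[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def wilcoxon_enumeration(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = a.size
    obs = ranks[:n1].sum()
    mean = n1 * (pooled.size + 1) / 2.0
    sums = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(pooled.size), n1)
    ]
    sums = np.asarray(sums)
    return float(np.mean(np.abs(sums - mean) >= abs(obs - mean) - 1e-12))


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration over all 2x2 tables."""
    M = a + b + c + d
    n = a + c          # total successes
    N = a + b          # row-1 size
    p_obs = stats.hypergeom.pmf(a, M, n, N)
    total = 0.0
    for k in range(max(0, n - (M - N)), min(n, N) + 1):
        pk = stats.hypergeom.pmf(k, M, n, N)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return float(total)


def nnls_fractions(signature, mixture_col):
    """Deconvolution by non-negative least squares on standardized data."""
    X = np.asarray(signature, dtype=float)
    y = np.asarray(mixture_col, dtype=float)
    X = (X - X.mean()) / X.std()
    y = (y - y.mean()) / y.std()
    w, _ = nnls(X, y)
    total = w.sum()
    return w / total if total > 0 else np.full(w.size, 1.0 / w.size)


def logrank_chi2(times, events, groups):
    """Textbook k-group log-rank statistic and p-value."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    k = labels.size
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in np.unique(t[d == 1]):
        at_risk = t >= et
        n_tot = at_risk.sum()
        deaths = ((t == et) & (d == 1)).sum()
        if n_tot == 0:
            continue
        n_g = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
        d_g = np.array(
            [((t == et) & (d == 1) & (g == lab)).sum() for lab in labels], dtype=float
        )
        O += d_g
        E += deaths * n_g / n_tot
        if n_tot > 1:
            frac = n_g / n_tot
            factor = deaths * (n_tot - deaths) / (n_tot - 1)
            V += factor * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if diff.size == 0 or np.allclose(Vsub, 0):
        return 0.0, 1.0
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    return chi2, float(stats.chi2.sf(chi2, k - 1))


def cosine_brute(u, v):
    """Cosine similarity by explicit dot products."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    num = sum(ui * vi for ui, vi in zip(u, v))
    du = sum(ui * ui for ui in u) ** 0.5
    dv = sum(vi * vi for vi in v) ** 0.5
    return num / (du * dv)
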