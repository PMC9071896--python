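"""Shared statistical primitives.

Moderated two-sample t statistics with empirical-Bayes variance shrinkage,
Benjamini-Hochberg adjustment, the rank (Mann-Whitney) AUC with DeLong
covariance for paired ROC comparison, exact small-sample Spearman and
rank-sum tests, and a directional two-group log-rank test.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "moderated_ttest",
    "trigamma_inverse",
    "mann_whitney_auc",
    "delong_test",
    "spearman_rho_p",
    "rank_sum_test",
    "logrank_two_group",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(y, max_iter: int = 50, tol: float = 1e-10):
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Used to fit the scaled inverse chi-square prior of the moderated t.
    Vectorized; y must be positive.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y <= 0):
        raise ValueError("trigamma_inverse requires positive input")
    x = 0.5 + 1.0 / y  # good starting value for both tails
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.max(np.abs(dif / x)) < tol:
            break
    return x if x.size > 1 else float(x[0])


@dataclass
class ModeratedTResult:
    """Per-feature moderated two-sample t test output."""

    diff: np.ndarray        # mean(a) - mean(b) per feature
    t: np.ndarray
    p: np.ndarray
    df_total: float
    df_prior: float
    s2_prior: float
    s2_post: np.ndarray


def moderated_ttest(a: np.ndarray, b: np.ndarray) -> ModeratedTResult:
    """Two-sample t per feature with empirical-Bayes variance moderation.

    Rows of ``a`` (features x n1) and ``b`` (features x n2) are the two
    groups.  Per-feature sample variances are shrunk toward a pooled prior
    fitted by matching moments of log variances (the standard moderated-t
    formulation); the resulting t statistic has df = df_residual + df_prior.
    Features must not be constant across all samples (filter upstream).
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    df = n1 + n2 - 2
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * va + (n2 - 1) * vb) / df

    # Fit the prior on strictly positive variances only.
    pos = s2 > 0
    s2_fit = s2[pos] if pos.any() else np.array([1.0])
    z = np.log(s2_fit)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid > 0:
        df_prior = 2.0 * float(trigamma_inverse(resid))
        s2_prior = math.exp(
            e_mean + special.digamma(df_prior / 2.0) - math.log(df_prior / 2.0)
        )
    else:
        df_prior = np.inf
        s2_prior = math.exp(e_mean)

    if np.isfinite(df_prior):
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
        df_total = df + df_prior
    else:
        s2_post = np.full_like(s2, s2_prior)
        df_total = 1e9  # effectively normal
    diff = ma - mb
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedTResult(diff, t, p, df_total, df_prior, s2_prior, s2_post)


def mann_whitney_auc(labels, scores) -> float:
    """AUC by the rank formulation with midranks for ties."""
    y = np.asarray(labels, dtype=int)
    x = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute an AUC")
    r = stats.rankdata(x)
    return (np.sum(r[y == 1]) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_components(y: np.ndarray, x: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = x[y == 1]
    neg = x[y == 0]
    # psi(pos_i, neg_j) = 1 if pos>neg, 0.5 if equal, 0 otherwise
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float)
    cmp_mat += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_mat.mean(axis=1)
    v01 = cmp_mat.mean(axis=0)
    return v10, v01


def delong_test(labels, scores_a, scores_b):
    """Paired DeLong comparison of two correlated AUCs.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.
    A predictor compared with itself (or zero estimated variance of the
    difference) yields z = 0, p = 1.
    """
    y = np.asarray(labels, dtype=int)
    v10a, v01a = _delong_components(y, np.asarray(scores_a, dtype=float))
    v10b, v01b = _delong_components(y, np.asarray(scores_b, dtype=float))
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 samples per class")
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var_diff <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry) / denom


def spearman_rho_p(x, y, exact_max_n: int = 9):
    """Spearman rho with two-sided p.

    For n <= ``exact_max_n`` the p-value is exact, computed by full
    enumeration of the n! rank permutations; otherwise the usual t
    approximation (scipy) is used.  Returns (rho, p); rho is NaN when
    either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    if math.isnan(rho):
        return float("nan"), float("nan")
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            r = _rho_of_ranks(rx, np.asarray(perm))
            total += 1
            if abs(r) >= target:
                count += 1
        return rho, count / total
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when the combined sample is <= 20 without ties; otherwise normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def logrank_two_group(time, event, in_group):
    """Two-group log-rank test with direction.

    Returns ``(chi2, p, o_minus_e)`` where ``o_minus_e`` is the observed
    minus expected event count in the ``in_group == True`` arm: negative
    means that arm had fewer events than expected (better survival).
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    g = np.asarray(in_group, dtype=bool)
    event_times = np.unique(t[d == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        deaths = int(((t == et) & (d == 1)).sum())
        d1 = int(((t == et) & (d == 1) & g).sum())
        if n_tot == 0:
            continue
        expected = deaths * n1 / n_tot
        o_minus_e += d1 - expected
        if n_tot > 1:
            var += (
                deaths * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - deaths) / (n_tot - 1)
            )
    if var <= 0:
        return 0.0, 1.0, o_minus_e
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1)), float(o_minus_e)
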