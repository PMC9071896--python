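"""TMEscore derivation and validation.

From cluster labels, cluster-marker genes are found with a moderated
one-vs-rest t test (adjusted P and fold-change filter), pruned with a
random-forest importance screen, and split into a hazard-decreasing set X
and a hazard-increasing set Y by the sign of each gene's univariate Cox
coefficient.  The per-sample score is then

    TMEscore = sum_{g in X} log2(expr_g + 1) - sum_{g in Y} log2(expr_g + 1)

and samples are dichotomized at the cohort median (strict > for "high").
With X holding the protective genes, a higher score predicts better
survival; frozen sets can be re-applied to validation cohorts without
refitting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.ensemble import RandomForestClassifier

from ._stats import bh_adjust, logrank_two_group, moderated_ttest


@dataclass
class GeneSignatureSets:
    """The X (hazard-decreasing) / Y (hazard-increasing) gene partition."""

    set_X: list
    set_Y: list
    coefficients: pd.Series  # per-gene Cox coefficient
    wald_p: pd.Series

    def __post_init__(self):
        if set(self.set_X) & set(self.set_Y):
            raise ValueError("X and Y gene sets must be disjoint")


@dataclass
class TMEscoreResult:
    table: pd.DataFrame  # sample_id, tmescore, group
    median: float


def cluster_marker_genes(
    expression: pd.DataFrame,
    labels: pd.Series,
    p_thresh: float = 0.05,
    fc_thresh: float = 1.5,
    use_adjusted_p: bool = True,
) -> pd.DataFrame:
    """One-vs-rest moderated t test per cluster on log2(expr + 1).

    Per contrast, p-values are BH-adjusted across genes; a gene passes
    when adj_p < ``p_thresh`` and |log2FC| strictly exceeds
    log2(``fc_thresh``).  Zero-variance genes are excluded with a warning.
    Returns the union over contrasts as a long DataFrame with columns
    feature_id, contrast, log2fc, p_value, adj_p, passes_filter.
    """
    labels = labels.loc[expression.columns]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    sizes = labels.value_counts()
    if (sizes < 3).any():
        raise ValueError("each cluster needs >= 3 samples")
    log2e = np.log2(expression.to_numpy(dtype=float) + 1.0)
    variances = log2e.var(axis=1)
    keep = variances > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance genes")
    genes = expression.index[keep]
    log2e = log2e[keep]
    lfc_cut = np.log2(fc_thresh)
    frames = []
    for c in clusters:
        mask = (labels == c).to_numpy()
        res = moderated_ttest(log2e[:, mask], log2e[:, ~mask])
        adj = bh_adjust(res.p)
        crit_p = adj if use_adjusted_p else res.p
        passes = (crit_p < p_thresh) & (np.abs(res.diff) > lfc_cut)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": genes,
                    "contrast": f"cluster{c}_vs_rest",
                    "log2fc": res.diff,
                    "p_value": res.p,
                    "adj_p": adj,
                    "passes_filter": passes,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, rng
) -> np.ndarray:
    """Per-feature permutation importance on each tree's out-of-bag samples."""
    n, p = X.shape
    importances = np.zeros(p)
    counts = np.zeros(p)
    # individual trees emit class indices; translate y once
    y_idx = np.searchsorted(forest.classes_, y).astype(float)
    for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples)
        if oob.size < 2:
            continue
        Xo, yo = X[oob], y_idx[oob]
        base = np.mean(tree.predict(Xo) == yo)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            importances[j] += base - np.mean(tree.predict(Xp) == yo)
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, importances / np.maximum(counts, 1), 0.0)


def prune_redundant(
    expression: pd.DataFrame,
    labels: pd.Series,
    candidate_genes,
    n_trees: int = 500,
    seed: int = 0,
) -> list:
    """Random-forest screen of candidate marker genes.

    Fits a forest of cluster label on log2(expr + 1) over the candidates,
    computes out-of-bag permutation importance, and keeps genes whose
    importance strictly exceeds the mean.  Never returns an empty set
    (falls back to the top 10 by importance).
    """
    candidates = [g for g in candidate_genes if g in expression.index]
    if len(candidates) < len(candidate_genes):
        missing = set(candidate_genes) - set(candidates)
        raise ValueError(f"candidate genes absent from expression: {sorted(missing)[:5]}")
    labels = labels.loc[expression.columns]
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("need >= 2 clusters")
    if len(candidates) < len(classes):
        warnings.warn("fewer candidates than classes; retaining all")
        return list(candidates)
    X = np.log2(expression.loc[candidates].to_numpy(dtype=float).T + 1.0)
    y = labels.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, bootstrap=True
    )
    forest.fit(X, y)
    rng = np.random.default_rng(seed)
    imp = _oob_permutation_importance(forest, X, y, rng)
    kept = [g for g, v in zip(candidates, imp) if v > imp.mean()]
    if not kept:
        order = np.argsort(-imp, kind="stable")[:10]
        kept = [candidates[i] for i in order]
    return kept


def cox_sign_split(
    expression: pd.DataFrame, clinical: pd.DataFrame, genes
) -> GeneSignatureSets:
    """Partition genes by the sign of their univariate Cox coefficient.

    Each gene's z-scored log2(expr + 1) enters a univariate Cox
    proportional-hazards fit of overall survival; coefficient < 0
    (hazard-decreasing) goes to X, > 0 to Y.  Non-converging or constant
    genes are excluded with a warning.
    """
    clin = clinical.set_index("sample_id").loc[expression.columns]
    if clin["os_event"].sum() < 10:
        raise ValueError("need >= 10 events for the Cox sign split")
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise ValueError(f"genes absent from expression: {missing[:5]}")
    set_x, set_y, coefs, pvals = [], [], {}, {}
    for gene in genes:
        vals = np.log2(expression.loc[gene].to_numpy(dtype=float) + 1.0)
        sd = vals.std()
        if sd == 0:
            warnings.warn(f"constant gene {gene!r} excluded")
            continue
        df = pd.DataFrame(
            {
                "z": (vals - vals.mean()) / sd,
                "os_time": clin["os_time"].to_numpy(),
                "os_event": clin["os_event"].to_numpy(),
            }
        )
        try:
            fitter = CoxPHFitter()
            fitter.fit(df, duration_col="os_time", event_col="os_event")
            coef = float(fitter.params_["z"])
            p = float(fitter.summary.loc["z", "p"])
        except Exception as exc:  # non-convergence
            warnings.warn(f"Cox fit failed for {gene!r}: {exc}")
            continue
        if not np.isfinite(coef) or coef == 0:
            warnings.warn(f"gene {gene!r} excluded (coefficient {coef})")
            continue
        coefs[gene] = coef
        pvals[gene] = p
        (set_x if coef < 0 else set_y).append(gene)
    return GeneSignatureSets(
        set_X=set_x,
        set_Y=set_y,
        coefficients=pd.Series(coefs, name="coef"),
        wald_p=pd.Series(pvals, name="p"),
    )


def compute_tmescore(
    expression: pd.DataFrame, sets: GeneSignatureSets
) -> TMEscoreResult:
    """Per-sample TMEscore and strict-median high/low split.

    score = sum over X of log2(expr + 1) minus the same sum over Y;
    genes missing from the expression table are dropped with a warning.
    Median ties go to "low" (group is "high" iff score > median).
    """
    x = [g for g in sets.set_X if g in expression.index]
    y = [g for g in sets.set_Y if g in expression.index]
    dropped = (set(sets.set_X) | set(sets.set_Y)) - set(x) - set(y)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} genes absent from expression")
    if not x and not y:
        raise ValueError("both gene sets empty after intersecting with expression")
    log2e = np.log2(expression + 1.0)
    score = pd.Series(0.0, index=expression.columns)
    if x:
        score += log2e.loc[x].sum(axis=0)
    if y:
        score -= log2e.loc[y].sum(axis=0)
    median = float(score.median())
    table = pd.DataFrame(
        {
            "sample_id": score.index,
            "tmescore": score.to_numpy(),
            "group": np.where(score.to_numpy() > median, "high", "low"),
        }
    ).reset_index(drop=True)
    return TMEscoreResult(table=table, median=median)


def validate_score(
    expression_new: pd.DataFrame,
    clinical_new: pd.DataFrame,
    sets: GeneSignatureSets,
):
    """Apply frozen gene sets to a new cohort and test prognosis.

    Scores use the frozen X/Y sets (no refitting); the median split is
    taken within the new cohort.  Returns a dict with the score table,
    per-group KM curves, the two-group log-rank chi2/p, and the Cox hazard
    ratio (high vs low) with its 95% CI, reported as missing when the
    score is constant.
    """
    clin = clinical_new.set_index("sample_id").loc[expression_new.columns]
    if clin["os_event"].sum() < 5:
        raise ValueError("validation cohort needs >= 5 events")
    result = compute_tmescore(expression_new, sets)
    groups = result.table.set_index("sample_id")["group"]
    high = (groups == "high").to_numpy()
    out = {
        "scores": result,
        "hr": np.nan,
        "hr_ci": (np.nan, np.nan),
        "logrank_p": np.nan,
        "logrank_chi2": np.nan,
    }
    if high.all() or (~high).all():
        warnings.warn("constant score: all samples in one group; HR undefined")
        return out
    chi2, p, _ = logrank_two_group(
        clin["os_time"].to_numpy(), clin["os_event"].to_numpy(), high
    )
    out["logrank_chi2"], out["logrank_p"] = chi2, p
    df = pd.DataFrame(
        {
            "high": high.astype(int),
            "os_time": clin["os_time"].to_numpy(),
            "os_event": clin["os_event"].to_numpy(),
        }
    )
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="os_time", event_col="os_event")
    out["hr"] = float(np.exp(fitter.params_["high"]))
    ci = fitter.confidence_intervals_
    out["hr_ci"] = (
        float(np.exp(ci.iloc[0, 0])),
        float(np.exp(ci.iloc[0, 1])),
    )
    return out
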