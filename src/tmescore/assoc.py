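"""Downstream association analyses.

Links the TMEscore to tumor mutation burden (Spearman), finds
differential miRNA/mRNA/methylation features between score groups,
screens differential features for survival association by median split,
compares TMB vs TME-group vs combined predictors of immunotherapy
response by paired DeLong AUC tests, runs Wilcoxon rank-sum group
comparisons (TIDE-like response, MSI), pools per-dataset hazard ratios by
fixed-effect inverse-variance meta-analysis, and assembles the per-sample
genome landscape table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import (
    bh_adjust,
    delong_test,
    logrank_two_group,
    mann_whitney_auc,
    moderated_ttest,
    rank_sum_test,
    spearman_rho_p,
)


def correlate_score_tmb(
    scores: pd.DataFrame, tmb: pd.Series, subtype: pd.Series | None = None
) -> pd.DataFrame:
    """Spearman correlation of TMEscore with TMB, overall and per subtype.

    ``scores`` is the TMEscore table (sample_id, tmescore); strata with
    fewer than 3 paired samples are skipped with a warning.  Exact p for
    n <= 9, t approximation otherwise; zero-variance ranks report a
    missing rho.
    """
    s = scores.set_index("sample_id")["tmescore"]
    paired = s.index.intersection(tmb.index)
    rows = []

    def _one(name, idx):
        if len(idx) < 3:
            warnings.warn(f"stratum {name!r} has < 3 pairs; skipped")
            return
        rho, p = spearman_rho_p(s.loc[idx].to_numpy(), tmb.loc[idx].to_numpy())
        rows.append({"stratum": name, "n": len(idx), "rho": rho, "p_value": p})

    _one("overall", paired)
    if subtype is not None:
        for level in pd.unique(subtype.dropna()):
            idx = paired.intersection(subtype.index[subtype == level])
            _one(str(level), idx)
    return pd.DataFrame(rows)


def differential_features(
    matrix: pd.DataFrame,
    groups: pd.Series,
    kind: str = "mrna",
    p_thresh: float = 0.05,
    effect_thresh: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential features between two score groups.

    mRNA/miRNA: test on log2(x + 1); pass when adj_p < 0.05 and
    |log2FC| > 1 (strict).  Methylation: test on the beta values (which
    must lie in [0, 1]); pass when adj_p < 0.05 and the absolute group
    mean beta difference exceeds 0.15 (strict).
    """
    if kind not in {"mrna", "mirna", "methylation"}:
        raise ValueError(f"unknown kind {kind!r}")
    groups = groups.loc[matrix.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if set(levels) == {"high", "low"}:
        levels = ["high", "low"]  # effect sign reads high minus low
    g1 = (groups == levels[0]).to_numpy()
    if g1.sum() < 3 or (~g1).sum() < 3:
        raise ValueError("each group needs >= 3 samples")
    vals = matrix.to_numpy(dtype=float)
    if kind == "methylation":
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("methylation beta values must lie in [0, 1]")
        data = vals
        cut = 0.15 if effect_thresh is None else effect_thresh
    else:
        data = np.log2(vals + 1.0)
        cut = 1.0 if effect_thresh is None else effect_thresh
    var = data.var(axis=1)
    keep = var > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant features")
    data = data[keep]
    res = moderated_ttest(data[:, g1], data[:, ~g1])
    adj = bh_adjust(res.p)
    passes = (adj < p_thresh) & (np.abs(res.diff) > cut)
    return pd.DataFrame(
        {
            "feature_id": matrix.index[keep],
            "contrast": f"{levels[0]}_vs_{levels[1]}",
            "log2fc": res.diff,
            "p_value": res.p,
            "adj_p": adj,
            "passes_filter": passes,
        }
    )


def survival_screen(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    p_thresh: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Median-split log-rank screen of features against survival.

    Each feature's samples are split at the strict median (> median is
    "high"); the two-group log-rank p, the direction (which side lives
    longer, from the observed-minus-expected event count), and a pass
    flag at raw p < ``p_thresh`` are reported.  Constant features are
    skipped with a warning.  ``adjust`` switches the pass flag to
    BH-adjusted p.
    """
    clin = clinical.set_index("sample_id").loc[features.columns]
    if clin["os_event"].sum() < 10:
        raise ValueError("need >= 10 events for survival screening")
    t = clin["os_time"].to_numpy()
    d = clin["os_event"].to_numpy()
    rows = []
    for fid, vals in features.iterrows():
        v = vals.to_numpy(dtype=float)
        med = np.median(v)
        high = v > med
        if high.all() or (~high).all():
            warnings.warn(f"constant feature {fid!r} skipped")
            continue
        chi2, p, ome = logrank_two_group(t, d, high)
        rows.append(
            {
                "feature_id": fid,
                "p_value": p,
                "direction": "high_better" if ome < 0 else "low_better",
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p_value"])
        crit = out["adj_p"] if adjust else out["p_value"]
        out["passes"] = crit < p_thresh
    return out


@dataclass
class AUCComparison:
    auc: pd.Series                 # per predictor
    pairwise: pd.DataFrame         # predictor_a, predictor_b, z, p_value
    response_definition: str


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def compare_auc(
    response,
    tmb,
    tme_group,
    combined=None,
    response_definition: str = "binary response as given",
) -> AUCComparison:
    """ROC comparison of TMB, TME group, and the combined predictor.

    AUCs use the rank (Mann-Whitney) formulation with midranks; each
    predictor pair gets a paired DeLong z and two-sided p.  The combined
    predictor defaults to the sum of min-max-standardized TMB and
    TME-group indicator, overridable via ``combined``.  A continuous
    response (more than two distinct values, e.g. a raw TIDE-like score)
    is dichotomized at its strict median.
    """
    resp = np.asarray(response, dtype=float)
    if len(np.unique(resp)) > 2:
        resp = (resp > np.median(resp)).astype(int)
        response_definition = "continuous response dichotomized at median"
    y = resp.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both classes")
    tmb = np.asarray(tmb, dtype=float)
    tme = np.asarray(tme_group, dtype=float)
    if combined is None:
        combined = _minmax(tmb) + _minmax(tme)
    preds = {"tmb": tmb, "tme_group": tme, "tmb_plus_tme": np.asarray(combined, float)}
    auc = pd.Series({k: mann_whitney_auc(y, v) for k, v in preds.items()})
    rows = []
    names = list(preds)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            _, _, z, p = delong_test(y, preds[a], preds[b])
            rows.append({"predictor_a": a, "predictor_b": b, "z": z, "p_value": p})
    return AUCComparison(auc, pd.DataFrame(rows), response_definition)


def group_score_test(values: pd.Series, grouping: pd.Series):
    """Two-sided Wilcoxon rank-sum comparison of a score between groups.

    Exact for combined n <= 20 without ties, otherwise normal
    approximation with tie and continuity correction.  Returns a dict
    with the p-value and per-group medians.
    """
    grouping = grouping.loc[values.index]
    levels = sorted(grouping.unique(), reverse=True)
    if len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    a = values[grouping == levels[0]].to_numpy(dtype=float)
    b = values[grouping == levels[1]].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    p = rank_sum_test(a, b)
    return {
        "p_value": p,
        "medians": {levels[0]: float(np.median(a)), levels[1]: float(np.median(b))},
    }


def pool_hazard_ratios(per_dataset) -> dict:
    """Fixed-effect inverse-variance pooling of log hazard ratios.

    ``per_dataset`` is an iterable of dicts with ``log_hr`` and ``se``.
    Returns pooled HR with its 95% CI (pooled log-HR +/- 1.96 pooled se,
    exponentiated).
    """
    log_hrs, ses = [], []
    for d in per_dataset:
        se = float(d["se"])
        if not np.isfinite(se) or se <= 0:
            raise ValueError("each dataset needs a finite se > 0")
        log_hrs.append(float(d["log_hr"]))
        ses.append(se)
    if not log_hrs:
        raise ValueError("need >= 1 dataset")
    w = 1.0 / np.square(ses)
    pooled = float(np.sum(w * np.asarray(log_hrs)) / w.sum())
    pooled_se = float(np.sqrt(1.0 / w.sum()))
    return {
        "hr": float(np.exp(pooled)),
        "ci": (
            float(np.exp(pooled - 1.96 * pooled_se)),
            float(np.exp(pooled + 1.96 * pooled_se)),
        ),
        "log_hr": pooled,
        "se": pooled_se,
    }


def assemble_landscape(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    tmb: pd.Series | None = None,
    maf: pd.DataFrame | None = None,
    genes=(),
    extra_columns: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Integrated per-sample table ordered by descending TMEscore.

    Left-joins clinical covariates, TMB, per-gene mutation indicator
    columns (1 if the sample carries >= 1 record of that gene), and any
    extra columns onto the score table.  Missing covariates stay missing;
    duplicated sample ids in any input are a hard error.
    """
    for name, frame in (("scores", scores), ("clinical", clinical)):
        if frame["sample_id"].duplicated().any():
            raise ValueError(f"duplicated sample_id in {name}")
    out = scores.merge(clinical, on="sample_id", how="left")
    if tmb is not None:
        if tmb.index.duplicated().any():
            raise ValueError("duplicated sample_id in tmb")
        out = out.merge(tmb.rename("tmb"), left_on="sample_id",
                        right_index=True, how="left")
    if maf is not None:
        for gene in genes:
            carriers = set(maf.loc[maf["gene"] == gene, "sample_id"])
            out[f"mut_{gene}"] = out["sample_id"].isin(carriers).astype(int)
    if extra_columns is not None:
        if extra_columns.index.duplicated().any():
            raise ValueError("duplicated sample_id in extra_columns")
        out = out.merge(extra_columns, left_on="sample_id",
                        right_index=True, how="left")
    return out.sort_values("tmescore", ascending=False, kind="stable").reset_index(
        drop=True
    )
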