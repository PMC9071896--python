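"""Immune-cell deconvolution of bulk expression.

Per-sample cell-type fractions are estimated by linear nu-support-vector
regression of the (standardized) mixture on the columns of a signature
matrix, following the published SVR deconvolution family: fit one model
per nu in a small grid, keep the nu with the lowest root-mean-square
reconstruction error, clip negative coefficients to zero and renormalize
to sum 1.  Significance comes from a permutation null on the mixture's
gene values.  A simpler marker-set abundance score (mean log2 expression
of population markers) is provided alongside.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import NuSVR

from .io import validate_expression, validate_signature_matrix

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _fit_sample(X: np.ndarray, y: np.ndarray, nu_grid) -> tuple[np.ndarray, float, float]:
    """Best-nu SVR fit of one mixture column; returns (weights, rmse, r)."""
    best = None
    for nu in sorted(nu_grid):
        model = NuSVR(nu=nu, kernel="linear", C=1.0, tol=1e-4, max_iter=20_000)
        with warnings.catch_warnings():
            # the iteration cap is a deliberate speed/accuracy trade-off
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        w = model.coef_.ravel().copy()
        w[w < 0] = 0.0
        recon = X @ w
        rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
        # strictly-smaller comparison keeps the smallest nu on RMSE ties
        if best is None or rmse < best[1]:
            r = _pearson(recon, y)
            best = (w, rmse, r)
    return best


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def estimate_fractions(
    mixture: pd.DataFrame,
    signature: pd.DataFrame,
    nu_grid=DEFAULT_NU_GRID,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate per-sample cell-type fractions from bulk expression.

    Parameters
    ----------
    mixture : genes x samples expression table (linear scale).
    signature : genes x cell-types signature matrix; at least half of its
        genes must be present in the mixture (the intersection is used).
    nu_grid : candidate nu values in (0, 1).
    n_perm : permutations for the per-sample p-value: the fraction of
        gene-shuffled copies of that sample's mixture whose refitted
        reconstruction correlation reaches the observed one, add-one
        smoothed.  ``n_perm < 1`` reports the p-value as missing.  Cost
        scales as n_samples * n_perm model fits, so large cohorts should
        use a modest n_perm (or 0 when only fractions are needed).
    seed : RNG seed for the permutations.

    Returns a sample x cell-type DataFrame of fractions (rows sum to 1)
    with ``rmse``, ``pearson_r`` and ``p_value`` columns appended.
    """
    validate_expression(mixture)
    validate_signature_matrix(signature)
    if not nu_grid or any(not (0 < nu < 1) for nu in nu_grid):
        raise ValueError("nu_grid must be non-empty with values in (0, 1)")
    shared = [g for g in signature.index if g in set(mixture.index)]
    if len(shared) < 0.5 * signature.shape[0]:
        missing = sorted(set(signature.index) - set(mixture.index))
        raise ValueError(
            f"only {len(shared)}/{signature.shape[0]} signature genes present; "
            f"missing e.g. {missing[:10]}"
        )
    X_raw = signature.loc[shared].to_numpy(dtype=float)
    X = _standardize(X_raw)
    rng = np.random.default_rng(seed)

    rows = []
    for sample in mixture.columns:
        y_raw = mixture.loc[shared, sample].to_numpy(dtype=float)
        y = _standardize(y_raw)
        w, rmse, r = _fit_sample(X, y, nu_grid)
        total = w.sum()
        if total <= 0:
            warnings.warn(f"all-zero coefficients for sample {sample}; uniform fractions")
            frac = np.full(w.size, 1.0 / w.size)
        else:
            frac = w / total
        p = np.nan
        if n_perm >= 1:
            # per-sample null: refit gene-shuffled copies of this mixture
            hits = 0
            for _ in range(n_perm):
                yb = _standardize(rng.permutation(y_raw))
                _, _, rb = _fit_sample(X, yb, nu_grid)
                hits += rb >= r
            p = (1 + hits) / (n_perm + 1)
        rows.append(np.concatenate([frac, [rmse, r, p]]))
    out = pd.DataFrame(
        rows,
        index=mixture.columns,
        columns=list(signature.columns) + ["rmse", "pearson_r", "p_value"],
    )
    return out


def fraction_matrix(fractions: pd.DataFrame) -> pd.DataFrame:
    """Drop the fit-statistic columns, keeping the sample x cell-type part."""
    return fractions.drop(columns=["rmse", "pearson_r", "p_value"], errors="ignore")


def mcp_abundance(mixture: pd.DataFrame, marker_sets: dict) -> pd.DataFrame:
    """Marker-set population abundance scores.

    abundance(population, sample) = mean of log2(expr + 1) over the
    population's marker genes present in the mixture.  Populations with no
    present marker genes are dropped with a warning.
    """
    validate_expression(mixture)
    log2e = np.log2(mixture + 1.0)
    cols = {}
    for pop, genes in marker_sets.items():
        present = [g for g in genes if g in mixture.index]
        if not present:
            warnings.warn(f"population {pop!r} has no marker genes in the mixture")
            continue
        cols[pop] = log2e.loc[present].mean(axis=0)
    if not cols:
        raise ValueError("no population had any marker genes present")
    return pd.DataFrame(cols)
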