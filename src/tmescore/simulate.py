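"""Synthetic cohorts with the statistical structure the analysis assumes.

Every downstream stage of the pipeline is testable against these
generators: bulk expression as mixtures of known cell fractions with
planted cluster structure and marker genes; exponential survival whose
log hazard follows a planted protective/risk gene axis with uniform
censoring; MAF files drawn from planted 96-context mutational signatures
with per-sample exposures and a controllable rank correlation between TMB
and a supplied score; and miRNA/methylation matrices with planted group
differences.  All draws are reproducible from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mutsig import BASES, CONTEXT_CATEGORIES, SUBSTITUTIONS, revcomp

__all__ = [
    "CohortTruth",
    "MafTruth",
    "OmicsTruth",
    "synthetic_signature_matrix",
    "simulate_cohort",
    "random_signatures",
    "simulate_maf",
    "simulate_omics",
]


@dataclass
class CohortTruth:
    """Ground truth planted by :func:`simulate_cohort`."""

    true_fractions: pd.DataFrame     # samples x cell types, rows sum to 1
    true_cluster: pd.Series          # per-sample label in 1..k_true
    protective_genes: list
    risk_genes: list
    hazard_beta: float
    baseline_hazard: float


@dataclass
class MafTruth:
    true_signatures: pd.DataFrame    # 96 x R, column-stochastic
    true_exposures: pd.DataFrame     # samples x R, rows sum to 1
    tmb_per_sample: pd.Series
    score_tmb_rho: float | None      # target rank correlation (None if uncoupled)


@dataclass
class OmicsTruth:
    de_features: list
    de_sign: dict = field(default_factory=dict)
    dm_features: list = field(default_factory=list)
    dm_direction: dict = field(default_factory=dict)
    survival_linked: list = field(default_factory=list)


def synthetic_signature_matrix(
    n_cell_types: int = 10,
    markers_per_type: int = 15,
    marker_boost: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A cell-type signature matrix with strong marker structure.

    Each cell type gets ``markers_per_type`` genes whose expression in that
    type is boosted ``marker_boost``-fold over a shared log-normal
    baseline — the conditioning an LM22-style leukocyte matrix provides.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_cell_types * markers_per_type
    base = rng.lognormal(mean=np.log(5.0), sigma=0.4, size=(n_genes, n_cell_types))
    for t in range(n_cell_types):
        rows = slice(t * markers_per_type, (t + 1) * markers_per_type)
        base[rows, t] *= marker_boost
    genes = [f"SIG{g + 1:04d}" for g in range(n_genes)]
    types = [f"CT{t + 1:02d}" for t in range(n_cell_types)]
    return pd.DataFrame(base, index=genes, columns=types)


def _separated_dirichlet_means(rng, k: int, dim: int, separation: float) -> np.ndarray:
    """k mean fraction vectors: Dirichlet draws pushed apart.

    A maximin greedy pick over a pool of Dirichlet(1) candidates, then
    sharpened by raising to the power ``separation`` and renormalizing
    (separation 1 leaves the draws untouched; larger values push the means
    toward distinct simplex corners).
    """
    pool = rng.dirichlet(np.ones(dim), size=max(50 * k, 100))
    chosen = [int(rng.integers(len(pool)))]
    while len(chosen) < k:
        d = np.min(
            np.linalg.norm(pool[:, None, :] - pool[chosen][None, :, :], axis=2),
            axis=1,
        )
        chosen.append(int(np.argmax(d)))
    means = pool[chosen] ** max(separation, 1e-9)
    return means / means.sum(axis=1, keepdims=True)


def _calibrate_censoring(rng, times: np.ndarray, censor_rate: float):
    """Uniform(0, c_max) censoring with c_max tuned to the target rate."""
    n = times.size
    if censor_rate <= 0:
        return times.copy(), np.ones(n, dtype=int)
    u = rng.uniform(size=n)
    lo, hi = 1e-9, float(times.max()) * 100
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = np.mean(u * mid < times)
        if frac > censor_rate:
            lo = mid
        else:
            hi = mid
    c = u * 0.5 * (lo + hi)
    event = (times <= c).astype(int)
    os_time = np.minimum(times, c)
    return os_time, event


def simulate_cohort(
    n_samples: int,
    n_genes: int,
    k_true: int,
    signature: pd.DataFrame,
    cluster_separation: float = 3.0,
    de_effect_log2fc: float = 2.0,
    hazard_beta: float = -1.0,
    censor_rate: float = 0.3,
    noise_sd: float = 0.3,
    seed: int = 0,
    markers_per_cluster: int = 10,
    library_size: float = 1e4,
    baseline_hazard: float = 1.0 / 365.0,
    jitter_sd: float = 0.02,
):
    """Generate a bulk-expression cohort with planted TME structure.

    Cluster labels are balanced (shuffled round-robin); per-cluster mean
    fraction vectors are Dirichlet draws pushed apart by
    ``cluster_separation``; per-sample fractions are jittered cluster means
    renormalized to sum 1.  Expression is signature @ fractions.T with
    columns scaled to ``library_size``, plus ``n_genes`` planted genes
    appended (``markers_per_cluster`` markers per cluster shifted up by
    ``de_effect_log2fc`` on the log2 scale in their own cluster, the rest
    pure noise), all under multiplicative log-normal noise of sd
    ``noise_sd``.  Survival is exponential with log hazard
    log(baseline) + hazard_beta * z, where z standardizes the planted
    protective-minus-risk gene score; censoring is independent uniform at
    approximately ``censor_rate``.

    Returns ``(expression, clinical, truth)``.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if k_true > n_samples:
        raise ValueError("k_true cannot exceed n_samples")
    for name, val in (
        ("cluster_separation", cluster_separation),
        ("de_effect_log2fc", de_effect_log2fc),
        ("noise_sd", noise_sd),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    n_types = signature.shape[1]
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]

    labels = rng.permutation(np.arange(n_samples) % k_true) + 1
    means = _separated_dirichlet_means(rng, k_true, n_types, cluster_separation)
    fracs = means[labels - 1] + rng.normal(0.0, jitter_sd, size=(n_samples, n_types))
    fracs = np.clip(fracs, 1e-6, None)
    fracs /= fracs.sum(axis=1, keepdims=True)

    sig_vals = signature.to_numpy(dtype=float)
    expr_sig = sig_vals @ fracs.T
    expr_sig *= library_size / expr_sig.sum(axis=0, keepdims=True)

    n_markers = min(k_true * markers_per_cluster, n_genes)
    n_noise = n_genes - n_markers
    marker_genes, noise_genes = [], []
    extra_rows = []
    protective, risk = [], []
    for c in range(k_true):
        per_c = n_markers // k_true + (1 if c < n_markers % k_true else 0)
        for j in range(per_c):
            gid = f"MRK{c + 1}_{j + 1:03d}"
            marker_genes.append(gid)
            base = rng.lognormal(np.log(20.0), 0.3)
            row = np.full(n_samples, base)
            row[labels == c + 1] *= 2.0**de_effect_log2fc
            extra_rows.append(row)
            if c == 0:
                protective.append(gid)
            elif c == 1:
                risk.append(gid)
    for j in range(n_noise):
        gid = f"NSE{j + 1:04d}"
        noise_genes.append(gid)
        extra_rows.append(np.full(n_samples, rng.lognormal(np.log(20.0), 0.5)))

    blocks = [expr_sig]
    if extra_rows:
        blocks.append(np.vstack(extra_rows))
    expr = np.vstack(blocks)
    if noise_sd > 0:
        expr = expr * np.exp(rng.normal(0.0, noise_sd, size=expr.shape))
    genes = list(signature.index) + marker_genes + noise_genes
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    log2e = np.log2(expression.to_numpy() + 1.0)
    gidx = {g: i for i, g in enumerate(genes)}
    score = np.zeros(n_samples)
    if protective:
        score += log2e[[gidx[g] for g in protective]].sum(axis=0)
    if risk:
        score -= log2e[[gidx[g] for g in risk]].sum(axis=0)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros(n_samples)
    rate = baseline_hazard * np.exp(hazard_beta * z)
    t_event = rng.exponential(1.0 / rate)
    os_time, os_event = _calibrate_censoring(rng, t_event, censor_rate)
    clinical = pd.DataFrame(
        {"sample_id": samples, "os_time": os_time, "os_event": os_event}
    )
    truth = CohortTruth(
        true_fractions=pd.DataFrame(fracs, index=samples, columns=signature.columns),
        true_cluster=pd.Series(labels, index=samples, name="true_cluster"),
        protective_genes=protective,
        risk_genes=risk,
        hazard_beta=hazard_beta,
        baseline_hazard=baseline_hazard,
    )
    return expression, clinical, truth


# ---------------------------------------------------------------------------
# mutational data


def random_signatures(
    n_signatures: int, seed: int = 0, concentration: float = 0.1,
    max_cosine: float = 0.3, max_tries: int = 500
) -> pd.DataFrame:
    """Distinct planted 96-context signatures (column-stochastic).

    Sparse Dirichlet draws over the 96 categories, redrawn until all
    pairwise cosines fall below ``max_cosine``.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        sigs = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
        norm = sigs / np.linalg.norm(sigs, axis=0, keepdims=True)
        sim = norm.T @ norm
        np.fill_diagonal(sim, 0.0)
        if n_signatures == 1 or sim.max() < max_cosine:
            cols = [f"P{i + 1}" for i in range(n_signatures)]
            return pd.DataFrame(sigs, index=list(CONTEXT_CATEGORIES), columns=cols)
    raise RuntimeError("could not draw sufficiently distinct signatures")


def _rank_couple(rng, values: np.ndarray, score: np.ndarray, rho: float) -> np.ndarray:
    """Reorder ``values`` so Spearman(values, score) is approximately rho.

    Iman-Conover-style: build a latent normal correlated with the rank
    normal scores of ``score`` at level rho, then place the sorted values
    at the latent variable's ranks.
    """
    n = values.size
    z = stats.norm.ppf((stats.rankdata(score) - 0.5) / n)
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    noise = rng.standard_normal(n)
    w = rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * noise
    out = np.empty(n, dtype=values.dtype)
    out[np.argsort(w, kind="stable")] = np.sort(values)
    return out


def _emit_snv(rng, category: str):
    """Realize a 96-context category as (ref, alt, 3-base context).

    The pyrimidine-strand category is placed on either strand with
    probability 1/2.
    """
    five, mid, three = category[0], category[2:5], category[6]
    ref, alt = mid[0], mid[2]
    context = five + ref + three
    if rng.uniform() < 0.5:
        ref, alt = revcomp(ref), revcomp(alt)
        context = revcomp(context)
    return ref, alt, context


def simulate_maf(
    n_samples: int,
    true_signatures: pd.DataFrame,
    exposure_concentration: float = 1.0,
    tmb_mean: float = 200.0,
    tmb_dispersion: float = 2.0,
    coupling_score=None,
    coupling_rho: float = 0.0,
    gene_pool=None,
    seed: int = 0,
    other_class_frac: float = 0.0,
):
    """Draw a MAF from planted 96-context signatures.

    Per-sample TMB is negative binomial (deterministic when
    ``tmb_dispersion`` is infinite) with a floor of 1; when
    ``coupling_score`` is supplied, TMB values are rank-reordered so their
    Spearman correlation with the score approximates ``coupling_rho``.
    Exposures are Dirichlet(``exposure_concentration``); each mutation
    draws a context category from the exposure-mixed signature and is
    emitted on a random strand.  ``other_class_frac`` optionally sprinkles
    frame-shift deletions (that fraction of each sample's SNV count) for
    summary-level tests.

    Returns ``(mutation_table, truth)``.
    """
    sigs = true_signatures.to_numpy(dtype=float)
    if sigs.shape[0] != 96:
        raise ValueError("true_signatures must have 96 rows")
    if np.max(np.abs(sigs.sum(axis=0) - 1.0)) > 1e-6:
        raise ValueError("signature columns must sum to 1")
    if tmb_mean <= 0:
        raise ValueError("tmb_mean must be positive")
    rng = np.random.default_rng(seed)
    n_sig = sigs.shape[1]
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    if gene_pool is None:
        gene_pool = [f"GENE{i + 1:03d}" for i in range(50)]
    gene_pool = list(gene_pool)

    if np.isinf(tmb_dispersion):
        tmb = np.full(n_samples, int(round(tmb_mean)))
    else:
        p = tmb_dispersion / (tmb_dispersion + tmb_mean)
        tmb = rng.negative_binomial(tmb_dispersion, p, size=n_samples)
    tmb = np.maximum(tmb, 1)
    if coupling_score is not None:
        tmb = _rank_couple(rng, tmb, np.asarray(coupling_score, dtype=float),
                           coupling_rho)

    exposures = rng.dirichlet(
        np.full(n_sig, exposure_concentration), size=n_samples
    )
    records = []
    pos_counter = 1
    for i, sample in enumerate(samples):
        probs = sigs @ exposures[i]
        probs = probs / probs.sum()
        cats = rng.choice(96, size=int(tmb[i]), p=probs)
        for cat_idx in cats:
            ref, alt, context = _emit_snv(rng, CONTEXT_CATEGORIES[cat_idx])
            records.append(
                {
                    "sample_id": sample,
                    "gene": gene_pool[int(rng.integers(len(gene_pool)))],
                    "chrom": "1",
                    "pos": pos_counter,
                    "ref": ref,
                    "alt": alt,
                    "var_class": "Missense_Mutation",
                    "var_type": "SNP",
                    "ref_context": context,
                }
            )
            pos_counter += 2
        n_other = int(round(other_class_frac * tmb[i]))
        for _ in range(n_other):
            records.append(
                {
                    "sample_id": sample,
                    "gene": gene_pool[int(rng.integers(len(gene_pool)))],
                    "chrom": "1",
                    "pos": pos_counter,
                    "ref": "A",
                    "alt": "-",
                    "var_class": "Frame_Shift_Del",
                    "var_type": "DEL",
                    "ref_context": None,
                }
            )
            pos_counter += 2
    maf = pd.DataFrame(records)
    truth = MafTruth(
        true_signatures=true_signatures.copy(),
        true_exposures=pd.DataFrame(
            exposures, index=samples, columns=true_signatures.columns
        ),
        tmb_per_sample=pd.Series(tmb, index=samples, name="tmb"),
        score_tmb_rho=None if coupling_score is None else float(coupling_rho),
    )
    return maf, truth


# ---------------------------------------------------------------------------
# miRNA / methylation


def simulate_omics(
    n_samples: int,
    n_features: int,
    group_labels,
    frac_de: float = 0.1,
    log2fc: float = 2.0,
    frac_dm: float = 0.05,
    delta_beta: float = 0.3,
    survival_link_frac: float = 0.0,
    seed: int = 0,
):
    """miRNA and methylation matrices with planted group differences.

    miRNA is log-normal with |log2FC| = ``log2fc`` planted in a
    ``frac_de`` subset (alternating direction); methylation beta values
    stay strictly inside (0, 1) with a planted group-mean difference of
    ``delta_beta`` in a ``frac_dm`` subset.  A ``survival_link_frac``
    subset of each matrix is flagged as survival-linked in the truth for
    screening tests.

    Returns ``(mirna, methylation, truth)``.
    """
    groups = np.asarray(group_labels)
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("group_labels must be binary 0/1")
    if groups.size != n_samples:
        raise ValueError("group_labels length must equal n_samples")
    if not 0 <= frac_de <= 1 or not 0 <= frac_dm <= 1 or not 0 <= survival_link_frac <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if delta_beta >= 1:
        raise ValueError("delta_beta must be < 1 to keep beta values in (0,1)")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    g1 = groups == 1

    mir_names = [f"mir{i + 1:04d}" for i in range(n_features)]
    base = rng.lognormal(np.log(50.0), 0.8, size=n_features)
    mirna = base[:, None] * np.exp(rng.normal(0.0, 0.4, size=(n_features, n_samples)))
    n_de = int(round(frac_de * n_features))
    de_features = mir_names[:n_de]
    de_sign = {}
    for i in range(n_de):
        sign = 1 if i % 2 == 0 else -1
        mirna[i, g1] *= 2.0 ** (sign * log2fc)
        de_sign[mir_names[i]] = sign
    mirna = pd.DataFrame(mirna, index=mir_names, columns=samples)

    cg_names = [f"cg{i + 1:06d}" for i in range(n_features)]
    centers = rng.uniform(0.2, 0.8, size=n_features)
    meth = centers[:, None] + rng.normal(0.0, 0.05, size=(n_features, n_samples))
    n_dm = int(round(frac_dm * n_features))
    dm_features = cg_names[:n_dm]
    dm_direction = {}
    eps = 1e-4
    for i in range(n_dm):
        up = centers[i] + delta_beta < 1.0 - 10 * eps
        shift = delta_beta if up else -delta_beta
        meth[i, g1] += shift
        dm_direction[cg_names[i]] = 1 if up else -1
    meth = np.clip(meth, eps, 1.0 - eps)
    meth = pd.DataFrame(meth, index=cg_names, columns=samples)

    n_link = int(round(survival_link_frac * n_features))
    truth = OmicsTruth(
        de_features=de_features,
        de_sign=de_sign,
        dm_features=dm_features,
        dm_direction=dm_direction,
        survival_linked=mir_names[:n_link],
    )
    return mirna, meth, truth
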