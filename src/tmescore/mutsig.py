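"""Mutation-spectrum analysis.

MAF summarization, tumor mutation burden (TMB), the 96 trinucleotide
substitution-context catalog, non-negative matrix factorization of the
catalog into mutational signatures (generalized Kullback-Leibler
divergence, multiplicative updates), cosine matching of extracted
signatures against a reference collection, and per-gene mutation-rate
comparison between sample groups.

The 96 categories are the six pyrimidine-strand single-base substitutions
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 4 x 4 immediate 5'/3'
flanking bases; substitutions observed on the purine strand are
reverse-complemented onto the pyrimidine strand before counting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 96 context categories, ordered by substitution class, then 5' flank,
#: then 3' flank (alphabetically) — the conventional reference row order.
CONTEXT_CATEGORIES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CATEGORY_INDEX = {c: i for i, c in enumerate(CONTEXT_CATEGORIES)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def context_category(ref: str, alt: str, context: str) -> str | None:
    """Map a SNV to its pyrimidine-strand category, or None if ambiguous.

    ``context`` is the odd-length reference sequence centered on the
    mutated base; only the immediate flanks are used.
    """
    mid = len(context) // 2
    five, three = context[mid - 1], context[mid + 1]
    if any(b not in COMPLEMENT for b in (ref, alt, five, three)):
        return None
    if ref in ("G", "A"):  # purine strand: flip everything
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    return f"{five}[{ref}>{alt}]{three}"


def snv_class(ref: str, alt: str) -> str | None:
    """Six-class substitution label on the pyrimidine strand."""
    if ref not in COMPLEMENT or alt not in COMPLEMENT:
        return None
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


# ---------------------------------------------------------------------------
# MAF summaries


@dataclass
class MafSummary:
    by_variant_classification: pd.Series
    by_variant_type: pd.Series
    by_snv_class: pd.Series
    per_sample_counts: pd.Series
    top_genes: pd.Series  # gene -> fraction of samples mutated


def summarize_maf(maf: pd.DataFrame, top_n: int = 10) -> MafSummary:
    """Deterministic count tables over a mutation table.

    SNV classes collapse G/A references onto the pyrimidine strand
    (G>A counts as C>T).  Gene ranking is by fraction of samples carrying
    at least one mutation; ties break alphabetically.
    """
    if len(maf) == 0:
        raise ValueError("empty mutation table")
    by_class = maf["var_class"].value_counts().sort_index()
    by_type = maf["var_type"].value_counts().sort_index()
    snp = maf[maf["var_type"] == "SNP"]
    classes = [snv_class(r, a) for r, a in zip(snp["ref"], snp["alt"])]
    by_snv = (
        pd.Series([c for c in classes if c is not None])
        .value_counts()
        .reindex(list(SUBSTITUTIONS), fill_value=0)
    )
    per_sample = maf.groupby("sample_id").size().sort_index()
    n_samples = maf["sample_id"].nunique()
    frac = (
        maf.groupby("gene")["sample_id"].nunique() / n_samples
    )
    frac = frac.sort_index().sort_values(ascending=False, kind="stable")
    return MafSummary(by_class, by_type, by_snv, per_sample, frac.head(top_n))


def compute_tmb(maf: pd.DataFrame, roster=None) -> pd.DataFrame:
    """Per-sample mutation counts with a strict-median high/low split.

    TMB is the raw count of somatic records per sample (no per-megabase
    normalization).  Samples in ``roster`` absent from the MAF get TMB 0.
    """
    counts = maf.groupby("sample_id").size()
    if roster is not None:
        counts = counts.reindex(list(roster), fill_value=0)
    counts = counts.sort_index()
    median = float(counts.median())
    group = np.where(counts > median, "high", "low")
    return pd.DataFrame({"sample_id": counts.index, "tmb": counts.to_numpy(),
                         "group": group}).reset_index(drop=True)


# ---------------------------------------------------------------------------
# 96-context catalog


@dataclass
class ContextCatalog:
    """96 x sample substitution-context count matrix."""

    counts: pd.DataFrame  # index = CONTEXT_CATEGORIES, columns = samples
    n_skipped: int  # SNVs dropped for ambiguous bases (N etc.)

    def __post_init__(self):
        assert list(self.counts.index) == list(CONTEXT_CATEGORIES)


def build_context_catalog(maf: pd.DataFrame, fasta=None) -> ContextCatalog:
    """Count 96 substitution contexts per sample from SNP records.

    Context comes from the ``ref_context`` column or, failing that, from an
    indexed FASTA; a SNP with neither is a hard error.  Records containing
    ambiguous bases are skipped and counted.  Non-SNP records are ignored.
    """
    snp = maf[maf["var_type"] == "SNP"]
    samples = sorted(maf["sample_id"].unique())
    mat = np.zeros((96, len(samples)), dtype=int)
    col = {s: j for j, s in enumerate(samples)}
    fa = None
    if fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta))
    n_skipped = 0
    for row in snp.itertuples():
        ctx = row.ref_context
        if ctx is None or (isinstance(ctx, float) and np.isnan(ctx)) or ctx is pd.NA:
            if fa is None:
                raise ValueError(
                    f"SNP at {row.chrom}:{row.pos} lacks ref_context and no FASTA given"
                )
            lo = max(row.pos - 2, 0)
            ctx = str(fa[row.chrom][lo : row.pos + 1]).upper()
        cat = context_category(row.ref, row.alt, str(ctx))
        if cat is None:
            n_skipped += 1
            continue
        mat[_CATEGORY_INDEX[cat], col[row.sample_id]] += 1
    counts = pd.DataFrame(mat, index=list(CONTEXT_CATEGORIES), columns=samples)
    return ContextCatalog(counts, n_skipped)


# ---------------------------------------------------------------------------
# NMF signature extraction


@dataclass
class SignatureDecomposition:
    signatures: pd.DataFrame  # 96 x R, column-stochastic
    exposures: pd.DataFrame   # R x samples, non-negative
    rank: int
    divergence: float
    n_restarts: int
    divergence_history: np.ndarray  # per-iteration divergence of the best run


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = float(WH.sum() - V.sum())
    div += float(np.sum(V[mask] * np.log(V[mask] / WH[mask])))
    return div


def _nmf_kl(V: np.ndarray, rank: int, rng: np.random.Generator,
            max_iter: int, tol: float):
    """Multiplicative-update NMF minimizing generalized KL divergence."""
    eps = 1e-12
    n, m = V.shape
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.1, 1.0, size=(n, rank)) * scale
    H = rng.uniform(0.1, 1.0, size=(rank, m)) * scale
    history = []
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1), eps)
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        div = _kl_divergence(V, W @ H + eps)
        history.append(div)
        if prev - div < tol * max(abs(prev), 1.0):
            break
        prev = div
    return W, H, history[-1], np.asarray(history)


def extract_signatures(
    catalog: ContextCatalog | pd.DataFrame,
    rank: int,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> SignatureDecomposition:
    """Factor the 96 x sample catalog into ``rank`` mutational signatures.

    Best of ``n_restarts`` random initializations by final divergence.
    Signatures are normalized to probability vectors (column sums 1) with
    the removed mass folded into the exposures.
    """
    counts = catalog.counts if isinstance(catalog, ContextCatalog) else catalog
    V = counts.to_numpy(dtype=float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if V.sum() == 0:
        raise ValueError("all-zero catalog")
    nonzero = (V.sum(axis=0) > 0).sum()
    if nonzero < rank:
        raise ValueError(f"need >= {rank} samples with nonzero counts")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        W, H, div, hist = _nmf_kl(V, rank, rng, max_iter, tol)
        if best is None or div < best[2]:
            best = (W, H, div, hist)
    W, H, div, hist = best
    colsum = np.maximum(W.sum(axis=0), 1e-300)
    W = W / colsum
    H = H * colsum[:, None]
    names = [f"S{i + 1}" for i in range(rank)]
    return SignatureDecomposition(
        signatures=pd.DataFrame(W, index=counts.index, columns=names),
        exposures=pd.DataFrame(H, index=names, columns=counts.columns),
        rank=rank,
        divergence=float(div),
        n_restarts=n_restarts,
        divergence_history=hist,
    )


def cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise cosine similarity matrix (columns of A x columns of B)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (A.T @ B) / np.outer(na, nb)


def greedy_match(A: np.ndarray, B: np.ndarray):
    """Greedily pair columns of A with columns of B by descending cosine.

    Returns a list of ``(i, j, cosine)`` with each column used at most once.
    """
    sim = cosine_matrix(A, B)
    pairs = []
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-sim, axis=None), sim.shape))[0]
    for i, j in order:
        if i in used_a or j in used_b:
            continue
        pairs.append((int(i), int(j), float(sim[i, j])))
        used_a.add(int(i))
        used_b.add(int(j))
        if len(pairs) == min(sim.shape):
            break
    return pairs


def match_signatures(
    extracted: SignatureDecomposition | pd.DataFrame, reference: pd.DataFrame
):
    """Cosine-match extracted signatures against a reference collection.

    ``reference`` must have the 96 categories as rows in catalog order.
    Returns ``(cosine_table, best_match)`` where ``best_match`` maps each
    extracted signature to its argmax reference column (ties break toward
    the lowest reference index).
    """
    sigs = (
        extracted.signatures
        if isinstance(extracted, SignatureDecomposition)
        else extracted
    )
    if reference.shape[0] != 96:
        raise ValueError("reference matrix must have exactly 96 rows")
    sim = cosine_matrix(sigs.to_numpy(), reference.to_numpy())
    table = pd.DataFrame(sim, index=sigs.columns, columns=reference.columns)
    best = table.columns[np.argmax(table.to_numpy(), axis=1)]
    return table, pd.Series(best, index=sigs.columns, name="best_match")


@dataclass
class RankScan:
    ranks: list
    stability: pd.Series       # mean matched cosine across restarts per rank
    divergence: pd.Series      # best-restart divergence per rank
    selected_rank: int


def select_rank(
    catalog: ContextCatalog | pd.DataFrame,
    ranks=range(1, 7),
    n_restarts: int = 20,
    stability_threshold: float = 0.9,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> RankScan:
    """Stability-based NMF rank selection.

    For each candidate rank, all restarts' signatures are greedily matched
    to the best-divergence solution; the per-restart score is the cosine of
    the WORST-matched signature, and stability is its mean over restarts.
    Ranks beyond the true complexity carry at least one signature that
    fails to reproduce across restarts, so the selected rank is the
    largest one whose stability reaches ``stability_threshold``.
    """
    counts = catalog.counts if isinstance(catalog, ContextCatalog) else catalog
    V = counts.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    stab, divs = {}, {}
    for rank in ranks:
        sols = []
        for _ in range(n_restarts):
            W, _, div, _ = _nmf_kl(V, rank, rng, max_iter, tol)
            sols.append((W / np.maximum(W.sum(axis=0), 1e-300), div))
        best_W = min(sols, key=lambda s: s[1])[0]
        worst = [
            min(c for _, _, c in greedy_match(best_W, W)) for W, _ in sols
        ]
        stab[rank] = float(np.mean(worst))
        divs[rank] = float(min(d for _, d in sols))
    stable = [r for r in ranks if stab[r] >= stability_threshold]
    selected = max(stable) if stable else min(ranks)
    return RankScan(
        ranks=list(ranks),
        stability=pd.Series(stab, name="stability"),
        divergence=pd.Series(divs, name="divergence"),
        selected_rank=int(selected),
    )


# ---------------------------------------------------------------------------
# group comparison of per-gene mutation rates


def compare_gene_mutation_rates(
    maf: pd.DataFrame, groups: pd.Series, min_mutated: int = 5
) -> pd.DataFrame:
    """Two-sided Fisher exact test of per-gene mutation rates between groups.

    ``groups`` maps sample id to 'high'/'low'.  Genes mutated in fewer
    than ``min_mutated`` samples overall are skipped.  BH adjustment is
    applied across the tested genes.
    """
    groups = groups.astype(str)
    high = set(groups.index[groups == "high"])
    low = set(groups.index[groups == "low"])
    if not high or not low:
        raise ValueError("both groups must be non-empty")
    mutated = maf.groupby("gene")["sample_id"].agg(lambda s: set(s))
    rows = []
    for gene, samples in mutated.items():
        if len(samples) < min_mutated:
            continue
        a = len(samples & high)
        b = len(high) - a
        c = len(samples & low)
        d = len(low) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "gene": gene,
                "n_high": a,
                "n_low": c,
                "frac_high": a / len(high),
                "frac_low": c / len(low),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p_value"])
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out
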