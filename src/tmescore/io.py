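"""Readers, writers and validators for the pipeline's tabular formats.

Expression, clinical, and signature tables travel as validated pandas
DataFrames; somatic mutations travel as a long-format DataFrame parsed from
MAF.  All on-disk formats are TSV (or MAF, itself tab-separated); an
optional indexed FASTA supplies trinucleotide context for SNVs.

Conventions
-----------
* Expression: genes in rows (index = gene ids), samples in columns,
  linear-scale non-negative values.  Inputs declared as log2 are
  back-transformed on read (2**v - 1, clipped at 0).
* Clinical: one row per sample; required columns ``sample_id``,
  ``os_time`` (days, > 0), ``os_event`` (0/1).  Optional columns
  (subtype, stage, response_score, msi_score, purity, ploidy, ...) are
  preserved.
* MAF positions are 1-based inclusive; flank extraction for a SNP at
  position p reads p-1..p+1.
"""
from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBTYPES = {"LumA", "LumB", "Basal", "Her2", "Normal"}

MAF_REQUIRED = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
]

#: canonical MutationTable columns
MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_class",
    "var_type",
    "ref_context",
]

VARIANT_TYPES = {"SNP", "INS", "DEL", "DNP", "TNP"}


# ---------------------------------------------------------------------------
# validators


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Check an expression table (genes x samples, linear scale)."""
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    if df.shape[1] < 2:
        raise ValueError("expression table needs at least 2 samples")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression table contains non-finite values")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative expression at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return df


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table (one row per sample)."""
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    bad = df.index[~(df["os_time"] > 0)].tolist()
    if bad:
        raise ValueError(f"os_time must be > 0; offending rows: {bad[:5]}")
    if not df["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be 0 or 1")
    if "purity" in df.columns:
        pur = df["purity"].dropna()
        if ((pur < 0) | (pur > 1)).any():
            raise ValueError("purity must lie in [0, 1]")
    if "ploidy" in df.columns:
        plo = df["ploidy"].dropna()
        if (plo <= 0).any():
            raise ValueError("ploidy must be positive")
    return df


def validate_signature_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Check a cell-type signature matrix (genes x cell types)."""
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate labels in signature matrix")
    if df.shape[1] < 2:
        raise ValueError("signature matrix needs >= 2 cell types")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("signature matrix values must be finite and >= 0")
    return df


def validate_mutation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a MutationTable DataFrame (canonical long format)."""
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns {missing}")
    if (df["pos"] < 1).any():
        raise ValueError("positions must be >= 1")
    snp = df[df["var_type"] == "SNP"]
    bad = snp[
        (snp["ref"].str.len() != 1)
        | (snp["alt"].str.len() != 1)
        | (snp["ref"] == snp["alt"])
    ]
    if len(bad):
        raise ValueError(f"malformed SNP records at rows {bad.index[:5].tolist()}")
    ctx = df["ref_context"].dropna()
    if len(ctx):
        rows = ctx.index
        lengths = ctx.str.len()
        if (lengths % 2 == 0).any():
            raise ValueError("ref_context must have odd length")
        centers = np.array([c[len(c) // 2] for c in ctx])
        refs = df.loc[rows, "ref"].to_numpy()
        mism = rows[(df.loc[rows, "var_type"] == "SNP").to_numpy() & (centers != refs)]
        if len(mism):
            raise ValueError(
                f"ref_context center disagrees with ref_allele at rows {mism[:5].tolist()}"
            )
    return df


# ---------------------------------------------------------------------------
# readers


def read_expression_table(path, log2_input: bool = False) -> pd.DataFrame:
    """Read a gene x sample expression TSV.

    First column holds gene ids, header row holds sample ids.  With
    ``log2_input`` the values are back-transformed to linear scale as
    ``2**v - 1`` and clipped at 0.  Duplicate gene rows are collapsed by
    arithmetic mean with a logged warning; duplicate sample ids are a hard
    error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({name for name in header if header.count(name) > 1})
    if dups:
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if log2_input:
        df = (np.power(2.0, df.astype(float)) - 1.0).clip(lower=0.0)
    if df.index.duplicated().any():
        ndup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean", ndup)
        warnings.warn(f"collapsed {ndup} duplicate gene rows by mean")
        df = df.groupby(level=0, sort=False).mean()
    return validate_expression(df.astype(float))


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical TSV; unknown columns are preserved as covariates."""
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str) if "sample_id" in df else None
    validate_clinical(df)
    if "subtype" in df.columns:
        df["subtype"] = pd.Categorical(df["subtype"])
    return df


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a gene x cell-type signature matrix TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return validate_signature_matrix(df.astype(float))


def read_maf(path, fasta=None) -> pd.DataFrame:
    """Parse a MAF into the canonical mutation DataFrame.

    When ``fasta`` (an indexed FASTA path) is given and a SNP record lacks
    ``ref_context``, the 3-base context pos-1..pos+1 is extracted.  SNP
    records whose reference allele disagrees with the FASTA are dropped
    with a warning; the rejection count is stored in ``df.attrs['n_rejected']``.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"MAF missing required columns {missing}")
    pos = pd.to_numeric(raw["Start_Position"], errors="coerce")
    if pos.isna().any():
        raise ValueError(
            f"malformed Start_Position at MAF rows {pos.index[pos.isna()][:5].tolist()}"
        )
    df = pd.DataFrame(
        {
            "sample_id": raw["Tumor_Sample_Barcode"].astype(str),
            "gene": raw["Hugo_Symbol"].astype(str),
            "chrom": raw["Chromosome"].astype(str),
            "pos": pos.astype(int),
            "ref": raw["Reference_Allele"].astype(str),
            "alt": raw["Tumor_Seq_Allele2"].astype(str),
            "var_class": raw["Variant_Classification"].astype(str),
            "var_type": raw["Variant_Type"].astype(str),
            "ref_context": raw["ref_context"] if "ref_context" in raw else pd.NA,
        }
    )
    n_rejected = 0
    if fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta))
        keep = np.ones(len(df), dtype=bool)
        contexts = df["ref_context"].astype(object).to_numpy()
        for i, row in enumerate(df.itertuples(index=False)):
            if row.var_type != "SNP":
                continue
            seq = fa[row.chrom]
            base = str(seq[row.pos - 1 : row.pos]).upper()
            if base != row.ref:
                keep[i] = False
                n_rejected += 1
                continue
            if contexts[i] is pd.NA or contexts[i] is None or contexts[i] != contexts[i]:
                lo = max(row.pos - 2, 0)
                contexts[i] = str(seq[lo : row.pos + 1]).upper()
        if n_rejected:
            warnings.warn(
                f"rejected {n_rejected} SNP records disagreeing with the FASTA"
            )
        df = df.loc[keep].reset_index(drop=True)
        df["ref_context"] = contexts[keep]
    df["ref_context"] = df["ref_context"].astype("string")
    df.attrs["n_rejected"] = n_rejected
    return validate_mutation_table(df)


# ---------------------------------------------------------------------------
# writers


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_clinical_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_maf(df: pd.DataFrame, path) -> None:
    """Write the canonical mutation table back out as a MAF."""
    out = pd.DataFrame(
        {
            "Hugo_Symbol": df["gene"],
            "Tumor_Sample_Barcode": df["sample_id"],
            "Chromosome": df["chrom"],
            "Start_Position": df["pos"],
            "Reference_Allele": df["ref"],
            "Tumor_Seq_Allele2": df["alt"],
            "Variant_Classification": df["var_class"],
            "Variant_Type": df["var_type"],
            "ref_context": df["ref_context"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_manifest(path, params: dict, input_paths: dict | None = None) -> None:
    """Write a plain-text key/value run manifest (parameters, seeds, hashes)."""
    lines = []
    for key, value in sorted(params.items()):
        lines.append(f"{key}\t{value}")
    for name, p in sorted((input_paths or {}).items()):
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        lines.append(f"sha256:{name}\t{digest}")
    Path(path).write_text("\n".join(lines) + "\n")
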