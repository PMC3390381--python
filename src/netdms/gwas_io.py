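"""Reading and writing GWAS summary tables and gene annotations.

The unit of input is a per-study SNP association table (TSV with header).
SNPs are mapped to protein-coding genes by physical position — a SNP belongs
to a gene if it falls within the gene body or within a flanking window
(default 20 kb) on either side — and every gene is summarised by the P value
of its most significant SNP ("gene-wise P").  This min-P summary is simple
and powerful but confounded by gene length and SNP density; the assessment
module corrects for exactly that.

All tables are carried as :class:`pandas.DataFrame` with canonical column
names; converters accept a ``dialect`` mapping for files with other headers.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError, DomainError

log = logging.getLogger(__name__)

#: canonical columns of a SNP association table
SNP_REQUIRED = ("snp_id", "chrom", "pos", "p")
SNP_OPTIONAL = ("allele_ref", "allele_alt", "beta", "se")

#: key used for SNPs that map to no gene
INTERGENIC = ""


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name: strip a leading ``chr``, upper-case X/Y/MT."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in {"X", "Y", "MT", "M"}:
        c = "MT" if c.upper() in {"MT", "M"} else c.upper()
    return c


def _rename(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def read_snp_associations(
    path,
    dialect: Mapping[str, str] | None = None,
    return_rejected: bool = False,
):
    """Read a per-study SNP association TSV.

    Parameters
    ----------
    path
        TSV file with a header line.  Required columns: ``snp_id``, ``chrom``,
        ``pos``, ``p``; optional: ``allele_ref``, ``allele_alt``, ``beta``,
        ``se``.  ``dialect`` maps canonical names to the file's column names,
        e.g. ``{"snp_id": "SNP", "p": "P"}``.
    return_rejected
        If True, also return the DataFrame of rejected rows with a ``reason``
        column.

    Rows with an unparsable or out-of-range P value (p <= 0 or p > 1) or a
    non-positive position are rejected and reported; the remainder is loaded
    with the input row order preserved.  P values of exactly 0 are a domain
    violation here — clamping happens only at the z-transformation stage.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    df = _rename(df, dialect)
    for col in SNP_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise FormatError(
            f"duplicate snp_id values in {path}: {sorted(set(dup))[:10]}"
        )
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["p"] = pd.to_numeric(df["p"], errors="coerce")
    for col in SNP_OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["se"] = pd.to_numeric(df["se"], errors="coerce")
    # se must be positive when present
    bad_se = df["se"].notna() & (df["se"] <= 0)
    if bad_se.any():
        warnings.warn(f"{int(bad_se.sum())} rows with non-positive se set to missing")
        df.loc[bad_se, "se"] = np.nan

    reason = pd.Series("", index=df.index)
    reason[df["p"].isna()] = "unparsable p"
    reason[(df["p"] <= 0) | (df["p"] > 1)] = "p out of (0, 1]"
    reason[df["pos"].isna() | (df["pos"] < 1)] = "invalid position"
    bad = reason != ""
    rejected = df[bad].assign(reason=reason[bad])
    if bad.any():
        warnings.warn(
            f"rejected {int(bad.sum())} of {len(df)} rows from {path}: "
            + "; ".join(f"{r}: {n}" for r, n in rejected["reason"].value_counts().items())
        )
    df = df[~bad].copy()
    df["pos"] = df["pos"].astype(np.int64)
    cols = list(SNP_REQUIRED) + list(SNP_OPTIONAL)
    df = df[cols].reset_index(drop=True)
    if return_rejected:
        return df, rejected
    return df


def write_snp_associations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_annotations(path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a gene annotation table.

    ``fmt='tsv'``: columns gene, chrom, start, end with 1-based inclusive
    coordinates.  ``fmt='bed'``: standard BED (chrom, start, end, name) with
    0-based half-open coordinates, converted to 1-based inclusive.
    """
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene"], usecols=range(4),
            dtype={"chrom": str},
        )
        df["start"] = df["start"].astype(np.int64) + 1
        df["end"] = df["end"].astype(np.int64)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
        for col in ("gene", "chrom", "start", "end"):
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r} in {path}")
    else:
        raise FormatError(f"unknown annotation format {fmt!r}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] > df["end"]).any():
        raise FormatError("annotation rows with start > end")
    if df["gene"].duplicated().any():
        raise FormatError(
            "duplicate gene symbols: "
            f"{sorted(set(df['gene'][df['gene'].duplicated()]))[:10]}"
        )
    df["length"] = df["end"] - df["start"] + 1
    return df[["gene", "chrom", "start", "end", "length"]].reset_index(drop=True)


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, flank: int = 20_000
) -> dict[str, frozenset]:
    """Map each SNP to the set of genes whose flanked interval contains it.

    A SNP maps to gene *g* iff ``start - flank <= pos <= end + flank`` on the
    same chromosome (boundaries inclusive).  A SNP may map to several
    overlapping genes and then counts fully toward each.  SNPs that map to no
    gene are returned with an empty set (the "intergenic" bucket).
    """
    if flank < 0:
        raise DomainError(f"flank must be >= 0, got {flank}")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        t = IntervalTree()
        for g, s, e in zip(sub["gene"], sub["start"], sub["end"]):
            # interval end is exclusive in intervaltree
            t.addi(max(0, s - flank), e + flank + 1, g)
        trees[chrom] = t
    mapping: dict[str, frozenset] = {}
    for sid, chrom, pos in zip(snps["snp_id"], snps["chrom"], snps["pos"]):
        t = trees.get(chrom)
        hits = frozenset(iv.data for iv in t[pos]) if t is not None else frozenset()
        mapping[sid] = hits
    n_inter = sum(1 for v in mapping.values() if not v)
    log.info("mapped %d SNPs, %d intergenic", len(mapping), n_inter)
    return mapping


def gene_wise_p(
    snps: pd.DataFrame,
    mapping: Mapping[str, frozenset],
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summarise SNP associations per gene by the most significant SNP.

    Returns a table with columns gene, p_gene, best_snp, n_snps, gene_length
    (length NaN when no annotation is supplied).  Genes with zero mapped
    SNPs are absent.  Ties on the minimum P are broken by the smallest
    snp_id so the result is order-invariant.
    """
    rows: dict[str, list] = {}
    for sid, p in zip(snps["snp_id"], snps["p"]):
        for g in mapping.get(sid, ()):
            if g != INTERGENIC:
                rows.setdefault(g, []).append((p, sid))
    if not rows:
        warnings.warn("empty SNP-to-gene mapping: no gene-wise P values produced")
        return pd.DataFrame(columns=["gene", "p_gene", "best_snp", "n_snps", "gene_length"])
    recs = []
    for g in sorted(rows):
        entries = rows[g]
        p_min, best = min(entries)
        recs.append((g, p_min, best, len(entries)))
    out = pd.DataFrame(recs, columns=["gene", "p_gene", "best_snp", "n_snps"])
    if genes is not None:
        out = out.merge(genes[["gene", "length"]], on="gene", how="left")
        out = out.rename(columns={"length": "gene_length"})
    else:
        out["gene_length"] = np.nan
    return out


def write_gene_associations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_associations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "p_gene"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    return df


def read_ppi_edges(path, require_evidence: bool = False) -> list[tuple[str, str]]:
    """Read a protein-interaction edge list (two columns of gene symbols,
    optional third evidence column).

    Self-loops are removed and duplicate / reversed pairs are collapsed to a
    single undirected edge.  With ``require_evidence``, rows whose evidence
    field is empty are dropped (keep interactions with experimental support
    only).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"PPI edge list {path} has fewer than 2 columns")
    if df.empty:
        warnings.warn(f"empty PPI edge list {path}")
        return []
    if require_evidence:
        if df.shape[1] < 3:
            raise FormatError("require_evidence set but no evidence column present")
        ev = df.iloc[:, 2].fillna("").str.strip()
        df = df[ev != ""]
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key not in seen:
            seen.add(key)
            edges.append(key)
    return edges


def write_ppi_edges(edges: Iterable[Sequence[str]], path) -> None:
    pd.DataFrame(list(edges)).to_csv(path, sep="\t", index=False, header=False)
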