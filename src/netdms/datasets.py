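"""Small published example datasets bundled with the package.

These are worked-example inputs for the meta-analysis bookkeeping and the
consensus-gene summaries: published fixed-effects meta-analysis results for
21 SNPs in schizophrenia candidate module genes from three GWAS cohorts
(GAIN, MGS-nonGAIN and ISC), and the published nominal-significance margins
of a 205-gene consensus subnetwork from the same two discovery cohorts.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def load_schizophrenia_meta() -> pd.DataFrame:
    """Published meta-analysis table: 21 SNPs in schizophrenia module genes.

    Columns: snp_id, genes (comma-joined when a SNP sits in two genes'
    regions), chrom, pos, allele, p_meta, beta, se, per-cohort P values
    and the heterogeneity-test P (p_het).
    """
    with resources.files("netdms.data").joinpath("schizophrenia_meta.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def count_distinct_genes(gene_col: pd.Series) -> int:
    """Number of distinct gene symbols in a comma-joined gene column."""
    genes: set[str] = set()
    for entry in gene_col:
        genes.update(g.strip() for g in str(entry).split(","))
    return len(genes)


#: published nominal-significance margins of the 205-gene consensus set
CONSENSUS_COUNTS = {
    "n_genes": 205,
    "n_sig_gain": 139,
    "n_sig_isc": 125,
    "n_sig_both": 97,
    "n_sig_either": 167,
}


def consensus_indicator_frame(counts: dict | None = None) -> pd.DataFrame:
    """A per-gene significance table consistent with the published margins.

    Builds one row per consensus gene with gene-wise P columns for the two
    discovery cohorts (0.01 where the gene is nominally significant, 0.5
    otherwise), laid out to reproduce the published both/either counts:
    n_both genes significant in both, then the study-specific remainders.
    Feeding this to the consensus significance summary reproduces the
    published percentages from their numerators and denominators.
    """
    c = dict(CONSENSUS_COUNTS if counts is None else counts)
    n = c["n_genes"]
    n_both = c["n_sig_both"]
    only_a = c["n_sig_gain"] - n_both
    only_b = c["n_sig_isc"] - n_both
    if n_both + only_a + only_b != c["n_sig_either"]:
        raise ValueError("inconsistent significance margins")
    sig_a = np.zeros(n, dtype=bool)
    sig_b = np.zeros(n, dtype=bool)
    sig_a[:n_both] = True
    sig_b[:n_both] = True
    sig_a[n_both:n_both + only_a] = True
    sig_b[n_both + only_a:n_both + only_a + only_b] = True
    return pd.DataFrame(
        {
            "gene": [f"CG{i+1:03d}" for i in range(n)],
            "p_gain": np.where(sig_a, 0.01, 0.5),
            "p_isc": np.where(sig_b, 0.01, 0.5),
        }
    )
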