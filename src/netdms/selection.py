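"""Bi-directional module selection, consensus merging and replication.

With two GWAS datasets for the same trait, each study is used once as the
*discovery* dataset (modules are grown and assessed on its weights) and once
as the *evaluation* dataset (every discovery module's fixed gene set is
re-scored with the other study's weights).  A module survives only if it
passes the combinatorial criteria in discovery — P(Zm), P_GL, P_nSNPs,
P_topo and P_emp all below their thresholds — and both evaluation criteria,
P(Zm(eval)) and P_emp(eval).  The member genes of modules surviving either
direction are merged into a consensus subnetwork with induced interaction
edges and per-gene provenance.

Replication against a third, independent study tests whether the consensus
genes carry more nominally significant signal than expected: at the gene
level by covariate-stratified weighted resampling, and at the SNP level by
uniform resampling of equally sized SNP sets.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assessment import (
    covariate_bins,
    empirical_p,
    fit_empirical_null,
    permutation_p,
    score_p,
)
from .dms import Module
from .errors import DomainError, NetdmsError
from .network import WeightedNetwork

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the combinatorial module-selection criteria."""

    alpha_zm: float = 0.05
    alpha_gl: float = 0.05
    alpha_nsnps: float = 0.05
    alpha_topo: float = 0.05
    alpha_emp: float = 0.05
    alpha_zm_eval: float = 0.05
    alpha_emp_eval: float = 0.05

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not 0 < v < 1:
                raise DomainError(f"{name} must be in (0, 1), got {v}")


_DISCOVERY_FIELDS = {
    "p_zm": "alpha_zm",
    "p_gl": "alpha_gl",
    "p_nsnps": "alpha_nsnps",
    "p_topo": "alpha_topo",
    "p_emp": "alpha_emp",
}


def select_modules(
    assessed: pd.DataFrame, criteria: SelectionCriteria = SelectionCriteria()
) -> pd.DataFrame:
    """Keep modules with every discovery-side P strictly below its threshold."""
    for col in _DISCOVERY_FIELDS:
        if col not in assessed.columns:
            raise NetdmsError(f"assessed table lacks column {col!r}")
        if assessed[col].isna().any():
            raise NetdmsError(f"assessed table has missing values in {col!r}")
    mask = np.ones(len(assessed), dtype=bool)
    for col, alpha_name in _DISCOVERY_FIELDS.items():
        mask &= assessed[col].to_numpy() < getattr(criteria, alpha_name)
    return assessed[mask].copy()


def evaluate_in_second_study(
    modules: Sequence[Module],
    eval_net: WeightedNetwork,
    eval_perm_gene_p: pd.DataFrame | None = None,
    max_missing_fraction: float = 0.2,
    center_fraction: float = 0.9,
) -> pd.DataFrame:
    """Re-score each module's fixed gene set with the evaluation study.

    Genes absent from the evaluation network are dropped from that module's
    evaluation score with k reduced accordingly; a module whose dropped
    fraction exceeds ``max_missing_fraction`` is marked invalid and never
    selected.  P(Zm(eval)) comes from an empirical null fitted to the
    evaluation scores of *all* candidate modules (a larger, less biased
    pool than the selected ones alone); P_emp(eval) from the evaluation
    permutation matrix.
    """
    rows = []
    eval_sets: list[list[str]] = []
    for m in modules:
        present = [g for g in m.members if g in eval_net]
        frac_missing = 1 - len(present) / m.k
        valid = bool(present) and frac_missing <= max_missing_fraction
        if present:
            zm_eval = eval_net.z[[eval_net._idx(g) for g in present]].sum() / math.sqrt(
                len(present)
            )
        else:
            zm_eval = np.nan
        eval_sets.append(present)
        rows.append((m.seed, m.k, len(present), frac_missing, zm_eval, valid))
    df = pd.DataFrame(
        rows,
        columns=["seed", "k", "k_eval", "frac_missing", "zm_eval", "valid"],
    )
    valid_scores = df.loc[df["valid"], "zm_eval"]
    if len(valid_scores) < 50:
        raise NetdmsError(
            f"only {len(valid_scores)} evaluable candidate modules; "
            ">= 50 are needed to fit the evaluation-side empirical null"
        )
    fit = fit_empirical_null(valid_scores.to_numpy(), center_fraction)
    df["p_zm_eval"] = np.where(df["valid"], score_p(df["zm_eval"].to_numpy(), fit), np.nan)
    if eval_perm_gene_p is not None:
        p_emp = np.full(len(df), np.nan)
        idx = [i for i, s in enumerate(eval_sets) if df["valid"].iat[i] and s]
        if idx:
            p_emp_valid = permutation_p(
                [eval_sets[i] for i in idx], eval_perm_gene_p, eval_net
            )
            p_emp[idx] = p_emp_valid
        df["p_emp_eval"] = p_emp
    else:
        df["p_emp_eval"] = np.nan
    return df


def select_evaluated(
    evaluated: pd.DataFrame, criteria: SelectionCriteria = SelectionCriteria()
) -> pd.DataFrame:
    """Keep evaluable modules passing both evaluation-side criteria."""
    mask = (
        evaluated["valid"]
        & (evaluated["p_zm_eval"] < criteria.alpha_zm_eval)
        & (evaluated["p_emp_eval"] < criteria.alpha_emp_eval)
    )
    return evaluated[mask.fillna(False)].copy()


@dataclass
class ConsensusSubnetwork:
    """Merged gene union of modules selected in the two directions."""

    genes: list[str]
    edges: list[tuple[str, str]]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def merge_selected(
    direction_a_modules: Iterable[Module],
    direction_b_modules: Iterable[Module],
    net,
    labels: tuple[str, str] = ("forward", "reverse"),
) -> ConsensusSubnetwork:
    """Union the member genes of both directions' selected modules.

    Edges are induced from the background network (a
    :class:`~netdms.network.WeightedNetwork` or a raw edge list);
    provenance records, per gene, the direction and seed of every
    contributing module.
    """
    provenance: dict[str, list[str]] = {}
    for label, mods in zip(labels, (direction_a_modules, direction_b_modules)):
        for m in mods:
            for g in m.members:
                provenance.setdefault(g, []).append(f"{label}:{m.seed}")
    genes = sorted(provenance)
    gene_set = set(genes)
    edge_iter = net.graph.edges if isinstance(net, WeightedNetwork) else net
    edges = sorted(
        {
            (min(a, b), max(a, b))
            for a, b, *_ in edge_iter
            if a in gene_set and b in gene_set and a != b
        }
    )
    return ConsensusSubnetwork(genes=genes, edges=edges, provenance=provenance)


def consensus_significance_summary(
    gene_p: pd.DataFrame, study_cols: Sequence[str], alpha: float = 0.05
) -> dict:
    """Nominal-significance bookkeeping over a consensus gene table.

    ``gene_p`` holds one row per consensus gene and one gene-wise P column
    per study.  Returns per-study counts plus the counts and percentages of
    genes nominally significant (P < alpha) in *all* studies and in *at
    least one* study, percentages rounded to two decimals as printed.
    """
    n = len(gene_p)
    sig = pd.concat([gene_p[c] < alpha for c in study_cols], axis=1)
    n_both = int(sig.all(axis=1).sum())
    n_either = int(sig.any(axis=1).sum())
    out = {
        "n_genes": n,
        "n_all_studies": n_both,
        "n_any_study": n_either,
        "pct_all_studies": round(100 * n_both / n, 2) if n else float("nan"),
        "pct_any_study": round(100 * n_either / n, 2) if n else float("nan"),
    }
    for c in study_cols:
        label = c[2:] if c.startswith("p_") else c
        out[f"n_{label}"] = int((gene_p[c] < alpha).sum())
    return out


@dataclass(frozen=True)
class ReplicationResult:
    p: float
    observed: int
    n_used: int
    n_dropped: int
    B: int


def replicate_gene_level(
    consensus_genes: Sequence[str],
    replication_assoc: pd.DataFrame,
    covariate: str = "gene_length",
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    n_strata: int = 10,
) -> ReplicationResult:
    """Gene-level replication by covariate-stratified weighted resampling.

    The observed statistic is the number of consensus genes whose gene-wise
    P in the replication study is below ``alpha``.  The null distribution
    of that count comes from resampled gene sets matching the consensus
    set's covariate decile profile.  Within each decile the resampled count
    of significant genes is hypergeometric, so the null is simulated as a
    sum of independent per-decile hypergeometric draws — exactly the
    distribution of explicit without-replacement resampling.
    """
    col = {"gene_length": "gene_length", "n_snps": "n_snps"}[covariate]
    table = replication_assoc.dropna(subset=[col]).reset_index(drop=True)
    lut = {g: i for i, g in enumerate(table["gene"])}
    present = [g for g in consensus_genes if g in lut]
    n_dropped = len(consensus_genes) - len(present)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} consensus genes absent from the replication table"
        )
    if not present:
        raise NetdmsError("no consensus genes present in the replication study")
    sig = (table["p_gene"] < alpha).to_numpy()
    observed = int(sig[[lut[g] for g in present]].sum())
    bins = covariate_bins(table[col].to_numpy(), n_strata)
    rng = np.random.default_rng(seed)
    null = np.zeros(B, dtype=np.int64)
    for b, c in pd.Series([bins[lut[g]] for g in present]).value_counts().items():
        in_bin = bins == b
        ngood = int(sig[in_bin].sum())
        nbad = int(in_bin.sum()) - ngood
        null += rng.hypergeometric(ngood, nbad, int(c), size=B)
    count = int((null >= observed).sum())
    return ReplicationResult(
        p=empirical_p(count, B), observed=observed,
        n_used=len(present), n_dropped=n_dropped, B=B,
    )


def replicate_snp_level(
    consensus_genes: Sequence[str],
    replication_snps: pd.DataFrame,
    mapping: Mapping[str, frozenset],
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ReplicationResult:
    """SNP-level replication by uniform resampling of equal-sized SNP sets.

    Counts the nominally significant SNPs among those mapped to consensus
    genes and compares with random SNP sets of the same size drawn from all
    genotyped SNPs (the uniform draw count is hypergeometric and is
    simulated as such).
    """
    gene_set = set(consensus_genes)
    in_module = np.array(
        [bool(mapping.get(s, frozenset()) & gene_set) for s in replication_snps["snp_id"]]
    )
    m = int(in_module.sum())
    if m == 0:
        raise NetdmsError("no SNPs map to the consensus genes")
    sig = (replication_snps["p"] < alpha).to_numpy()
    observed = int((sig & in_module).sum())
    ngood = int(sig.sum())
    nbad = len(sig) - ngood
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(ngood, nbad, m, size=B)
    count = int((null >= observed).sum())
    return ReplicationResult(
        p=empirical_p(count, B), observed=observed, n_used=m, n_dropped=0, B=B
    )
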