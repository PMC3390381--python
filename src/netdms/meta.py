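"""SNP-level fixed-effects meta-analysis across GWAS studies.

Study effects are combined by inverse-variance weighting on the log-odds
scale: with w_i = 1/se_i^2,

    beta_meta = sum(w_i beta_i) / sum(w_i),    se_meta = 1/sqrt(sum(w_i)),
    z = beta_meta / se_meta,                   p_meta = 2 * (1 - Phi(|z|)).

Between-study heterogeneity is measured by Cochran's Q = sum w_i (beta_i -
beta_meta)^2 with a chi-square test on k-1 degrees of freedom, and by
I^2 = max(0, (Q - (k-1))/Q) * 100.  SNPs with significant heterogeneity
are excluded from the fixed-effects results by :func:`filter_meta`.

Genomic control is applied per study before combining: each study's
standard errors are inflated by sqrt(lambda), lambda its genomic inflation
factor.  Only SNPs genotyped in every study are combined (no imputation),
after per-SNP allele alignment to the first study's orientation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .assessment import empirical_p
from .errors import DomainError, NetdmsError

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class StudyEffect:
    study: str
    beta: float
    se: float
    lam: float = 1.0

    def __post_init__(self):
        if not self.se > 0:
            raise DomainError(f"se must be positive, got {self.se}")
        if not self.lam > 0:
            raise DomainError(f"lambda must be positive, got {self.lam}")
        if self.lam < 1:
            warnings.warn(f"study {self.study}: lambda {self.lam} < 1 (deflation)")


@dataclass(frozen=True)
class MetaResult:
    snp_id: str
    k_studies: int
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    Q: float
    I2: float
    p_het: float


def gc_adjust(effect: StudyEffect) -> StudyEffect:
    """Genomic-control adjustment: se <- se * sqrt(lambda), beta unchanged."""
    return replace(effect, se=effect.se * math.sqrt(effect.lam), lam=1.0)


def fixed_effects_meta(
    effects: Sequence[StudyEffect], snp_id: str = ""
) -> MetaResult:
    """Inverse-variance fixed-effects combination of pre-aligned effects."""
    if not effects:
        raise NetdmsError("fixed_effects_meta needs at least one study effect")
    beta = np.array([e.beta for e in effects])
    se = np.array([e.se for e in effects])
    w = 1.0 / se**2
    beta_meta = float((w * beta).sum() / w.sum())
    se_meta = float(1.0 / math.sqrt(w.sum()))
    z = beta_meta / se_meta
    p_meta = float(2 * norm.sf(abs(z)))
    k = len(effects)
    Q = float((w * (beta - beta_meta) ** 2).sum())
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100 if Q > 0 else 0.0
    p_het = float(chi2.sf(Q, k - 1)) if k > 1 else 1.0
    return MetaResult(
        snp_id=snp_id, k_studies=k, beta_meta=beta_meta, se_meta=se_meta,
        z_meta=z, p_meta=p_meta, Q=Q, I2=I2, p_het=p_het,
    )


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    return frozenset((str(ref).upper(), str(alt).upper())) in _AMBIGUOUS


def align_alleles(rows: pd.DataFrame) -> pd.DataFrame:
    """Align per-study rows for one SNP to the first row's allele orientation.

    The consensus orientation is the first study's (ref, alt).  A study's
    effect is kept as-is when its alleles match, sign-flipped when they are
    swapped, and likewise after strand complementation.  Strand-ambiguous
    (A/T, C/G) SNPs are flagged; rows whose alleles cannot be reconciled are
    dropped with a warning.  Returns the rows with aligned ``beta`` and an
    ``ambiguous`` column.
    """
    ref0 = str(rows["allele_ref"].iloc[0]).upper()
    alt0 = str(rows["allele_alt"].iloc[0]).upper()
    out = rows.copy()
    out["ambiguous"] = is_strand_ambiguous(ref0, alt0)
    keep = np.ones(len(out), dtype=bool)
    betas = out["beta"].to_numpy(dtype=float, copy=True)
    for i in range(len(out)):
        r = str(out["allele_ref"].iloc[i]).upper()
        a = str(out["allele_alt"].iloc[i]).upper()
        rc, ac = _COMPLEMENT.get(r), _COMPLEMENT.get(a)
        if (r, a) == (ref0, alt0) or (rc, ac) == (ref0, alt0):
            continue
        if (a, r) == (ref0, alt0) or (ac, rc) == (ref0, alt0):
            betas[i] = -betas[i]
        else:
            keep[i] = False
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(
            f"{n_drop} study rows with irreconcilable alleles dropped for "
            f"SNP {rows['snp_id'].iloc[0]!r}"
        )
    out["beta"] = betas
    return out[keep]


def meta_table(
    study_tables: Sequence[pd.DataFrame],
    lambdas: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
    strict_ambiguous: bool = False,
) -> pd.DataFrame:
    """Meta-analyse the SNP intersection of two or more study tables.

    Each table needs snp_id, beta, se (and alleles for alignment; when any
    table lacks allele columns, effects are assumed pre-aligned).  SNPs
    absent from any study are excluded — genotyped markers only, no
    imputation.  Returns one row per shared SNP with the combined effect,
    heterogeneity statistics and per-study P values.
    """
    if len(study_tables) < 2:
        raise NetdmsError("meta_table needs at least two study tables")
    k = len(study_tables)
    lambdas = list(lambdas) if lambdas is not None else [1.0] * k
    labels = list(labels) if labels is not None else [f"study{i+1}" for i in range(k)]
    if len(lambdas) != k or len(labels) != k:
        raise NetdmsError("lambdas/labels must match the number of studies")

    have_alleles = all(
        {"allele_ref", "allele_alt"} <= set(t.columns)
        and t["allele_ref"].notna().all()
        for t in study_tables
    )
    shared = None
    for t in study_tables:
        if t["beta"].isna().any() or t["se"].isna().any():
            raise NetdmsError("meta-analysis requires beta and se in every table")
        s = set(t["snp_id"])
        shared = s if shared is None else shared & s
    if not shared:
        raise NetdmsError("no SNPs shared across all studies")
    order = [s for s in study_tables[0]["snp_id"] if s in shared]

    frames = []
    for i, t in enumerate(study_tables):
        sub = t.set_index("snp_id").loc[order].copy()
        sub["se"] = sub["se"] * math.sqrt(lambdas[i])
        frames.append(sub)

    beta = np.column_stack([f["beta"].to_numpy(dtype=float) for f in frames])
    se = np.column_stack([f["se"].to_numpy(dtype=float) for f in frames])
    ambiguous = np.zeros(len(order), dtype=bool)
    dropped_snps: list[str] = []
    if have_alleles:
        ref = np.column_stack(
            [f["allele_ref"].astype(str).str.upper().to_numpy() for f in frames]
        )
        alt = np.column_stack(
            [f["allele_alt"].astype(str).str.upper().to_numpy() for f in frames]
        )
        comp = np.vectorize(lambda x: _COMPLEMENT.get(x, "?"))
        ref_c, alt_c = comp(ref), comp(alt)
        same = (ref == ref[:, :1]) & (alt == alt[:, :1])
        same |= (ref_c == ref[:, :1]) & (alt_c == alt[:, :1])
        swapped = (alt == ref[:, :1]) & (ref == alt[:, :1])
        swapped |= (alt_c == ref[:, :1]) & (ref_c == alt[:, :1])
        beta = np.where(swapped & ~same, -beta, beta)
        bad = ~(same | swapped)
        ambiguous = np.array(
            [is_strand_ambiguous(r, a) for r, a in zip(ref[:, 0], alt[:, 0])]
        )
        unresolved = bad.any(axis=1)
        if unresolved.any():
            dropped_snps = [s for s, u in zip(order, unresolved) if u]
            warnings.warn(
                f"{len(dropped_snps)} SNPs dropped with irreconcilable alleles"
            )
        keep = ~unresolved
        if strict_ambiguous:
            keep &= ~ambiguous
        beta, se = beta[keep], se[keep]
        ambiguous = ambiguous[keep]
        order = [s for s, kp in zip(order, keep) if kp]

    w = 1.0 / se**2
    beta_meta = (w * beta).sum(axis=1) / w.sum(axis=1)
    se_meta = 1.0 / np.sqrt(w.sum(axis=1))
    z = beta_meta / se_meta
    p_meta = 2 * norm.sf(np.abs(z))
    Q = (w * (beta - beta_meta[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        I2 = np.where(Q > 0, np.maximum(0.0, (Q - (k - 1)) / Q) * 100, 0.0)
    p_het = chi2.sf(Q, k - 1)

    out = pd.DataFrame(
        {
            "snp_id": order,
            "k_studies": k,
            "beta_meta": beta_meta,
            "se_meta": se_meta,
            "z_meta": z,
            "p_meta": p_meta,
            "Q": Q,
            "I2": I2,
            "p_het": p_het,
            "ambiguous": ambiguous,
        }
    )
    snp0 = study_tables[0].set_index("snp_id")
    for col in ("chrom", "pos"):
        if col in snp0.columns:
            out[col] = snp0.loc[order, col].to_numpy()
    for lab, t in zip(labels, study_tables):
        if "p" in t.columns:
            out[f"p_{lab}"] = t.set_index("snp_id").loc[order, "p"].to_numpy()
    return out


def filter_meta(
    results: pd.DataFrame, p_max: float = 1e-4, het_min: float = 0.05
) -> pd.DataFrame:
    """Keep SNPs with p_meta < p_max and no substantial heterogeneity
    (p_het >= het_min)."""
    mask = (results["p_meta"] < p_max) & (results["p_het"] >= het_min)
    return results[mask].copy()


@dataclass(frozen=True)
class SetEnrichmentResult:
    p: float
    observed: int
    set_size: int
    universe_size: int
    B: int


def meta_set_enrichment(
    results: pd.DataFrame,
    module_snp_ids: Sequence[str],
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SetEnrichmentResult:
    """Test whether a SNP set is enriched for meta-analysis signal.

    The observed statistic k is the number of module SNPs with
    p_meta < alpha; each resample draws an equally sized SNP set uniformly
    from the result universe and counts its significant SNPs K (a
    hypergeometric count, simulated as such); P = (1 + #{K >= k})/(B + 1).
    """
    universe = set(results["snp_id"])
    module = set(module_snp_ids)
    if not module <= universe:
        raise NetdmsError(
            f"{len(module - universe)} module SNPs absent from the meta results"
        )
    if len(module) > len(universe):
        raise NetdmsError("module SNP set larger than the universe")
    sig = (results["p_meta"] < alpha).to_numpy()
    in_module = results["snp_id"].isin(module).to_numpy()
    observed = int((sig & in_module).sum())
    ngood = int(sig.sum())
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(ngood, len(universe) - ngood, len(module), size=B)
    count = int((null >= observed).sum())
    return SetEnrichmentResult(
        p=empirical_p(count, B), observed=observed,
        set_size=len(module), universe_size=len(universe), B=B,
    )
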