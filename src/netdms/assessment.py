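"""Multi-layered significance assessment of candidate modules.

Four complementary P values are attached to every module:

``P(Zm)``
    A parametric P from an *empirical null*: module scores are
    median-centered and a normal null N(delta, sigma^2) is fitted to the
    central bulk of the centered scores by central matching (a quadratic
    fit to the central log-density, in the spirit of Efron's empirical-null
    estimation).  Standardised scores Z_S = (Zm - median - delta)/sigma are
    converted by P = 1 - Phi(Z_S), which preserves the score ranking
    exactly.

``P_GL`` and ``P_nSNPs``
    Weighted-resampling P values that absorb the gene-length / SNP-density
    confounding of min-P gene summaries: network genes are binned into
    deciles of the covariate and each resample draws, without replacement,
    the same number of genes from each decile as the observed module has
    there, so every resample mimics the module's covariate profile.

``P_topo``
    Topology-matched randomization that absorbs hub bias: nodes are binned
    by degree into [0,4], (4,16], (16,64], (64,inf) and resamples match the
    module's per-bin composition.

``P_emp``
    Phenotype-permutation P: the fixed member set is re-scored under each
    column of a gene x permutation matrix of null gene-wise P values
    (produced upstream by case/control label shuffling, or by the synthetic
    generator), and compared with the observed score.

All empirical P values use the +1-corrected estimator
P = (1 + #{null >= observed}) / (B + 1); ties count toward the exceedance
(both choices configurable).  Resamples for a batch of modules share one
stratified pool per covariate, which makes the P values monotone in the
observed score across modules and keeps the cost independent of the number
of modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dms import Module
from .errors import DegenerateDistributionError, DomainError, MembershipError, NetdmsError
from .network import WeightedNetwork, z_weight

DEGREE_BIN_EDGES = (4, 16, 64)  # [0,4], (4,16], (16,64], (64,inf)


# ---------------------------------------------------------------------------
# empirical null


@dataclass(frozen=True)
class NullFit:
    """Empirical null N(delta, sigma^2) on the median-centered score scale."""

    delta: float
    sigma: float
    n_scores: int
    median: float
    center_fraction: float = 0.9


def fit_empirical_null(
    scores: Sequence[float], center_fraction: float = 0.9, n_bins: int | None = None
) -> NullFit:
    """Fit the empirical null to a collection of module scores.

    Scores are median-centered and (delta, sigma) are estimated by central
    matching: a quadratic is fitted to the log-histogram of the centered
    scores over the central ``center_fraction`` quantile window (count-
    weighted least squares, the Poisson-regression approximation).  For a
    normal bulk, log f(x) = a + bx + cx^2 with c = -1/(2 sigma^2) and
    delta = -b/(2c), so the bulk alone determines the null and signal
    modules in the upper tail do not inflate it.  Requires at least 50
    scores and a non-degenerate spread.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 50:
        raise NetdmsError(f"need >= 50 scores to fit the empirical null, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDistributionError("all module scores are identical")
    if not 0 < center_fraction <= 1:
        raise DomainError("center_fraction must be in (0, 1]")
    med = float(np.median(x))
    c = x - med
    lo_q = (1 - center_fraction) / 2
    a, b = np.quantile(c, [lo_q, 1 - lo_q])
    if b <= a:
        raise DegenerateDistributionError("central window of scores is constant")
    if n_bins is None:
        n_bins = int(np.clip(len(x) // 70, 11, 71))

    def _quadratic(frac: float):
        lo = (1 - frac) / 2
        wa, wb = np.quantile(c, [lo, 1 - lo])
        if wb <= wa:
            return None
        edges = np.linspace(wa, wb, n_bins + 1)
        counts, _ = np.histogram(c, bins=edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        if keep.sum() < 5:
            return None
        design = np.column_stack([np.ones(keep.sum()), mids[keep], mids[keep] ** 2])
        w = np.sqrt(counts[keep])
        coef, *_ = np.linalg.lstsq(
            design * w[:, None], np.log(counts[keep]) * w, rcond=None
        )
        if coef[2] >= 0:
            return None
        return -coef[1] / (2.0 * coef[2]), math.sqrt(-1.0 / (2.0 * coef[2]))

    fitted = None
    for frac in (center_fraction, 0.7 * center_fraction, 0.5 * center_fraction):
        fitted = _quadratic(frac)
        if fitted is not None:
            break
    if fitted is None:
        # multimodal or heavily skewed score landscape: fall back to a
        # robust quantile null (delta 0, sigma from the interquartile range)
        import warnings

        q1, q3 = np.quantile(c, [0.25, 0.75])
        if q3 <= q1:
            raise DegenerateDistributionError("central window of scores is constant")
        warnings.warn(
            "central log-density is not concave; falling back to the "
            "interquartile-range null estimate"
        )
        fitted = (0.0, (q3 - q1) / 1.349)
    delta, sigma = fitted
    return NullFit(
        delta=float(delta),
        sigma=float(sigma),
        n_scores=len(x),
        median=med,
        center_fraction=center_fraction,
    )


def score_p(scores: Sequence[float], fit: NullFit) -> np.ndarray:
    """Convert scores to P(Zm) = 1 - Phi((score - median - delta)/sigma).

    A strictly decreasing transform of the score, so the P ranking is the
    exact reverse of the score ranking (Spearman correlation -1).
    """
    zs = (np.asarray(scores, dtype=float) - fit.median - fit.delta) / fit.sigma
    return norm.sf(zs)


# ---------------------------------------------------------------------------
# stratified resampling machinery


def empirical_p(count: int, B: int, plus_one: bool = True) -> float:
    """+1-corrected empirical P from an exceedance count over B resamples."""
    if plus_one:
        return (1 + count) / (B + 1)
    return count / B


def _members(module) -> list[str]:
    if isinstance(module, Module):
        return list(module.members)
    return list(module)


def covariate_bins(values: np.ndarray, n_strata: int = 10) -> np.ndarray:
    """Decile (or coarser, under heavy ties) bin codes for a covariate."""
    codes = pd.qcut(values, q=n_strata, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=np.int64)


def degree_bins(degree: np.ndarray) -> np.ndarray:
    """Degree bin codes with lower-inclusive powers-of-two edges."""
    return np.digitize(degree, DEGREE_BIN_EDGES, right=True).astype(np.int64)


class StratifiedPool:
    """Shared resampling pool: per bin, B without-replacement ordered draws.

    For bin b the pool holds a (B, kmax_b) matrix of cumulative sums of the
    statistic over a uniformly random kmax_b-subset of the bin, ordered so
    that the first c entries of each row are themselves a uniform c-subset.
    The null statistic of a module that occupies bin b with count c is then
    the sum over bins of column c-1, at O(B) per module.
    """

    def __init__(
        self,
        values: np.ndarray,
        bin_ids: np.ndarray,
        need: Mapping[int, int],
        B: int,
        rng: np.random.Generator,
    ):
        self.B = B
        self._cums: dict[int, np.ndarray] = {}
        self.bin_sizes: dict[int, int] = {}
        for b in sorted(need):
            kmax = need[b]
            idx = np.flatnonzero(bin_ids == b)
            self.bin_sizes[b] = len(idx)
            if kmax > len(idx):
                raise NetdmsError(
                    f"stratum {b} holds {len(idx)} genes but {kmax} are required"
                )
            if kmax == 0:
                continue
            keys = rng.random((B, len(idx)))
            order = np.argsort(keys, axis=1)[:, :kmax]
            self._cums[b] = np.cumsum(values[idx][order], axis=1)

    def null_sums(self, counts: Mapping[int, int]) -> np.ndarray:
        """B null sums for a module with the given per-bin counts."""
        total = np.zeros(self.B)
        for b, c in counts.items():
            if c > 0:
                total += self._cums[b][:, c - 1]
        return total


def _bin_counts(bin_ids: np.ndarray, member_idx: Sequence[int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for i in member_idx:
        out[bin_ids[i]] = out.get(bin_ids[i], 0) + 1
    return out


def _stratified_p(
    net: WeightedNetwork,
    member_lists: list[list[str]],
    bin_ids: np.ndarray,
    B: int,
    rng: np.random.Generator,
    tie: str = "ge",
    plus_one: bool = True,
) -> np.ndarray:
    """Shared-pool stratified resampling P for a batch of modules."""
    idx_lists = [[net._idx(g) for g in m] for m in member_lists]
    counts_list = [_bin_counts(bin_ids, idx) for idx in idx_lists]
    need: dict[int, int] = {}
    for counts in counts_list:
        for b, c in counts.items():
            need[b] = max(need.get(b, 0), c)
    pool = StratifiedPool(net.z, bin_ids, need, B, rng)
    out = np.empty(len(member_lists))
    for j, (idx, counts) in enumerate(zip(idx_lists, counts_list)):
        k = len(idx)
        obs = net.z[idx].sum() / math.sqrt(k)
        null = pool.null_sums(counts) / math.sqrt(k)
        count = int((null >= obs).sum() if tie == "ge" else (null > obs).sum())
        out[j] = empirical_p(count, B, plus_one)
    return out


def _covariate_values(
    net: WeightedNetwork, gene_assoc: pd.DataFrame, covariate: str,
    member_lists: list[list[str]],
) -> np.ndarray:
    col = {"gene_length": "gene_length", "n_snps": "n_snps"}.get(covariate)
    if col is None:
        raise DomainError(f"unknown covariate {covariate!r}")
    lut = dict(zip(gene_assoc["gene"], gene_assoc[col]))
    vals = np.array([lut.get(g, np.nan) for g in net.nodes], dtype=float)
    for members in member_lists:
        for g in members:
            if not np.isfinite(vals[net._idx(g)]):
                raise MembershipError(
                    f"module gene {g!r} lacks covariate {covariate!r}"
                )
    if np.isnan(vals).any():
        # non-module genes without the covariate cannot enter the resampling
        # universe; park them in a separate stratum that no module occupies
        vals = np.where(np.isnan(vals), -np.inf, vals)
    return vals


def weighted_resample_p(
    module,
    net: WeightedNetwork,
    gene_assoc: pd.DataFrame,
    covariate: str = "gene_length",
    B: int = 1000,
    seed: int | None = None,
    n_strata: int = 10,
    tie: str = "ge",
    plus_one: bool = True,
) -> float:
    """Bias-matched resampling P for one module (covariate deciles)."""
    if B < 100:
        raise DomainError(f"B must be >= 100, got {B}")
    members = _members(module)
    vals = _covariate_values(net, gene_assoc, covariate, [members])
    bins = covariate_bins(vals, n_strata)
    rng = np.random.default_rng(seed)
    return float(_stratified_p(net, [members], bins, B, rng, tie, plus_one)[0])


def batch_weighted_resample_p(
    member_lists,
    net: WeightedNetwork,
    gene_assoc: pd.DataFrame,
    covariate: str = "gene_length",
    B: int = 1000,
    seed: int | None = None,
    n_strata: int = 10,
    tie: str = "ge",
    plus_one: bool = True,
) -> np.ndarray:
    """Bias-matched resampling P for a batch of gene sets (shared pool)."""
    member_lists = [_members(m) for m in member_lists]
    vals = _covariate_values(net, gene_assoc, covariate, member_lists)
    bins = covariate_bins(vals, n_strata)
    rng = np.random.default_rng(seed)
    return _stratified_p(net, member_lists, bins, B, rng, tie, plus_one)


def batch_topology_matched_p(
    member_lists,
    net: WeightedNetwork,
    B: int = 1000,
    seed: int | None = None,
    tie: str = "ge",
    plus_one: bool = True,
) -> np.ndarray:
    """Degree-matched randomization P for a batch of gene sets (shared pool)."""
    member_lists = [_members(m) for m in member_lists]
    rng = np.random.default_rng(seed)
    return _stratified_p(
        net, member_lists, degree_bins(net.degree), B, rng, tie, plus_one
    )


def topology_matched_p(
    module,
    net: WeightedNetwork,
    B: int = 1000,
    seed: int | None = None,
    tie: str = "ge",
    plus_one: bool = True,
) -> float:
    """Degree-bin-matched randomization P for one module."""
    members = _members(module)
    bins = degree_bins(net.degree)
    rng = np.random.default_rng(seed)
    return float(_stratified_p(net, [members], bins, B, rng, tie, plus_one)[0])


def permutation_p(
    modules,
    perm_gene_p: pd.DataFrame,
    observed_net: WeightedNetwork,
    tie: str = "ge",
    plus_one: bool = True,
    clamp_eps: float = 1e-15,
) -> np.ndarray:
    """Phenotype-permutation P for each module.

    ``perm_gene_p`` is a gene x permutation matrix of null gene-wise P
    values; each module's fixed member set is re-scored under every
    permutation column and compared with its observed score.
    """
    single = isinstance(modules, Module) or (
        modules and isinstance(next(iter(modules)), str)
    )
    member_lists = [_members(modules)] if single else [_members(m) for m in modules]
    B = perm_gene_p.shape[1]
    gene_pos = {g: i for i, g in enumerate(perm_gene_p.index)}
    perm_z = z_weight(perm_gene_p.to_numpy(), clamp_eps)
    out = np.empty(len(member_lists))
    for j, members in enumerate(member_lists):
        rows = []
        for g in members:
            if g not in gene_pos:
                raise MembershipError(f"permutation matrix lacks gene {g!r}")
            rows.append(gene_pos[g])
        k = len(rows)
        obs = observed_net.z[[observed_net._idx(g) for g in members]].sum() / math.sqrt(k)
        null = perm_z[rows].sum(axis=0) / math.sqrt(k)
        count = int((null >= obs).sum() if tie == "ge" else (null > obs).sum())
        out[j] = empirical_p(count, B, plus_one)
    return float(out[0]) if single else out


def assess_all(
    modules: list[Module],
    net: WeightedNetwork,
    gene_assoc: pd.DataFrame,
    perm_gene_p: pd.DataFrame | None = None,
    B: int = 1000,
    seed: int | None = None,
    n_strata: int = 10,
    center_fraction: float = 0.9,
    tie: str = "ge",
    plus_one: bool = True,
) -> pd.DataFrame:
    """Apply all assessment procedures to a batch of modules.

    Returns one row per module: seed, k, zm, p_zm, p_gl, p_nsnps, p_topo,
    p_emp.  Deterministic under a fixed seed, and per-module results do not
    depend on the order of the input list (resampling pools are generated
    from the network alone).
    """
    member_lists = [list(m.members) for m in modules]
    scores = np.array([m.zm for m in modules])
    fit = fit_empirical_null(scores, center_fraction)
    p_zm = score_p(scores, fit)

    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    p_cov = {}
    for sub, covariate in zip(seeds[:2], ("gene_length", "n_snps")):
        vals = _covariate_values(net, gene_assoc, covariate, member_lists)
        bins = covariate_bins(vals, n_strata)
        rng = np.random.default_rng(sub)
        p_cov[covariate] = _stratified_p(
            net, member_lists, bins, B, rng, tie, plus_one
        )
    rng = np.random.default_rng(seeds[2])
    p_topo = _stratified_p(
        net, member_lists, degree_bins(net.degree), B, rng, tie, plus_one
    )
    if perm_gene_p is not None:
        p_emp = permutation_p(modules, perm_gene_p, net, tie, plus_one)
    else:
        p_emp = np.full(len(modules), np.nan)

    return pd.DataFrame(
        {
            "seed": [m.seed for m in modules],
            "members": [";".join(m.members) for m in modules],
            "k": [m.k for m in modules],
            "zm": scores,
            "p_zm": p_zm,
            "p_gl": p_cov["gene_length"],
            "p_nsnps": p_cov["n_snps"],
            "p_topo": p_topo,
            "p_emp": p_emp,
        }
    )
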