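"""Gene-set over-representation analysis of consensus genes.

Over-representation of a query gene list in a gene set is tested with the
upper-tail hypergeometric probability

    P = sum_{i=x}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n)

with N the universe size (genes present in the weighted network by
default), K the set size within the universe, n the query size and x the
overlap.  Raw P values are corrected by Bonferroni and Benjamini-Hochberg;
an additional empirical layer resamples random query-sized gene sets from
the universe and reports, per set, the fraction of resamples in which the
set reaches significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .assessment import empirical_p
from .errors import DomainError, FormatError

DEFAULT_SIZE_RANGE = (10, 250)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with < 3 fields")
            sets.append(
                GeneSet(fields[0], fields[1], frozenset(g for g in fields[2:] if g))
            )
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def hypergeometric_p(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric P of observing >= x overlap."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= min(K, n)):
        raise DomainError(
            f"inconsistent counts N={N}, K={K}, n={n}, x={x}"
        )
    return float(hypergeom.sf(x - 1, N, K, n))


def adjust(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni' or 'BH' (step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p values must lie in (0, 1]")
    key = {"bonferroni": "bonferroni", "BH": "fdr_bh", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise DomainError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def empirical_set_p(
    gene_set: frozenset | set,
    query_size: int,
    universe_genes: Sequence[str],
    threshold: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
) -> float:
    """Empirical significance of one gene set over random queries.

    Draws B random query-sized gene sets uniformly from the universe, tests
    the set against each (hypergeometric, raw threshold) and returns
    P = (1 + #significant resamples)/(B + 1).  The random overlap is
    hypergeometric and is simulated as such.
    """
    universe = list(dict.fromkeys(universe_genes))
    N = len(universe)
    if query_size > N:
        raise DomainError("query_size exceeds the universe")
    K = len(set(gene_set) & set(universe))
    rng = np.random.default_rng(seed)
    overlaps = rng.hypergeometric(K, N - K, query_size, size=B) if K else np.zeros(B)
    p_rand = hypergeom.sf(overlaps - 1, N, K, query_size)
    count = int((p_rand < threshold).sum())
    return empirical_p(count, B)


def enrich(
    query_genes: Sequence[str],
    gene_sets: Sequence[GeneSet],
    universe_genes: Sequence[str],
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    B: int = 1000,
    empirical_threshold: float = 0.05,
    empirical_adjust: str = "bonferroni",
    seed: int | None = None,
) -> pd.DataFrame:
    """Full over-representation pipeline for a query gene list.

    Sets are restricted to the universe and filtered to ``size_range``.
    The empirical layer shares one batch of B random query sets across all
    sets; within each resample significance is judged on the
    ``empirical_adjust``-corrected P at ``empirical_threshold``.
    Returns a table sorted by BH-adjusted P.
    """
    universe = list(dict.fromkeys(universe_genes))
    uni_set = set(universe)
    N = len(universe)
    query = [g for g in dict.fromkeys(query_genes) if g in uni_set]
    n = len(query)
    if n == 0:
        raise DomainError("no query genes present in the universe")

    kept = []
    for s in gene_sets:
        members = s.genes & uni_set
        if size_range[0] <= len(members) <= size_range[1]:
            kept.append((s, members))
    if not kept:
        return pd.DataFrame(
            columns=["set_name", "set_size", "overlap", "p_hyper",
                     "p_bonferroni", "p_bh", "p_empirical"]
        )

    qset = set(query)
    rows = []
    for s, members in kept:
        x = len(members & qset)
        rows.append((s.name, len(members), x, hypergeometric_p(N, len(members), n, x)))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_hyper"])
    df["p_bonferroni"] = adjust(df["p_hyper"], "bonferroni")
    df["p_bh"] = adjust(df["p_hyper"], "BH")

    # shared empirical layer: B random query-sized draws from the universe
    rng = np.random.default_rng(seed)
    gene_idx = {g: i for i, g in enumerate(universe)}
    draws = np.empty((B, n), dtype=np.int64)
    for b in range(B):
        draws[b] = rng.choice(N, size=n, replace=False)
    m = len(kept)
    p_emp = np.empty(m)
    member_mask = np.zeros((m, N), dtype=bool)
    for j, (_, members) in enumerate(kept):
        member_mask[j, [gene_idx[g] for g in members]] = True
    for j in range(m):
        overlaps = member_mask[j][draws].sum(axis=1)
        p_rand = hypergeom.sf(overlaps - 1, N, int(member_mask[j].sum()), n)
        if empirical_adjust == "bonferroni":
            p_rand = np.minimum(1.0, p_rand * m)
        count = int((p_rand < empirical_threshold).sum())
        p_emp[j] = empirical_p(count, B)
    df["p_empirical"] = p_emp
    return df.sort_values("p_bh", kind="stable").reset_index(drop=True)
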