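"""Synthetic GWAS + interaction-network generator with known ground truth.

Every downstream operation of the package can be exercised without any
external download: the generator emits a scale-free interaction network, a
gene annotation table, per-study SNP association tables, phenotype-
permutation gene-wise P matrices and GMT gene-set collections, in exactly
the dialects the I/O layer reads.

What it emulates
    * scale-free topology by preferential attachment (the real human
      interactome used in this kind of analysis has ~10^4 nodes and
      ~5x10^4 experimentally supported interactions; the "paper-scale"
      preset reproduces that order of magnitude);
    * gene lengths log-normal, SNP counts Poisson in gene length, so the
      min-P gene summary inherits the usual gene-length / SNP-density
      confounding that the weighted resampling must absorb;
    * a planted connected module of high-signal genes shared across a
      configurable fraction of 2-3 correlated "studies";
    * effects injected at the SNP level on the log-odds scale with
      se ~ 1/sqrt(2 N maf (1-maf)), maf ~ Uniform(0.05, 0.5), echoing the
      usual MAF >= 0.05 genotyping filter, so emitted beta, se and P are
      mutually consistent (z = beta/se).

What it does not emulate: linkage disequilibrium (SNPs within a gene are
independent), population stratification, and genotyping error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .errors import DomainError, NetdmsError

_AUTOSOMES = [str(c) for c in range(1, 23)]
_INTERGENIC_GAP = 50_000  # > default mapping flank, keeps SNP->gene 1:1
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic experiment."""

    n_genes: int = 1000
    topology: str = "scale-free"
    attachment: int = 2           # edges per new node (preferential attachment)
    planted_size: int = 10        # genes in the planted module
    planted_effect: float = 3.0   # mean shift of SNP z-scores in planted genes
    n_studies: int = 2
    shared_fraction: float = 1.0  # fraction of studies carrying the signal
    length_log_mean: float = math.log(20_000)
    length_log_sigma: float = 1.0
    snps_per_kb: float = 0.5
    n_samples: int = 2500         # cases + controls per study
    n_bridges: int = 1            # bridges tying the complex to the background
    tether_len: int = 2           # null adapter genes along each bridge
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise DomainError("n_genes must be >= 10")
        if not 0 <= self.shared_fraction <= 1:
            raise DomainError("shared_fraction must lie in [0, 1]")
        if self.planted_size > self.n_genes:
            raise DomainError("planted module larger than the gene universe")
        if self.attachment >= self.n_genes or self.attachment < 1:
            raise DomainError("infeasible attachment parameter")


PRESETS: dict[str, SimulationSpec] = {
    "toy": SimulationSpec(
        n_genes=50, attachment=2, planted_size=5, n_permutations=200, seed=0
    ),
    "default": SimulationSpec(),
    "paper-scale": SimulationSpec(n_genes=10_377, attachment=5),
}


@dataclass
class SyntheticStudy:
    """A complete synthetic experiment with ground truth."""

    spec: SimulationSpec
    edges: list[tuple[str, str]]
    annotation: pd.DataFrame           # gene, chrom, start, end, length, n_snps
    studies: list[pd.DataFrame]        # per-study SNP association tables
    truth: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.annotation["gene"])


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def planted_gene_names(spec: SimulationSpec) -> list[str]:
    """The gene symbols reserved for the planted module (the last ones)."""
    return _gene_names(spec.n_genes)[spec.n_genes - spec.planted_size:]


def _adapter_gene_names(spec: SimulationSpec) -> list[str]:
    n_adapt = spec.tether_len * spec.n_bridges
    lo = spec.n_genes - spec.planted_size - n_adapt
    return _gene_names(spec.n_genes)[lo:spec.n_genes - spec.planted_size]


def expected_edge_count(spec: SimulationSpec) -> int:
    """Closed-form edge count of the scale-free construction.

    The background preferential-attachment graph contributes m(n_bg - m)
    edges with n_bg the background size; the planted k-gene complex is
    wired as a double ring (2k edges for k >= 5, a clique below) and each
    bridge adds tether_len + 1 edges along its adapter path.
    """
    n, m, k = spec.n_genes, spec.attachment, spec.planted_size
    n_bg = n - k - spec.tether_len * spec.n_bridges
    cluster = 2 * k if k >= 5 else k * (k - 1) // 2
    return m * (n_bg - m) + cluster + spec.n_bridges * (spec.tether_len + 1)


def simulate_network(spec: SimulationSpec) -> list[tuple[str, str]]:
    """Scale-free gene network with a peripherally attached planted complex.

    The background is a preferential-attachment (Barabasi-Albert) graph on
    n - k genes.  The k planted genes form a separate densely wired
    cluster (a double ring: each gene linked to its two nearest and two
    second-nearest neighbours) that is attached to the background through
    ``n_bridges`` bridge edges anchored at low-degree background genes —
    emulating a disease-associated protein complex sitting at the
    periphery of the interactome rather than on its hubs.  Deterministic
    under the SimulationSpec seed.
    """
    rng = _rng(spec, 0)
    names = _gene_names(spec.n_genes)
    k = spec.planted_size
    n_adapt = spec.tether_len * spec.n_bridges
    n_bg = spec.n_genes - k - n_adapt
    seed = int(rng.integers(2**31 - 1))
    if spec.topology == "scale-free":
        g = nx.barabasi_albert_graph(n_bg, spec.attachment, seed=seed)
    elif spec.topology == "small-world":
        g = nx.connected_watts_strogatz_graph(
            n_bg, max(2, 2 * spec.attachment), 0.1, seed=seed
        )
    else:
        raise DomainError(f"unknown topology {spec.topology!r}")
    edges = {(a, b) if a < b else (b, a) for a, b in g.edges}
    # planted complex: double ring over the reserved gene indices
    adapter_idx = list(range(n_bg, n_bg + n_adapt))
    planted_idx = list(range(n_bg + n_adapt, spec.n_genes))
    if k >= 5:
        for step in (1, 2):
            for i in range(k):
                a = planted_idx[i]
                b = planted_idx[(i + step) % k]
                edges.add((a, b) if a < b else (b, a))
    else:
        for i in range(k):
            for j in range(i + 1, k):
                edges.add((planted_idx[i], planted_idx[j]))
    # tether the complex to peripheral low-degree background genes through
    # a path of adapter genes, keeping the complex outside the d = 2
    # horizon of the background
    degrees = np.array([g.degree[i] for i in range(n_bg)])
    hub = int(np.argmax(degrees))
    dist = nx.single_source_shortest_path_length(g, hub)
    dvec = np.array([dist.get(i, 0) for i in range(n_bg)])
    far = np.flatnonzero((degrees <= np.median(degrees)) & (dvec >= np.quantile(dvec, 0.9)))
    anchors = rng.choice(far, size=spec.n_bridges, replace=False)
    for j, anchor in enumerate(anchors):
        path = (
            [int(anchor)]
            + adapter_idx[j * spec.tether_len:(j + 1) * spec.tether_len]
            + [planted_idx[j % k]]
        )
        for a, b in zip(path, path[1:]):
            edges.add((a, b) if a < b else (b, a))
    return sorted(
        (names[a], names[b]) if names[a] < names[b] else (names[b], names[a])
        for a, b in edges
    )


def _simulate_annotation(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    names = _gene_names(spec.n_genes)
    lengths = np.exp(
        rng.normal(spec.length_log_mean, spec.length_log_sigma, spec.n_genes)
    )
    lengths = np.clip(lengths, 1_000, 2_000_000).astype(np.int64)
    n_snps = rng.poisson(lengths / 1000 * spec.snps_per_kb)
    n_snps = np.maximum(1, n_snps)
    chroms, starts, ends = [], [], []
    cursor = {c: 1 for c in _AUTOSOMES}
    for i in range(spec.n_genes):
        c = _AUTOSOMES[i % len(_AUTOSOMES)]
        start = cursor[c]
        end = start + int(lengths[i]) - 1
        cursor[c] = end + 1 + _INTERGENIC_GAP
        chroms.append(c)
        starts.append(start)
        ends.append(end)
    return pd.DataFrame(
        {
            "gene": names,
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "length": lengths,
            "n_snps": n_snps,
        }
    )


def _planted_module(
    edges: Sequence[tuple[str, str]],
    size: int,
    rng: np.random.Generator,
    max_degree_quantile: float = 0.8,
) -> list[str]:
    """A connected peripheral gene set of the requested size, grown by BFS.

    Disease modules are typically built from moderately connected proteins
    rather than the promiscuous hubs, so the module is grown among nodes
    with degree between 2 and the ``max_degree_quantile`` of the degree
    distribution.  Growing through a hub would also make the module
    trivially reachable from the whole graph, which a realistically sized
    interactome does not exhibit.
    """
    g = nx.Graph(edges)
    nodes = sorted(g.nodes)
    degrees = np.array([g.degree[n] for n in nodes])
    for q in (max_degree_quantile, 0.9, 0.95, 0.99, 1.0):
        cutoff = np.quantile(degrees, q)
        allowed = {n for n, d in zip(nodes, degrees) if d <= cutoff}
        starts = sorted(allowed)
        rng.shuffle(starts)
        for start in starts:
            module = [start]
            seen = {start}
            frontier = [start]
            while len(module) < size and frontier:
                nxt = []
                for u in frontier:
                    for v in sorted(g.neighbors(u)):
                        if v not in seen and v in allowed:
                            seen.add(v)
                            module.append(v)
                            nxt.append(v)
                            if len(module) == size:
                                return module
                frontier = nxt
    raise NetdmsError("could not grow a connected planted module of that size")


def simulate_gwas(
    spec: SimulationSpec, edges: Sequence[tuple[str, str]] | None = None
) -> SyntheticStudy:
    """Simulate per-study SNP association tables with a planted module.

    Null SNP z-scores are N(0, 1); SNPs of planted genes get their mean
    shifted by ``planted_effect`` (direction drawn once per gene, shared
    across studies) in the signal-carrying studies.  Two-sided P values,
    betas and SEs are emitted consistently (beta = z * se).
    """
    if edges is None:
        edges = simulate_network(spec)
    rng = _rng(spec, 1)
    annotation = _simulate_annotation(spec, rng)
    reserved = planted_gene_names(spec)
    node_set = {g for e in edges for g in e}
    if set(reserved) <= node_set:
        planted = reserved
    else:  # user-supplied edge list: grow a connected peripheral module
        planted = _planted_module(edges, spec.planted_size, rng)
    planted_set = set(planted)
    gene_sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in planted}
    n_signal = max(1, round(spec.shared_fraction * spec.n_studies))
    signal_studies = list(range(n_signal))

    n_snps = annotation["n_snps"].to_numpy()
    total = int(n_snps.sum())
    width = len(str(total))
    snp_gene_idx = np.repeat(np.arange(spec.n_genes), n_snps)
    snp_ids = [f"s{i:0{width}d}" for i in range(1, total + 1)]
    chrom = annotation["chrom"].to_numpy()[snp_gene_idx]
    start = annotation["start"].to_numpy()[snp_gene_idx]
    length = annotation["length"].to_numpy()[snp_gene_idx]
    pos = start + (rng.random(total) * length).astype(np.int64)
    ref_idx = rng.integers(0, 4, total)
    alt_idx = (ref_idx + rng.integers(1, 4, total)) % 4
    maf = rng.uniform(0.05, 0.5, total)
    se = 1.0 / np.sqrt(2 * spec.n_samples * maf * (1 - maf))

    shift = np.zeros(total)
    planted_mask = np.isin(snp_gene_idx, [i for i, g in enumerate(annotation["gene"]) if g in planted_set])
    signs = np.array(
        [gene_sign.get(annotation["gene"].iat[i], 0.0) for i in snp_gene_idx]
    )
    shift[planted_mask] = spec.planted_effect * signs[planted_mask]

    from scipy.stats import norm

    studies = []
    for s in range(spec.n_studies):
        srng = _rng(spec, 100 + s)
        z = srng.standard_normal(total)
        if s in signal_studies:
            z = z + shift
        beta = z * se
        p = 2 * norm.sf(np.abs(z))
        studies.append(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "chrom": chrom,
                    "pos": pos,
                    "allele_ref": _BASES[ref_idx],
                    "allele_alt": _BASES[alt_idx],
                    "beta": beta,
                    "se": se,
                    "p": p,
                }
            )
        )
    truth = {
        "planted_genes": planted,
        "signal_studies": signal_studies,
        "spec": asdict(spec),
    }
    return SyntheticStudy(
        spec=spec, edges=list(edges), annotation=annotation,
        studies=studies, truth=truth,
    )


def simulate_permutations(
    spec: SimulationSpec, sim: SyntheticStudy, study: int = 0
) -> pd.DataFrame:
    """Gene x permutation matrix of null gene-wise P values.

    Each column is a fresh global-null study with the same per-gene SNP
    counts: the gene-wise P (minimum of s i.i.d. two-sided normal P
    values, i.e. of s uniforms) is drawn directly from its order-statistic
    distribution 1 - (1 - U)^(1/s).
    """
    rng = _rng(spec, 200 + study)
    s = sim.annotation["n_snps"].to_numpy()[:, None].astype(float)
    u = rng.random((len(s), spec.n_permutations))
    p = 1.0 - (1.0 - u) ** (1.0 / s)
    # guard against exact zeros from floating rounding
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(p, index=sim.annotation["gene"].to_numpy())


def simulate_gene_sets(
    network_genes: Sequence[str],
    n_sets: int = 50,
    size_range: tuple[int, int] = (10, 50),
    planted_genes: Sequence[str] | None = None,
    planted_overlap: int = 8,
    seed: int | None = None,
) -> list[GeneSet]:
    """Random gene sets plus one set enriched for the planted genes."""
    genes = list(network_genes)
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets.append(GeneSet(f"RANDOM_{i+1:03d}", "random", frozenset(members)))
    if planted_genes:
        overlap = min(planted_overlap, len(planted_genes))
        chosen = list(rng.choice(list(planted_genes), size=overlap, replace=False))
        others = [g for g in genes if g not in set(planted_genes)]
        fill = max(size_range[0] - overlap, 0)
        chosen += list(rng.choice(others, size=fill, replace=False))
        sets.append(GeneSet("PLANTED_SET", "planted-signal genes", frozenset(chosen)))
    return sets
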