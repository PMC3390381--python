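"""The GWAS-weighted protein-interaction network and module scoring.

Gene-wise P values are converted to node weights z_i = Phi^-1(1 - p_i)
(the upper-tail standard-normal quantile), so small P values become large
positive weights.  A candidate module m with k member genes is scored

    Z_m = sum_i z_i / sqrt(k)

which is standard normal when the members' P values are i.i.d. uniform.
Only genes represented in both the GWAS and the interaction data are kept
(induced-subgraph semantics); nodes isolated after the intersection are
retained — they can only ever form singleton modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DomainError, MembershipError, NetdmsError

DEFAULT_CLAMP_EPS = 1e-15


def z_weight(p, clamp_eps: float = DEFAULT_CLAMP_EPS):
    """Node weight z = Phi^-1(1 - p), with p clamped into [eps, 1 - eps].

    Accepts a scalar or array.  Clamping keeps extreme P values finite
    (typical GWAS minima around 1e-8 are far from the default eps = 1e-15
    and unaffected).  Monotone decreasing in p; z(0.5) = 0.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise DomainError("p values must lie in (0, 1]")
    clamped = np.clip(arr, clamp_eps, 1 - clamp_eps)
    z = norm.isf(clamped)
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


@dataclass(frozen=True)
class ModuleScore:
    genes: tuple
    k: int
    z_sum: float
    zm: float


class WeightedNetwork:
    """Undirected gene network with a z weight on every node.

    Nodes are stored in sorted order; ``z`` and ``degree`` are parallel numpy
    arrays for fast scoring, and ``adj`` holds adjacency as index sets.
    """

    def __init__(self, graph: nx.Graph, weights: dict):
        missing = [n for n in graph.nodes if n not in weights]
        if missing:
            raise MembershipError(f"nodes without weight: {sorted(missing)[:10]}")
        self.graph = graph
        self.nodes: list[str] = sorted(graph.nodes)
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        self.z = np.array([float(weights[g]) for g in self.nodes])
        if not np.all(np.isfinite(self.z)):
            raise DomainError("non-finite node weights")
        self.adj: list[set[int]] = [
            {self.index[v] for v in graph.neighbors(g)} for g in self.nodes
        ]
        self.degree = np.array([len(a) for a in self.adj], dtype=np.int64)
        self._hop_cache: dict[tuple[int, int], frozenset] = {}

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def weight(self, gene: str) -> float:
        return float(self.z[self._idx(gene)])

    def _idx(self, gene: str) -> int:
        try:
            return self.index[gene]
        except KeyError:
            raise MembershipError(f"gene {gene!r} is not in the network") from None

    def hop_ball(self, i: int, d: int) -> frozenset:
        """Indices within shortest-path distance d of node i (excluding i)."""
        key = (i, d)
        cached = self._hop_cache.get(key)
        if cached is not None:
            return cached
        frontier = {i}
        seen = {i}
        out: set[int] = set()
        for _ in range(d):
            nxt: set[int] = set()
            for u in frontier:
                nxt |= self.adj[u]
            nxt -= seen
            out |= nxt
            seen |= nxt
            frontier = nxt
            if not frontier:
                break
        result = frozenset(out)
        self._hop_cache[key] = result
        return result

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Serialize as (node table, edge table)."""
        nodes = pd.DataFrame(
            {"gene": self.nodes, "z": self.z, "degree": self.degree}
        )
        edges = pd.DataFrame(
            sorted((min(a, b), max(a, b)) for a, b in self.graph.edges),
            columns=["gene_a", "gene_b"],
        )
        return nodes, edges


def build_weighted_network(
    edges: Iterable[Sequence[str]], gene_assoc: pd.DataFrame,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> WeightedNetwork:
    """Intersect the interaction genes with the GWAS genes and weight nodes.

    The node set is the intersection of interaction-network genes and genes
    with a gene-wise P; edges are induced on that set.  An empty intersection
    almost always means the two inputs use different symbol namespaces.
    """
    edges = list(edges)
    if not edges or gene_assoc.empty:
        raise NetdmsError("need a nonempty edge list and gene association table")
    ppi_genes = {g for e in edges for g in e[:2]}
    p_map = dict(zip(gene_assoc["gene"], gene_assoc["p_gene"]))
    common = ppi_genes & p_map.keys()
    if not common:
        raise NetdmsError(
            "no genes shared between the interaction network and the GWAS "
            "table — check for a gene-symbol namespace mismatch"
        )
    g = nx.Graph()
    g.add_nodes_from(common)
    g.add_edges_from(
        (a, b) for a, b in ((e[0], e[1]) for e in edges)
        if a in common and b in common and a != b
    )
    weights = {gene: z_weight(p_map[gene], clamp_eps) for gene in common}
    return WeightedNetwork(g, weights)


def module_score(net: WeightedNetwork, genes: Iterable[str]) -> ModuleScore:
    """Score a gene set: Z_m = sum(z) / sqrt(k).  Order-independent."""
    members = tuple(genes)
    if not members:
        raise DomainError("cannot score an empty module")
    idx = [net._idx(g) for g in members]
    if len(set(idx)) != len(idx):
        raise DomainError("duplicate genes in module")
    z_sum = float(net.z[idx].sum())
    k = len(members)
    return ModuleScore(genes=members, k=k, z_sum=z_sum, zm=z_sum / math.sqrt(k))


def neighborhood(net: WeightedNetwork, genes: Iterable[str], d: int = 2) -> set[str]:
    """All non-member genes within shortest-path distance d of the gene set."""
    if d < 1:
        raise DomainError(f"hop distance d must be >= 1, got {d}")
    member_idx = {net._idx(g) for g in genes}
    out: set[int] = set()
    for i in member_idx:
        out |= net.hop_ball(i, d)
    out -= member_idx
    return {net.nodes[i] for i in out}
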