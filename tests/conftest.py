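import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netdms.network import WeightedNetwork


@pytest.fixture
def path_net():
    """Path graph A-B-C with z = (2, 2, 0): the hand-traceable example."""
    g = nx.Graph([("A", "B"), ("B", "C")])
    return WeightedNetwork(g, {"A": 2.0, "B": 2.0, "C": 0.0})


@pytest.fixture
def random_net_factory():
    """Erdos-Renyi weighted networks with standard-normal node weights."""

    def make(n=30, p=0.12, seed=0):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
        weights = {node: float(z) for node, z in zip(sorted(g.nodes), rng.standard_normal(n))}
        return WeightedNetwork(g, weights)

    return make


@pytest.fixture
def snp_table(tmp_path):
    """A small well-formed SNP association TSV on disk."""
    df = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "2"],
            "pos": [11000, 32000, 500],
            "allele_ref": ["A", "T", "C"],
            "allele_alt": ["G", "C", "T"],
            "beta": [0.2, -0.1, 0.05],
            "se": [0.05, 0.04, 0.08],
            "p": [0.0001, 0.02, 0.5],
        }
    )
    path = tmp_path / "snps.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path, df


@pytest.fixture
def gene_annotation():
    return pd.DataFrame(
        {
            "gene": ["GENE1", "GENE2"],
            "chrom": ["1", "2"],
            "start": [10000, 100],
            "end": [12000, 900],
            "length": [2001, 801],
        }
    )
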