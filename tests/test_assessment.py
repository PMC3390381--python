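"""Empirical null fit, score P, stratified resampling, permutation P."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from netdms.assessment import (
    NullFit,
    assess_all,
    batch_topology_matched_p,
    batch_weighted_resample_p,
    degree_bins,
    empirical_p,
    fit_empirical_null,
    permutation_p,
    score_p,
    topology_matched_p,
    weighted_resample_p,
)
from netdms.dms import search_all
from netdms.errors import (
    DegenerateDistributionError,
    DomainError,
    MembershipError,
    NetdmsError,
)
from netdms.network import WeightedNetwork


class TestFitEmpiricalNull:
    def test_recovers_standard_normal(self):
        rng = np.random.default_rng(11)
        fit = fit_empirical_null(rng.normal(0, 1, 5000))
        assert abs(fit.delta) < 0.1
        assert 0.9 < fit.sigma < 1.1

    def test_recovers_scaled_shifted_normal(self):
        rng = np.random.default_rng(12)
        fit = fit_empirical_null(rng.normal(0.5, 2, 5000))
        assert 1.8 < fit.sigma < 2.2

    def test_resists_upper_tail_contamination(self):
        rng = np.random.default_rng(13)
        scores = np.concatenate([rng.normal(0, 1, 4750), rng.normal(5, 1, 250)])
        fit = fit_empirical_null(scores)
        assert 0.9 < fit.sigma < 1.15

    def test_constant_scores_error(self):
        with pytest.raises(DegenerateDistributionError):
            fit_empirical_null(np.ones(100))

    def test_too_few_scores_error(self):
        with pytest.raises(NetdmsError):
            fit_empirical_null(np.arange(10.0))


class TestScoreP:
    def test_null_mean_gives_half(self):
        fit = NullFit(delta=0.0, sigma=1.0, n_scores=100, median=3.0)
        assert score_p([3.0], fit)[0] == pytest.approx(0.5)

    def test_standardised_quantile(self):
        fit = NullFit(delta=0.0, sigma=1.0, n_scores=100, median=0.0)
        assert score_p([1.644854], fit)[0] == pytest.approx(0.05, abs=1e-6)

    def test_rank_is_reverse_of_scores(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(2, 3, 500)
        p = score_p(scores, fit_empirical_null(scores))
        rho, _ = spearmanr(scores, p)
        assert rho == pytest.approx(-1.0)


def _grid_net(n=200, seed=0):
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, 0.04, seed=3)
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
    nodes = sorted(g.nodes)
    net = WeightedNetwork(g, {v: float(z) for v, z in zip(nodes, rng.standard_normal(n))})
    assoc = pd.DataFrame(
        {
            "gene": nodes,
            "p_gene": rng.uniform(size=n),
            "gene_length": np.exp(rng.normal(10, 1, n)).astype(int),
            "n_snps": rng.integers(1, 60, n),
        }
    )
    return net, assoc


class TestWeightedResampling:
    def test_extreme_module_gets_minimum_p(self):
        net, assoc = _grid_net(seed=1)
        # the genes with the highest z in their covariate deciles
        order = np.argsort(-net.z)
        members = [net.nodes[i] for i in order[:3]]
        p = weighted_resample_p(members, net, assoc, B=1000, seed=0)
        assert p <= 0.01

    def test_null_modules_approximately_uniform(self):
        net, assoc = _grid_net(seed=2)
        rng = np.random.default_rng(0)
        member_lists = [list(rng.choice(net.nodes, 8, replace=False)) for _ in range(400)]
        p = batch_weighted_resample_p(member_lists, net, assoc, B=500, seed=1)
        assert abs(p.mean() - 0.5) < 0.05

    def test_missing_covariate_names_gene(self):
        net, assoc = _grid_net(seed=3)
        assoc = assoc.copy()
        assoc.loc[assoc["gene"] == net.nodes[0], "gene_length"] = np.nan
        with pytest.raises(MembershipError, match=net.nodes[0]):
            weighted_resample_p([net.nodes[0]], net, assoc, B=500, seed=0)

    def test_b_too_small_rejected(self):
        net, assoc = _grid_net(seed=4)
        with pytest.raises(DomainError):
            weighted_resample_p([net.nodes[0]], net, assoc, B=50)

    def test_length_and_snp_density_agree_when_collinear(self):
        """With length exactly proportional to SNP count the two adjusted
        P values are equal in distribution (same deciles)."""
        from scipy.stats import ks_2samp

        net, assoc = _grid_net(seed=5)
        assoc = assoc.copy()
        assoc["gene_length"] = assoc["n_snps"] * 1000
        rng = np.random.default_rng(1)
        members = [list(rng.choice(net.nodes, 6, replace=False)) for _ in range(200)]
        p_gl = batch_weighted_resample_p(members, net, assoc, "gene_length", B=500, seed=2)
        p_ns = batch_weighted_resample_p(members, net, assoc, "n_snps", B=500, seed=3)
        assert ks_2samp(p_gl, p_ns).pvalue > 0.01


class TestTopologyMatched:
    @pytest.mark.parametrize(
        "degree,bin_", [(0, 0), (3, 0), (4, 0), (5, 1), (16, 1), (17, 2), (64, 2), (100, 3)]
    )
    def test_degree_bin_edges_lower_inclusive(self, degree, bin_):
        assert degree_bins(np.array([degree]))[0] == bin_

    def test_hub_module_calibrated_where_naive_is_biased(self):
        # degree-correlated weights: hub modules must not be flagged
        rng = np.random.default_rng(8)
        g = nx.barabasi_albert_graph(300, 3, seed=1)
        g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
        nodes = sorted(g.nodes)
        deg = {v: g.degree[v] for v in nodes}
        weights = {v: 0.3 * math.log1p(deg[v]) + rng.standard_normal() for v in nodes}
        net = WeightedNetwork(g, weights)
        hubs = sorted(nodes, key=lambda v: -deg[v])[:30]
        member_lists = [list(rng.choice(hubs, 5, replace=False)) for _ in range(200)]
        p_topo = batch_topology_matched_p(member_lists, net, B=500, seed=2)
        # naive unmatched resampling for comparison
        naive = []
        z = net.z
        for mem in member_lists:
            obs = z[[net.index[v] for v in mem]].sum() / math.sqrt(5)
            null = np.array(
                [z[rng.choice(len(z), 5, replace=False)].sum() / math.sqrt(5) for _ in range(200)]
            )
            naive.append((1 + (null >= obs).sum()) / 201)
        assert abs(np.mean(p_topo) - 0.5) < 0.12
        assert np.mean(naive) < 0.45  # the hub bias the matching removes

    def test_single_occupant_bin_is_usable_and_pool_guards_overdraw(self):
        g = nx.star_graph(80)
        g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
        net = WeightedNetwork(g, {v: 0.0 for v in g.nodes})
        hub = "N000"  # degree 80 -> sole occupant of the top bin
        assert 0 < topology_matched_p([hub, "N001"], net, B=500, seed=0) <= 1
        # drawing more genes from a stratum than it holds is an error
        from netdms.assessment import StratifiedPool, degree_bins

        with pytest.raises(NetdmsError):
            StratifiedPool(
                net.z, degree_bins(net.degree), {3: 2}, B=100,
                rng=np.random.default_rng(0),
            )


class TestPermutationP:
    def test_identical_permutations_give_p_one(self, path_net):
        perm = pd.DataFrame(
            {i: [0.022750131948, 0.022750131948, 0.5] for i in range(100)},
            index=["A", "B", "C"],
        )  # two-sided-ish p whose z-weight equals the observed weights
        # recompute exactly: weights 2,2,0 correspond to p = sf(2), sf(2), 0.5
        from scipy.stats import norm

        perm.loc["A"] = norm.sf(2)
        perm.loc["B"] = norm.sf(2)
        perm.loc["C"] = 0.5
        p = permutation_p(["A", "B", "C"], perm, path_net)
        assert p == pytest.approx(1.0)

    def test_missing_gene_errors(self, path_net):
        perm = pd.DataFrame(np.full((2, 10), 0.5), index=["A", "B"])
        with pytest.raises(MembershipError, match="C"):
            permutation_p(["A", "C"], perm, path_net)

    def test_minimum_p_for_planted_signal(self, path_net):
        rng = np.random.default_rng(0)
        perm = pd.DataFrame(rng.uniform(0.5, 1, (3, 999)), index=["A", "B", "C"])
        p = permutation_p(["A", "B"], perm, path_net)
        assert p == pytest.approx(1 / 1000)


class TestEmpiricalP:
    def test_plus_one_correction(self):
        assert empirical_p(0, 999) == pytest.approx(0.001)
        assert empirical_p(999, 999) == 1.0

    def test_raw_form(self):
        assert empirical_p(3, 100, plus_one=False) == pytest.approx(0.03)


class TestAssessAll:
    def _inputs(self):
        net, assoc = _grid_net(n=220, seed=6)
        mods = search_all(net)[:80]
        rng = np.random.default_rng(2)
        perm = pd.DataFrame(rng.uniform(size=(len(net), 300)), index=net.nodes)
        return mods, net, assoc, perm

    def test_all_p_populated_and_in_range(self):
        mods, net, assoc, perm = self._inputs()
        out = assess_all(mods, net, assoc, perm, B=200, seed=0)
        for col in ("p_zm", "p_gl", "p_nsnps", "p_topo", "p_emp"):
            assert out[col].between(0, 1, inclusive="right").all()

    def test_fixed_seed_reruns_identical(self):
        mods, net, assoc, perm = self._inputs()
        a = assess_all(mods, net, assoc, perm, B=200, seed=42)
        b = assess_all(mods, net, assoc, perm, B=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_module_order_invariance(self):
        mods, net, assoc, perm = self._inputs()
        a = assess_all(mods, net, assoc, perm, B=200, seed=7)
        rev = assess_all(mods[::-1], net, assoc, perm, B=200, seed=7)
        merged = a.merge(rev, on="seed", suffixes=("_f", "_r"))
        for col in ("p_gl", "p_nsnps", "p_topo", "p_emp"):
            np.testing.assert_allclose(merged[f"{col}_f"], merged[f"{col}_r"])

    def test_shared_pool_monotone_in_observed_score(self):
        """Against the same pool, a higher-scoring module with the same
        stratum profile cannot get a larger empirical P."""
        mods, net, assoc, perm = self._inputs()
        out = assess_all(mods, net, assoc, perm, B=200, seed=1)
        prof = {}
        from netdms.assessment import covariate_bins, _covariate_values

        vals = _covariate_values(net, assoc, "gene_length", [list(m.members) for m in mods])
        bins = covariate_bins(vals)
        for row, m in zip(out.itertuples(), mods):
            key = tuple(sorted(bins[net.index[g]] for g in m.members))
            prof.setdefault(key, []).append((row.zm, row.p_gl))
        for entries in prof.values():
            entries.sort()
            ps = [p for _, p in entries]
            assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(len(ps) - 1))
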