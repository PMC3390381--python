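"""Fixed-effects meta-analysis, genomic control, allele alignment, filters."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from netdms.errors import DomainError, NetdmsError
from netdms.meta import (
    StudyEffect,
    align_alleles,
    filter_meta,
    fixed_effects_meta,
    gc_adjust,
    meta_set_enrichment,
    meta_table,
)


class TestGcAdjust:
    def test_lambda_one_identity(self):
        e = gc_adjust(StudyEffect("a", 0.2, 0.03, 1.0))
        assert e.se == 0.03

    def test_sqrt_lambda_scaling(self):
        e = gc_adjust(StudyEffect("a", 0.2, 0.03, 1.04))
        assert e.se == pytest.approx(0.030594, abs=1e-6)

    def test_lambda_four_doubles_se(self):
        e = gc_adjust(StudyEffect("a", 0.2, 0.03, 4.0))
        assert e.se == pytest.approx(0.06)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(DomainError):
            StudyEffect("a", 0.2, 0.03, 0.0)


class TestFixedEffectsMeta:
    def test_single_study_identity(self):
        r = fixed_effects_meta([StudyEffect("a", 0.2, 0.1)])
        assert r.beta_meta == pytest.approx(0.2)
        assert r.se_meta == pytest.approx(0.1)
        assert r.Q == pytest.approx(0.0, abs=1e-30)
        assert r.p_het == 1.0

    def test_two_identical_studies(self):
        r = fixed_effects_meta([StudyEffect("a", 0.2, 0.1), StudyEffect("b", 0.2, 0.1)])
        assert r.beta_meta == pytest.approx(0.2)
        assert r.se_meta == pytest.approx(0.1 / math.sqrt(2), abs=1e-9)
        assert r.Q == pytest.approx(0.0) and r.I2 == 0.0

    def test_hand_worked_example(self):
        r = fixed_effects_meta([StudyEffect("a", 0.3, 0.1), StudyEffect("b", 0.1, 0.2)])
        assert r.beta_meta == pytest.approx(0.26)
        assert r.se_meta == pytest.approx(0.089443, abs=1e-6)
        assert r.Q == pytest.approx(0.8)
        assert r.I2 == 0.0
        assert r.p_het == pytest.approx(0.3711, abs=1e-4)

    def test_agrees_with_wls_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(2, 7))
            betas = rng.normal(0, 0.3, k)
            ses = rng.uniform(0.02, 0.3, k)
            r = fixed_effects_meta(
                [StudyEffect(f"s{i}", b, s) for i, (b, s) in enumerate(zip(betas, ses))]
            )
            wls = sm.WLS(betas, np.ones(k), weights=1 / ses**2).fit()
            assert r.beta_meta == pytest.approx(wls.params[0], abs=1e-10)
            # WLS bse uses the residual-scaled variance; the fixed-effects SE
            # is the unscaled 1/sqrt(sum w)
            assert r.se_meta == pytest.approx(
                float(wls.bse[0]) / np.sqrt(wls.scale), abs=1e-10
            )

    def test_k_copies_shrink_se_by_sqrt_k(self):
        one = fixed_effects_meta([StudyEffect("a", 0.15, 0.07)])
        four = fixed_effects_meta([StudyEffect(f"s{i}", 0.15, 0.07) for i in range(4)])
        assert four.beta_meta == pytest.approx(one.beta_meta)
        assert four.se_meta == pytest.approx(one.se_meta / 2, abs=1e-12)

    def test_beta_within_range_and_q_order_invariant(self):
        rng = np.random.default_rng(1)
        effects = [StudyEffect(f"s{i}", b, s) for i, (b, s) in
                   enumerate(zip(rng.normal(0, 1, 5), rng.uniform(0.1, 1, 5)))]
        r = fixed_effects_meta(effects)
        betas = [e.beta for e in effects]
        assert min(betas) <= r.beta_meta <= max(betas)
        r2 = fixed_effects_meta(effects[::-1])
        assert r.Q == pytest.approx(r2.Q, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(NetdmsError):
            fixed_effects_meta([])


class TestAlignAlleles:
    def _rows(self, alleles, betas):
        return pd.DataFrame(
            {
                "snp_id": ["rs1"] * len(betas),
                "allele_ref": [a[0] for a in alleles],
                "allele_alt": [a[1] for a in alleles],
                "beta": betas,
            }
        )

    def test_swapped_alleles_flip_sign(self):
        out = align_alleles(self._rows([("A", "G"), ("G", "A")], [0.15, -0.15]))
        np.testing.assert_allclose(out["beta"], [0.15, 0.15])

    def test_strand_complement_recognised(self):
        out = align_alleles(self._rows([("A", "G"), ("T", "C")], [0.1, 0.1]))
        np.testing.assert_allclose(out["beta"], [0.1, 0.1])

    def test_at_snp_flagged_ambiguous(self):
        out = align_alleles(self._rows([("A", "T")], [0.1]))
        assert out["ambiguous"].all()

    def test_disjoint_alleles_dropped(self):
        with pytest.warns(UserWarning, match="irreconcilable"):
            out = align_alleles(self._rows([("A", "G"), ("A", "C")], [0.1, 0.2]))
        assert len(out) == 1


def _study_frame(snp_ids, betas, ses, ps=None, flip=None):
    n = len(snp_ids)
    rng = np.random.default_rng(0)
    ref = np.array(["A"] * n)
    alt = np.array(["G"] * n)
    betas = np.asarray(betas, dtype=float).copy()
    if flip is not None:
        ref[flip], alt[flip] = "G", "A"
        betas[flip] = -betas[flip]
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "allele_ref": ref,
            "allele_alt": alt,
            "beta": betas,
            "se": ses,
            "p": ps if ps is not None else rng.uniform(size=n),
        }
    )


class TestMetaTable:
    def test_intersection_only(self):
        ids = [f"s{i}" for i in range(120)]
        rng = np.random.default_rng(2)
        t1 = _study_frame(ids, rng.normal(0, 0.1, 120), np.full(120, 0.05))
        t2 = _study_frame(ids[:100], rng.normal(0, 0.1, 100), np.full(100, 0.05))
        t3 = _study_frame(ids[10:110], rng.normal(0, 0.1, 100), np.full(100, 0.05))
        out = meta_table([t1, t2, t3])
        assert len(out) == 90  # s10..s99

    def test_rowwise_equals_scalar_meta(self):
        ids = ["a", "b"]
        t1 = _study_frame(ids, [0.3, 0.1], [0.1, 0.1])
        t2 = _study_frame(ids, [0.1, 0.2], [0.2, 0.3])
        out = meta_table([t1, t2]).set_index("snp_id")
        for sid in ids:
            r = fixed_effects_meta(
                [
                    StudyEffect("1", t1.set_index("snp_id").loc[sid, "beta"],
                                t1.set_index("snp_id").loc[sid, "se"]),
                    StudyEffect("2", t2.set_index("snp_id").loc[sid, "beta"],
                                t2.set_index("snp_id").loc[sid, "se"]),
                ]
            )
            assert out.loc[sid, "beta_meta"] == pytest.approx(r.beta_meta)
            assert out.loc[sid, "p_het"] == pytest.approx(r.p_het)

    def test_engineered_flips_detected(self):
        ids = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(3)
        betas = rng.normal(0, 0.2, 10)
        t1 = _study_frame(ids, betas, np.full(10, 0.1))
        t2 = _study_frame(ids, betas, np.full(10, 0.1), flip=[1, 4, 7])
        out = meta_table([t1, t2])
        # after alignment both studies agree exactly -> Q = 0 everywhere
        np.testing.assert_allclose(out["Q"], 0, atol=1e-20)

    def test_gc_lambda_inflates_se(self):
        ids = ["a"]
        t1 = _study_frame(ids, [0.2], [0.1])
        t2 = _study_frame(ids, [0.2], [0.1])
        plain = meta_table([t1, t2])
        adj = meta_table([t1, t2], lambdas=[1.04, 1.04])
        assert adj["se_meta"].iloc[0] == pytest.approx(
            plain["se_meta"].iloc[0] * math.sqrt(1.04)
        )

    def test_null_simulation_type_i_error(self):
        rng = np.random.default_rng(4)
        n = 10_000
        ids = [f"s{i}" for i in range(n)]
        se = np.full(n, 0.1)
        tables = [_study_frame(ids, rng.normal(0, 0.1, n), se) for _ in range(3)]
        out = meta_table(tables)
        rate = (out["p_meta"] < 0.05).mean()
        assert 0.04 < rate < 0.06

    def test_empty_intersection_errors(self):
        t1 = _study_frame(["a"], [0.1], [0.1])
        t2 = _study_frame(["b"], [0.1], [0.1])
        with pytest.raises(NetdmsError):
            meta_table([t1, t2])


class TestFilterMeta:
    def _results(self):
        return pd.DataFrame(
            {
                "snp_id": list("abcd"),
                "p_meta": [1e-6, 1e-5, 0.2, 1e-5],
                "p_het": [0.5, 0.01, 0.5, 0.06],
            }
        )

    def test_stated_filter(self):
        out = filter_meta(self._results(), p_max=1e-4, het_min=0.05)
        assert list(out["snp_id"]) == ["a", "d"]

    def test_het_zero_keeps_all_rows_passing_p(self):
        out = filter_meta(self._results(), p_max=1e-4, het_min=0.0)
        assert list(out["snp_id"]) == ["a", "b", "d"]

    def test_p_max_zero_empties(self):
        assert filter_meta(self._results(), p_max=0.0).empty


class TestMetaSetEnrichment:
    def test_whole_universe_ties_to_one(self):
        df = pd.DataFrame({"snp_id": ["a", "b"], "p_meta": [0.01, 0.5]})
        res = meta_set_enrichment(df, ["a", "b"], B=200, seed=0)
        assert res.p == 1.0

    def test_enriched_set_minimal_p(self):
        rng = np.random.default_rng(0)
        n = 2000
        p = rng.uniform(size=n)
        p[:200] = 1e-6
        df = pd.DataFrame({"snp_id": [f"s{i}" for i in range(n)], "p_meta": p})
        res = meta_set_enrichment(df, [f"s{i}" for i in range(200)], B=999, seed=1)
        assert res.p == pytest.approx(1 / 1000)

    def test_unknown_snps_error(self):
        df = pd.DataFrame({"snp_id": ["a"], "p_meta": [0.5]})
        with pytest.raises(NetdmsError):
            meta_set_enrichment(df, ["zz"], B=200, seed=0)
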