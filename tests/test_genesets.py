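"""Resampling enrichment machinery: empirical p, FDR, gene-mode tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from diffsel.genesets import (
    GeneSetCollection, binomial_overlap_test, empirical_p, gene_mode_resample,
    remove_geneset_snps, resampling_fdr, snp_category_test, weighted_gene_resample,
)


class TestEmpiricalP:
    @pytest.mark.parametrize("observed,n_above,n,expected", [
        (10.0, 0, 999, 1 / 1000),    # observed exceeds every resample
        (10.0, 49, 999, 50 / 1000),
        (-5.0, 999, 999, 1.0),       # observed below every resample
    ])
    def test_plus_one_rule(self, observed, n_above, n, expected):
        resamples = np.concatenate([
            np.full(n_above, observed + 1), np.full(n - n_above, observed - 1)])
        assert empirical_p(observed, resamples, "ge") == pytest.approx(expected)

    def test_direction_le(self):
        assert empirical_p(0.0, [1, 2, 3], "le") == pytest.approx(1 / 4)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=100),
           st.floats(-10, 10), st.floats(-10, 10))
    def test_never_zero_and_monotone(self, resamples, a, b):
        pa = empirical_p(a, resamples, "ge")
        pb = empirical_p(b, resamples, "ge")
        assert 0 < pa <= 1
        if a <= b:
            assert pa >= pb


class TestGeneSetCollection:
    def test_min_size_filter(self):
        gs = GeneSetCollection({"big": frozenset("abcd"), "tiny": frozenset("ab")})
        assert list(gs.sets) == ["big"]

    def test_two_column_and_gmt(self, tmp_path):
        p = tmp_path / "sets.tsv"
        p.write_text("s1\tg1\ns1\tg2\ns1\tg3\ns2\tg9\n")
        gs = GeneSetCollection.from_two_column(p)
        assert gs.sets == {"s1": frozenset({"g1", "g2", "g3"})}
        g = tmp_path / "sets.gmt"
        g.write_text("s1\tdesc\tg1\tg2\tg3\n")
        assert GeneSetCollection.from_gmt(g).sets == {"s1": frozenset({"g1", "g2", "g3"})}


class TestSnpCategoryTest:
    def test_extreme_enrichment(self):
        bg = [f"s{i}" for i in range(200)]
        cats = pd.Series({s: ("A" if i < 20 else "B") for i, s in enumerate(bg)})
        cand = bg[:20]  # 100% category A on a 10% background
        res = snp_category_test(cand, bg, cats, n_resamples=200, seed=1)
        pa = res.loc[res["category"] == "A", "p_greater"].item()
        assert pa == pytest.approx(1 / 201)

    def test_null_is_calibrated(self):
        rng = np.random.default_rng(0)
        bg = [f"s{i}" for i in range(300)]
        hits = 0
        for rep in range(20):
            cats = pd.Series(rng.choice(["A", "B"], size=300, p=[0.3, 0.7]), index=bg)
            cand = list(rng.choice(bg, size=40, replace=False))
            res = snp_category_test(cand, bg, cats, n_resamples=400, seed=rep)
            hits += (res["p_greater"] > 0.01).all()
        assert hits >= 18   # >= 90% of null replicates clear p > 0.01

    def test_planted_excess_detected(self):
        rng = np.random.default_rng(3)
        bg = [f"s{i}" for i in range(2000)]
        cats = pd.Series(rng.choice(["A", "B"], size=2000, p=[0.15, 0.85]), index=bg)
        sig = 0
        for rep in range(10):
            # candidates with a 2x excess of category A
            a = [s for s in bg if cats[s] == "A"]
            b = [s for s in bg if cats[s] == "B"]
            cand = (list(rng.choice(a, size=60, replace=False))
                    + list(rng.choice(b, size=140, replace=False)))
            res = snp_category_test(cand, bg, cats, n_resamples=500, seed=rep)
            sig += (res.loc[res["category"] == "A", "p_greater"].item() < 0.01)
        assert sig >= 9

    def test_candidate_not_subset_errors(self):
        with pytest.raises(ValueError):
            snp_category_test(["x"], ["a", "b"], pd.Series({"a": "A", "b": "B"}))


def simple_gene_universe(n_genes=100, snps_per_gene=5):
    snp_genes = {}
    for g in range(n_genes):
        for k in range(snps_per_gene):
            snp_genes[f"g{g}_s{k}"] = [f"g{g}"]
    return snp_genes


class TestGeneModeResample:
    def test_all_gene_set_has_p_one(self):
        snp_genes = simple_gene_universe(50)
        sets = GeneSetCollection({"all": frozenset(f"g{i}" for i in range(50))})
        bg = list(snp_genes)
        cand = bg[:25]
        res = gene_mode_resample(cand, bg, snp_genes, sets, n_resamples=100, seed=1)
        assert res.table["p"].item() == 1.0

    def test_perfectly_concentrated_candidates(self):
        # all candidate genes inside one 10-gene set of a 1000-gene universe:
        # hypergeometric probability < 1e-20, so the empirical p floors
        snp_genes = simple_gene_universe(1000, snps_per_gene=2)
        target = frozenset(f"g{i}" for i in range(10))
        sets = GeneSetCollection({
            "target": target,
            "all": frozenset(f"g{i}" for i in range(1000)),
        })
        bg = list(snp_genes)
        cand = [s for s in bg if snp_genes[s][0] in target]
        res = gene_mode_resample(cand, bg, snp_genes, sets, n_resamples=199, seed=2)
        p = res.table.set_index("set").loc["target", "p"]
        assert p == pytest.approx(1 / 200)

    def test_null_fdr_calibration(self):
        rng = np.random.default_rng(7)
        snp_genes = simple_gene_universe(200, snps_per_gene=3)
        sets = {f"set{i}": frozenset(rng.choice([f"g{j}" for j in range(200)],
                                                size=10, replace=False))
                for i in range(15)}
        sets["all"] = frozenset(f"g{j}" for j in range(200))
        coll = GeneSetCollection(sets)
        bg = list(snp_genes)
        n_sig = 0
        for rep in range(10):
            cand = list(rng.choice(bg, size=60, replace=False))
            res = gene_mode_resample(cand, bg, snp_genes, coll,
                                     n_resamples=200, seed=rep)
            n_sig += int((res.table["fdr"] < 0.1).sum())
        assert n_sig <= 2   # near-zero significant sets under the null

    def test_unattainable_gene_count_errors(self):
        snp_genes = {"s1": ["g1"], "s2": ["g2"]}
        sets = GeneSetCollection({"s": frozenset(["g1", "g2", "g3"])}, min_size=2)
        with pytest.raises(ValueError):
            gene_mode_resample(["s1", "s2"], ["s1"], snp_genes, sets, 10, 1)

    def test_order_invariance_given_seed(self):
        snp_genes = simple_gene_universe(50)
        sets = GeneSetCollection({"a": frozenset(["g1", "g2", "g3", "g4"]),
                                  "all": frozenset(f"g{i}" for i in range(50))})
        bg = list(snp_genes)
        cand = bg[10:40]
        r1 = gene_mode_resample(cand, bg, snp_genes, sets, 100, seed=5)
        r2 = gene_mode_resample(list(reversed(cand)), bg, snp_genes, sets, 100, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestResamplingFdr:
    def test_formula_and_cap(self):
        obs = np.array([0.001, 0.002, 0.003, 0.004, 0.005, 0.5])
        pseudo = np.full((10, 6), 0.4)
        pseudo[:, 0] = 0.004   # mean count of pseudo <= 0.005 is 1 per resample
        assert resampling_fdr(obs, pseudo, 0.005) == pytest.approx(1 / 5)
        assert resampling_fdr(obs, np.full((4, 6), 0.0001), 0.005) == 1.0

    def test_null_identity_near_one(self, rng):
        obs = rng.random(50)
        pseudo = rng.random((200, 50))
        assert resampling_fdr(obs, pseudo, 0.5) == pytest.approx(1.0, abs=0.25)

    def test_zero_observed_errors(self):
        with pytest.raises(ValueError):
            resampling_fdr(np.array([0.5]), np.zeros((5, 1)), 0.01)


class TestWeightedGeneResample:
    def test_uniform_weights_match_hypergeometric(self):
        genes = [f"g{i}" for i in range(60)]
        weights = pd.Series(1 / 60, index=genes)
        target = set(genes[:15])
        cand = set(genes[5:25])     # overlap 10 of size 20
        res = weighted_gene_resample({"popX": cand}, target, weights,
                                     n_resamples=3000, seed=11)
        observed = res["observed"].item()
        assert observed == 10
        # hypergeometric oracle: P(overlap >= 10) drawing 20 of 60 with 15 marked
        p_exact = stats.hypergeom.sf(observed - 1, 60, 15, 20)
        assert res["p"].item() == pytest.approx(p_exact, abs=0.02)

    def test_dominant_weight_gene_always_drawn(self):
        genes = ["big", "a", "b", "c"]
        w = pd.Series([0.97, 0.01, 0.01, 0.01], index=genes)
        res = weighted_gene_resample({"m": {"a"}}, {"big"}, w,
                                     n_resamples=300, seed=3)
        # singleton draws pick "big" ~97% of the time -> expected overlap ~0.97
        assert res["expected"].item() == pytest.approx(0.97, abs=0.05)

    def test_planted_overlap_significant(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(300)]
        weights = pd.Series(1 / 300, index=genes)
        target = set(genes[:30])
        hits = 0
        for rep in range(10):
            cand = set(rng.choice(genes[:30], 12, replace=False)) | \
                set(rng.choice(genes[30:], 8, replace=False))
            res = weighted_gene_resample({"m": cand}, target, weights,
                                         n_resamples=300, seed=rep)
            hits += res["p"].item() < 0.05
        assert hits >= 9

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            weighted_gene_resample({"m": {"a"}}, {"a"},
                                   pd.Series([0.5, 0.2], index=["a", "b"]), 10, 1)


class TestBinomialOverlap:
    def test_printed_hiv2_case(self):
        # 3 of 8 genes at a background proportion of 0.13
        assert round(binomial_overlap_test(3, 8, 0.13), 2) == 0.07

    def test_degenerate_cases(self):
        assert binomial_overlap_test(0, 10, 0.0) == 1.0
        assert binomial_overlap_test(8, 8, 0.13) == pytest.approx(0.13 ** 8, rel=1e-6)

    @pytest.mark.parametrize("k,n", [(0, 8), (2, 8), (3, 9), (5, 11)])
    def test_symmetric_at_half(self, k, n):
        assert binomial_overlap_test(k, n, 0.5) == pytest.approx(
            binomial_overlap_test(n - k, n, 0.5))

    def test_validation(self):
        with pytest.raises(ValueError):
            binomial_overlap_test(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_overlap_test(1, 4, 1.5)


class TestRemoveGenesetSnps:
    def setup_masks(self):
        snp_ids = [f"s{i}" for i in range(6)]
        snp_genes = {"s0": ["g1"], "s1": ["g1", "g2"], "s2": ["g3"],
                     "s3": [], "s4": ["g2"], "s5": ["g4"]}
        masks = {"popA": np.array([1, 1, 1, 1, 0, 0], bool),
                 "popB": np.array([1, 1, 0, 0, 1, 1], bool)}
        return snp_ids, snp_genes, masks

    def test_empty_set_identity(self):
        ids, genes, masks = self.setup_masks()
        out = remove_geneset_snps(ids, genes, set(), masks, "popA")
        np.testing.assert_array_equal(out["popA"], masks["popA"])

    def test_target_only_removed(self):
        ids, genes, masks = self.setup_masks()
        out = remove_geneset_snps(ids, genes, {"g1", "g2"}, masks, "popA")
        np.testing.assert_array_equal(out["popA"], [0, 0, 1, 1, 0, 0])
        np.testing.assert_array_equal(out["popB"], masks["popB"])  # untouched

    def test_full_coverage_empties_tail(self):
        ids, genes, masks = self.setup_masks()
        out = remove_geneset_snps(ids, genes, {"g1", "g2", "g3"}, masks, "popA")
        assert out["popA"].sum() == 1   # only the gene-less s3 remains
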