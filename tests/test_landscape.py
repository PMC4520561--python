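"""Ranking, percentile bins, quota curves and enrichment statistics."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from csplandscape import (
    category_quota,
    enrichment_test,
    landscape_report,
    rank_and_bin,
    top_bottom_sets,
)
from csplandscape import binding_scores, simulate_annotation, simulate_counts

from conftest import mpr_effect_config


def binding_frame(scores, categories=None):
    genes = [f"g{i:03d}" for i in range(len(scores))]
    df = pd.DataFrame(
        {"binding_score": scores, "defined": [s == s for s in scores]},
        index=pd.Index(genes, name="gene_id"),
    )
    ann = pd.DataFrame(
        {
            "gene_id": genes,
            "length_nt": 1000,
            "category": categories if categories is not None else ["OTHER"] * len(genes),
        }
    ).set_index("gene_id")
    return df, ann


def exact_upper_tail(N, K, n, k):
    """Arbitrary-precision hypergeometric upper tail P(X >= k)."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return total


class TestRankAndBin:
    def test_even_split(self):
        df, _ = binding_frame(np.linspace(0, 1, 100))
        res = rank_and_bin(df, 10)
        assert (res.bin_sizes() == 10).all()

    def test_remainder_to_lowest_bins(self):
        df, _ = binding_frame(np.linspace(0, 1, 101))
        sizes = rank_and_bin(df, 10).bin_sizes()
        assert sizes.loc[1] == 11
        assert (sizes.loc[2:] == 10).all()

    def test_ties_broken_lexicographically(self):
        df, _ = binding_frame([1.0] * 30)
        res = rank_and_bin(df, 3)
        assert list(res.table.index) == sorted(df.index)
        assert list(res.table["bin"].unique()) == [1, 2, 3]

    def test_undefined_excluded_and_reported(self):
        df, _ = binding_frame(list(np.linspace(0, 1, 20)))
        df.loc["g003", "binding_score"] = np.nan
        res = rank_and_bin(df, 2)
        assert "g003" in res.excluded
        assert "g003" not in res.table.index

    def test_too_few_genes(self):
        df, _ = binding_frame([0.1, 0.2])
        with pytest.raises(ValueError):
            rank_and_bin(df, 10)


class TestCategoryQuota:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(1)
        cats = rng.choice(["MPR", "CPR"], size=60).tolist()
        df, ann = binding_frame(rng.random(60), cats)
        res = rank_and_bin(df, 6)
        raw, smoothed = category_quota(res, ann, smooth_window=1)
        pd.testing.assert_frame_equal(raw, smoothed)

    def test_single_category_quota_is_one(self):
        df, ann = binding_frame(np.linspace(0, 1, 40), ["MPR"] * 40)
        raw, _ = category_quota(rank_and_bin(df, 4), ann)
        assert np.allclose(raw["MPR"], 1.0)

    def test_smoothing_matches_brute_force(self):
        rng = np.random.default_rng(7)
        cats = rng.choice(["MPR", "CPR", "OTHER"], size=90).tolist()
        df, ann = binding_frame(rng.random(90), cats)
        res = rank_and_bin(df, 9)
        raw, smoothed = category_quota(res, ann, smooth_window=3)
        for cat in raw.columns:
            vals = raw[cat].to_numpy()
            for i in range(len(vals)):
                h = min(1, i, len(vals) - 1 - i)
                assert smoothed[cat].iloc[i] == pytest.approx(
                    vals[i - h : i + h + 1].mean()
                )

    def test_quota_conservation(self):
        rng = np.random.default_rng(3)
        cats = rng.choice(["MPR", "CPR", "SPR"], size=83).tolist()
        df, ann = binding_frame(rng.random(83), cats)
        res = rank_and_bin(df, 10)
        raw, _ = category_quota(res, ann)
        sizes = res.bin_sizes()
        for cat in raw.columns:
            total = (raw[cat] * sizes).sum()
            assert total == pytest.approx(cats.count(cat))

    def test_even_window_rejected(self):
        df, ann = binding_frame(np.linspace(0, 1, 40), ["MPR"] * 40)
        with pytest.raises(ValueError):
            category_quota(rank_and_bin(df, 4), ann, smooth_window=2)


class TestTopBottom:
    def test_small_sets(self):
        df, _ = binding_frame(np.linspace(0, 1, 10))
        top, bottom = top_bottom_sets(df, 0.3)
        assert len(top) == 3 and len(bottom) == 3
        assert not set(top) & set(bottom)

    def test_ceil_rule_published_scale(self):
        df, _ = binding_frame(np.linspace(0, 1, 2731))
        top, bottom = top_bottom_sets(df, 0.30)
        assert len(top) == 820 and len(bottom) == 820

    def test_reversal_swaps_sets(self):
        scores = np.linspace(0, 1, 50)
        df1, _ = binding_frame(scores)
        df2, _ = binding_frame(scores[::-1])
        top1, bottom1 = top_bottom_sets(df1, 0.2)
        top2, bottom2 = top_bottom_sets(df2, 0.2)
        assert set(top1) == set(bottom2) and set(bottom1) == set(top2)

    def test_overlapping_fraction_rejected(self):
        df, _ = binding_frame(np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            top_bottom_sets(df, 0.5)


class TestEnrichment:
    def test_complete_overlap(self):
        genes = [f"g{i}" for i in range(10)]
        res = enrichment_test(genes[:5], genes[:5], genes)
        assert res.p_enriched == pytest.approx(1 / 252)
        assert res.direction == "enriched"

    def test_symmetric_instance(self):
        genes = ["a", "b", "c", "d"]
        res = enrichment_test(["a", "c"], ["a", "b"], genes)
        assert res.k == 1
        assert res.p_enriched == pytest.approx(5 / 6)

    def test_zero_hits_upper_tail_is_one(self):
        genes = [f"g{i}" for i in range(8)]
        res = enrichment_test(genes[:3], genes[5:], genes)
        assert res.k == 0
        assert res.p_enriched == 1.0

    def test_matches_exact_enumeration_small_universes(self):
        """scipy-backed tails equal arbitrary-precision sums for N <= 12."""
        for N in range(1, 13):
            genes = [f"g{i}" for i in range(N)]
            for K in range(N + 1):
                for n in range(N + 1):
                    k = min(K, n)  # draw maximally overlapping sets
                    sel = genes[:n]
                    cat = genes[:k] + genes[n : n + (K - k)]
                    res = enrichment_test(sel, cat, genes)
                    assert res.k == k
                    exact = exact_upper_tail(N, K, n, k)
                    assert res.p_enriched == pytest.approx(float(exact), rel=1e-9)

    def test_tail_identity(self):
        """Upper and lower tails overlap exactly in the point mass at k."""
        from scipy.stats import hypergeom

        for (N, K, n, k) in [(10, 4, 5, 2), (12, 6, 6, 3), (9, 3, 4, 0)]:
            genes = [f"g{i}" for i in range(N)]
            sel = genes[:n]
            cat = genes[:k] + genes[n : n + (K - k)]
            res = enrichment_test(sel, cat, genes)
            pmf = hypergeom.pmf(k, N, K, n)
            assert res.p_enriched + res.p_depleted == pytest.approx(1 + pmf)

    def test_monotone_in_category_hits(self):
        genes = [f"g{i:02d}" for i in range(20)]
        cat = genes[:8]
        previous = 1.1
        for k in range(0, 6):
            sel = cat[:k] + genes[8 : 8 + (5 - k)]
            p = enrichment_test(sel, cat, genes).p_enriched
            assert p <= previous + 1e-12
            previous = p

    def test_ease_more_conservative(self):
        genes = [f"g{i}" for i in range(30)]
        res = enrichment_test(genes[:10], genes[:12], genes)
        assert res.p_ease >= res.p_enriched

    def test_bonferroni_capped(self):
        genes = [f"g{i}" for i in range(10)]
        res = enrichment_test(genes[:3], genes[5:], genes, n_tests=50)
        assert res.p_bonferroni == 1.0

    def test_printed_count_magnitudes(self):
        """On the published detection counts the MPR top-30% tail is
        astronomically small and the CPR bottom-30% tail clears 1e-6."""
        genes = [f"g{i:04d}" for i in range(2731)]
        mpr = genes[:471]
        sel_top = mpr[:213] + genes[471 : 471 + 607]
        res = enrichment_test(sel_top, mpr, genes)
        assert res.k == 213 and res.n == 820
        assert res.p_enriched < 1e-12
        cpr = genes[:1363]
        sel_bottom = cpr[:487] + genes[1363 : 1363 + 333]
        res2 = enrichment_test(sel_bottom, cpr, genes)
        assert res2.k == 487 and res2.n == 820
        assert res2.p_enriched < 1e-6

    def test_selected_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(["x"], ["a"], ["a", "b"])


class TestReport:
    def test_effect_shows_in_fold_enrichment(self):
        cfg = mpr_effect_config(41, n_genes=1000)
        ann = simulate_annotation(cfg)
        counts, _ = simulate_counts(ann, cfg)
        scores = binding_scores(counts, ann, condition="on")
        rep = landscape_report(scores, ann)
        enr = rep["enrichment"].set_index(["set", "category"])
        assert enr.loc[("top", "MPR"), "fold_enrichment"] > 1
        assert enr.loc[("bottom", "MPR"), "fold_enrichment"] < 1

    def test_deterministic(self, small_dataset):
        ann, counts, _ = small_dataset
        scores = binding_scores(counts, ann, condition="Mg2")
        r1 = landscape_report(scores, ann)
        r2 = landscape_report(scores, ann)
        pd.testing.assert_frame_equal(r1["enrichment"], r2["enrichment"])
        pd.testing.assert_frame_equal(r1["quota_smoothed"], r2["quota_smoothed"])
        assert r1["top_set"] == r2["top_set"]

    def test_per_condition_mapping(self, small_dataset):
        ann, counts, _ = small_dataset
        by_cond = {
            c: binding_scores(counts, ann, condition=c) for c in ("Mg2", "Mg15")
        }
        rep = landscape_report(by_cond, ann)
        assert set(rep) == {"Mg2", "Mg15"}
        for r in rep.values():
            assert {"landscape", "enrichment", "top_set", "bottom_set"} <= set(r)
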