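import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_sample
from foltile import tiling_dm
from foltile.synthetic_data import SimConfig, gen_methylomes
from foltile.tiling_dm import (adjust_fdr, aggregate_tiles, call_dmts, logistic_lrt_p,
                               magnitude_bin, summarize_dmts)
from foltile.tiling_dm import test_contrast as contrast_tiles
from foltile.tiling_dm import test_tile as tile_p_value


class TestAggregation:
    def test_tile_methylation_is_unweighted_cpg_mean(self):
        # per-CpG fractions 0%, 50%, 100% at very different coverages -> 50%
        s = make_sample("s", "placenta", "Ctrl",
                        [("chr1", 5, 0, 40), ("chr1", 50, 10, 10), ("chr1", 99, 3, 0)])
        ts = aggregate_tiles([s])
        assert ts.frac_mean[0, 0] == pytest.approx(0.5)
        assert ts.tiles.iloc[0]["n_cpgs"] == 3

    def test_single_cpg_tile_excluded_from_testing(self):
        rows_a = [("chr1", 5, 10, 10), ("chr1", 50, 10, 10), ("chr1", 150, 10, 10)]
        a = [make_sample(f"c{i}", "placenta", "Ctrl", rows_a) for i in range(2)]
        b = [make_sample(f"t{i}", "placenta", "20FS", rows_a) for i in range(2)]
        res = contrast_tiles(aggregate_tiles(a + b), "placenta", "20FS")
        assert list(res["start"]) == [0]  # tile [100,200) has 1 CpG -> dropped

    def test_low_coverage_sample_excludes_tile(self):
        rows_good = [("chr1", 5, 10, 10), ("chr1", 50, 10, 10)]
        rows_thin = [("chr1", 5, 3, 2), ("chr1", 50, 2, 2)]  # total 9 < 10
        a = [make_sample("c0", "placenta", "Ctrl", rows_good),
             make_sample("c1", "placenta", "Ctrl", rows_thin)]
        b = [make_sample(f"t{i}", "placenta", "20FS", rows_good) for i in range(2)]
        res = contrast_tiles(aggregate_tiles(a + b), "placenta", "20FS")
        assert len(res) == 0

    def test_tile_grid_is_zero_based_half_open(self):
        # 1-based position 100 is the last base of tile [0, 100); 101 starts [100, 200)
        s = make_sample("s", "placenta", "Ctrl", [("chr1", 100, 5, 5), ("chr1", 101, 5, 5)])
        ts = aggregate_tiles([s])
        assert list(ts.tiles["start"]) == [0, 100]

    def test_sliding_windows_cover_cpg_multiple_times(self):
        s = make_sample("s", "placenta", "Ctrl", [("chr1", 151, 5, 5)])
        ts = aggregate_tiles([s], tile_size=100, step=50)
        assert list(ts.tiles["start"]) == [100, 150]

    def test_empty_input(self):
        assert len(aggregate_tiles([])) == 0


class TestTileTest:
    def test_identical_pooled_counts_fisher_p_is_one(self):
        assert tile_p_value([10], [20], [10], [20]) == pytest.approx(1.0)

    def test_extreme_separation_tiny_p(self):
        # pooled 100/0 vs 0/100 methylated/unmethylated
        p = tile_p_value([100], [100], [0], [100])
        assert p < 1e-20

    def test_fisher_path_matches_scipy_on_1v1(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ma, mb = rng.integers(0, 30, 2)
            ca, cb = ma + rng.integers(1, 30), mb + rng.integers(1, 30)
            expected = stats.fisher_exact([[ma, ca - ma], [mb, cb - mb]])[1]
            assert tile_p_value([ma], [ca], [mb], [cb]) == pytest.approx(expected, abs=1e-12)

    def test_lrt_matches_statsmodels_glm(self):
        """The closed-form G statistic equals a statsmodels binomial GLM LRT."""
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        for _ in range(5):
            cov = rng.integers(10, 60, size=12)
            meth = rng.binomial(cov, np.r_[np.full(6, 0.3), np.full(6, 0.5)])
            y = np.column_stack([meth, cov - meth])
            x_full = sm.add_constant(np.r_[np.zeros(6), np.ones(6)])
            full = sm.GLM(y, x_full, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, np.ones((12, 1)), family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - null.llf)
            p_sm = stats.chi2.sf(lrt, 1)
            p_ours = tile_p_value(meth[:6], cov[:6], meth[6:], cov[6:])
            assert p_ours == pytest.approx(p_sm, rel=1e-8)

    def test_group_swap_symmetry(self, two_group_samples):
        ts = aggregate_tiles(two_group_samples)
        res = contrast_tiles(ts, "placenta", "20FS", control="Ctrl")
        swapped = contrast_tiles(ts, "placenta", "Ctrl", control="20FS")
        np.testing.assert_allclose(res["delta"].values, -swapped["delta"].values)
        np.testing.assert_allclose(res["p_value"].values, swapped["p_value"].values, rtol=1e-12)

    def test_zero_coverage_undefined(self):
        assert np.isnan(tile_p_value([0], [0], [5], [10]))

    def test_sample_label_permutation_tracks_parametric_p(self):
        """Sample-label permutation p and the pooled LRT p agree in the bulk
        (median fold-ratio < 2); per-tile agreement is intrinsically looser
        because the permutation conditions on only 12 sample summaries."""
        from itertools import combinations
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(20):
            p0 = rng.uniform(0.25, 0.75)
            cov = np.maximum(rng.negative_binomial(5, 5 / 35, size=(12, 3)), 1)
            meth = rng.binomial(cov, p0)
            m, c = meth.sum(1), cov.sum(1)
            obs = tile_p_value(m[:6], c[:6], m[6:], c[6:])
            stats_ = []
            for idx in combinations(range(12), 6):
                sel = np.zeros(12, bool)
                sel[list(idx)] = True
                stats_.append(logistic_lrt_p(m[sel].sum(), c[sel].sum(),
                                             m[~sel].sum(), c[~sel].sum()))
            pperm = float((np.array(stats_) <= obs + 1e-12).mean())
            ratios.append(max(obs / pperm, pperm / obs))
        assert np.median(ratios) < 2.0


class TestFdr:
    def test_bh_worked_example(self):
        q = adjust_fdr([0.01, 0.02, 0.03])
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.42])[0] == pytest.approx(0.42)

    def test_nan_excluded_from_m(self):
        q = adjust_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.02])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200) ** 2
        np.testing.assert_allclose(adjust_fdr(p),
                                   multipletests(p, method="fdr_bh")[1], rtol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_monotone_in_sorted_order_and_bounded(self, pvals):
        q = adjust_fdr(pvals)
        assert ((q >= np.asarray(pvals) - 1e-12) | np.isnan(q)).all()
        assert (q[~np.isnan(q)] <= 1.0).all()
        order = np.argsort(pvals, kind="mergesort")
        qs = q[order]
        assert (np.diff(qs) >= -1e-12).all()


class TestDmtCalls:
    def make_results(self, rows):
        df = pd.DataFrame(rows, columns=["q_value", "delta"])
        df["chrom"] = "chr1"
        df["start"] = np.arange(len(df)) * 100
        df["end"] = df["start"] + 100
        return df

    @pytest.mark.parametrize("q,delta,is_dmt", [
        (0.005, 12.0, True),    # passes both gates
        (0.02, 30.0, False),    # q fails
        (0.001, -9.5, False),   # delta fails
        (0.01, 20.0, False),    # q tie -> strict inequality
        (0.005, 10.0, False),   # delta tie -> strict inequality
        (0.005, -10.5, True),   # hypo direction counts too
    ])
    def test_threshold_gates(self, q, delta, is_dmt):
        dmts = call_dmts(self.make_results([(q, delta)]))
        assert (len(dmts) == 1) == is_dmt

    def test_direction_and_bins(self):
        dmts = call_dmts(self.make_results(
            [(0.001, 12.0), (0.001, -17.0), (0.001, 20.0), (0.001, 20.5), (0.001, 44.0)]))
        assert list(dmts["direction"]) == ["hyper", "hypo", "hyper", "hyper", "hyper"]
        assert list(dmts["magnitude_bin"]) == ["10-15", "15-20", "15-20", ">20", ">20"]

    def test_bins_partition_abs_delta(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(10.01, 60, 500)
        bins = magnitude_bin(d)
        assert ((bins == "10-15") == (d <= 15)).all()
        assert ((bins == "15-20") == ((d > 15) & (d <= 20))).all()
        assert ((bins == ">20") == (d > 20)).all()

    def test_summary_fractions(self):
        dmts = call_dmts(self.make_results(
            [(0.001, 12.0), (0.001, 13.0), (0.001, 14.0), (0.001, -11.0)]))
        s = summarize_dmts(dmts)
        assert s["n_dmts"] == 4
        assert s["hyper_fraction"] == pytest.approx(0.75)
        assert s["bin_counts"]["10-15"] == 4

    def test_empty_summary(self):
        s = summarize_dmts(call_dmts(self.make_results([(0.9, 1.0)])))
        assert s["n_dmts"] == 0
        assert "hyper_fraction" not in s

    def test_permissive_thresholds_make_everything_a_dmt(self, two_group_samples):
        ts = aggregate_tiles(two_group_samples)
        res = contrast_tiles(ts, "placenta", "20FS")
        dmts = call_dmts(res, q_threshold=1.01, min_delta=-1.0)
        assert len(dmts) == len(res)

    def test_planted_hyper_fraction_matches_generator(self):
        """80% of plants positive -> hyper fraction within a binomial CI of 0.8."""
        cfg = SimConfig(seed=21, diets=("Ctrl", "7FD"), tissues=("placenta",))
        cfg = cfg.with_random_plants(n_planted=60, hyper_fraction=0.8,
                                    shared_fraction=0.0, diets=("7FD",))
        samples, _ = gen_methylomes(cfg)
        res = contrast_tiles(aggregate_tiles(samples), "placenta", "7FD")
        s = summarize_dmts(call_dmts(res))
        assert s["n_dmts"] >= 30
        # binomial 99% CI around 0.8 at n>=30 is ~ +-0.19
        assert abs(s["hyper_fraction"] - 0.8) < 0.19
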