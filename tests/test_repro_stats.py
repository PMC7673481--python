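import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foltile.repro_stats import (abnormal_litter_test, classify_growth,
                                 dunnett_vs_control, litter_outcome_table,
                                 postimplantation_loss, preimplantation_loss)
from foltile.synthetic_data import SimConfig, gen_litters


def litter_frame(rows):
    return pd.DataFrame(rows, columns=["dam_id", "diet", "corpora_lutea",
                                       "implantation_sites", "resorptions"])


def embryo_frame(rows):
    df = pd.DataFrame(rows, columns=["dam_id", "weight"])
    df["embryo_id"] = [f"e{i}" for i in range(len(df))]
    df["placenta_weight"] = 0.08
    df["sex"] = "M"
    df["crown_rump"] = 22.0
    df["malformed"] = False
    return df


class TestLossDerivations:
    @pytest.mark.parametrize("cl,imp,expected", [(10, 8, 2), (8, 8, 0)])
    def test_preimplantation_loss(self, cl, imp, expected):
        assert preimplantation_loss(cl, imp) == expected

    def test_miscount_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            assert preimplantation_loss(7, 8) == 0

    @pytest.mark.parametrize("imp,res,default,literal", [
        (8, 2, 2, 6), (8, 0, 0, 8), (8, 8, 8, 0)])
    def test_postimplantation_both_readings(self, imp, res, default, literal):
        assert postimplantation_loss(imp, res) == default
        assert postimplantation_loss(imp, res, mode="literal") == literal


class TestGrowthClassifier:
    def control_data(self):
        # three control litters with litter-mean weights 1.1, 1.2, 1.3 -> mu=1.2, sd=0.1
        litters = litter_frame([("c1", "Ctrl", 10, 2, 0), ("c2", "Ctrl", 10, 2, 0),
                                ("c3", "Ctrl", 10, 2, 0), ("t1", "20FS", 10, 3, 0)])
        embryos = embryo_frame([("c1", 1.1), ("c1", 1.1), ("c2", 1.2), ("c2", 1.2),
                                ("c3", 1.3), ("c3", 1.3)])
        return litters, embryos

    @pytest.mark.parametrize("weight,expected", [
        (0.95, "restricted"),   # below mu - 2 sd = 1.0
        (1.45, "enhanced"),     # above mu + 2 sd = 1.4
        (1.0, "normal"),        # exactly on the boundary -> strict inequality
        (1.4, "normal"),
        (1.2, "normal"),
    ])
    def test_two_sd_boundaries(self, weight, expected):
        litters, embryos = self.control_data()
        test_embryos = pd.concat(
            [embryos, embryo_frame([("t1", weight)])], ignore_index=True)
        cls = classify_growth(test_embryos, litters)
        assert cls.iloc[-1] == expected

    def test_translation_equivariance(self):
        litters, embryos = self.control_data()
        probe = pd.concat([embryos, embryo_frame([("t1", 0.97)])], ignore_index=True)
        base = classify_growth(probe, litters)
        shifted = probe.copy()
        shifted["weight"] = shifted["weight"] + 0.5
        assert list(classify_growth(shifted, litters)) == list(base)

    def test_requires_two_control_litters(self):
        litters = litter_frame([("c1", "Ctrl", 10, 2, 0)])
        embryos = embryo_frame([("c1", 1.2), ("c1", 1.2)])
        with pytest.raises(ValueError, match="control litters"):
            classify_growth(embryos, litters)

    def test_conservation_on_simulated_litters(self):
        cfg = SimConfig(seed=13)
        litters, embryos = gen_litters(cfg)
        cls = classify_growth(embryos, litters)
        counts = cls.value_counts()
        assert counts.sum() == len(embryos)  # every viable embryo classified once


class TestAbnormalLitterTest:
    def build(self, ctrl_flagged, ctrl_total, treated_flagged, treated_total):
        """Litters flagged via resorptions = 2; embryo weights kept well
        inside the 2-sigma growth bounds so only resorptions drive flags."""
        rows, emb = [], []

        def add(diet, dam, flagged, weight):
            rows.append((dam, diet, 12, 10, 2 if flagged else 0))
            emb.extend([(dam, weight), (dam, weight)])

        # control litter-mean weights spread symmetrically: max deviation
        # from their mean is always < 2 sd of the litter means
        offsets = np.linspace(-0.01, 0.01, ctrl_total)
        for i in range(ctrl_total):
            add("Ctrl", f"c{i}", i < ctrl_flagged, 1.2 + offsets[i])
        for i in range(treated_total):
            diet = ("7FD", "10FS", "20FS")[i % 3]
            add(diet, f"t{i}", i < treated_flagged, 1.2)
        return litter_frame(rows), embryo_frame(emb)

    def test_balanced_table_p_one(self):
        litters, embryos = self.build(1, 2, 1, 2)
        table, p = abnormal_litter_test(litters, embryos)
        assert table == [[1, 1], [1, 1]]
        assert p == pytest.approx(1.0)

    def test_perfect_separation_enumeration(self):
        litters, embryos = self.build(5, 5, 0, 5)
        table, p = abnormal_litter_test(litters, embryos)
        assert table == [[5, 0], [0, 5]]
        assert p == pytest.approx(2 / 252, rel=1e-9)  # 2 / C(10,5)

    def test_row_swap_exchangeability(self):
        litters, embryos = self.build(3, 8, 6, 9)
        table, p = abnormal_litter_test(litters, embryos)
        swapped = [table[1], table[0]]
        assert p == pytest.approx(stats.fisher_exact(swapped)[1], rel=1e-12)

    def test_per_diet_tables_when_not_pooled(self):
        litters, embryos = self.build(2, 6, 6, 9)
        out = abnormal_litter_test(litters, embryos, pool_treated=False)
        assert set(out) == {"7FD", "10FS", "20FS"}
        for tab, p in out.values():
            assert tab[0] == [2, 4]
            assert 0 <= p <= 1


class TestDunnett:
    def test_identical_constants_p_one(self):
        vals = [5.0] * 12
        groups = ["Ctrl"] * 3 + ["7FD"] * 3 + ["10FS"] * 3 + ["20FS"] * 3
        out = dunnett_vs_control(vals, groups)
        assert (out["p_adjusted"] == 1.0).all()

    def test_bounded_between_raw_and_bonferroni(self):
        rng = np.random.default_rng(5)
        groups = np.array(["Ctrl"] * 8 + ["7FD"] * 8 + ["10FS"] * 8 + ["20FS"] * 8)
        vals = rng.normal(10, 2, 32)
        vals[groups == "10FS"] += 2.0
        out = dunnett_vs_control(vals, groups).set_index("group")
        # raw p of the same contrast statistic (pooled variance, N - k df)
        df_resid = len(vals) - 4
        for g in ("7FD", "10FS", "20FS"):
            raw = 2 * stats.t.sf(abs(out.loc[g, "statistic"]), df_resid)
            adj = out.loc[g, "p_adjusted"]
            assert raw <= adj + 1e-6
            assert adj <= min(1.0, 3 * raw) + 0.03  # Bonferroni bound (3 contrasts)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(6)
        groups = np.array(["Ctrl"] * 10 + ["7FD"] * 10 + ["20FS"] * 10)
        vals = rng.normal(0, 1, 30)
        vals[groups == "20FS"] += 10.0
        out = dunnett_vs_control(vals, groups).set_index("group")
        assert out.loc["20FS", "p_adjusted"] < 0.001
        assert out.loc["7FD", "p_adjusted"] > 0.05

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            dunnett_vs_control([1.0, 2.0, 3.0], ["Ctrl", "Ctrl", "7FD"])


class TestOutcomeTable:
    def test_derived_columns(self):
        litters = litter_frame([("d1", "Ctrl", 12, 10, 2), ("d2", "Ctrl", 9, 9, 0)])
        embryos = embryo_frame([("d1", 1.2), ("d1", 1.3), ("d2", 1.1)])
        out = litter_outcome_table(litters, embryos).set_index("dam_id")
        assert out.loc["d1", "litter_size"] == 8
        assert out.loc["d1", "preimplantation_loss"] == 2
        assert out.loc["d1", "postimplantation_loss"] == 2
        assert out.loc["d1", "mean_embryo_weight"] == pytest.approx(1.25)
        assert out.loc["d2", "mean_ep_ratio"] == pytest.approx(1.1 / 0.08)
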