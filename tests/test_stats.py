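"""Tests for the statistical pipeline stages."""

import numpy as np
import pandas as pd
import pytest

from vitdfree.binding import all_diplotypes
from vitdfree.stats import (
    adjusted_regression,
    compare_categorical,
    compare_isoform_groups,
    compare_two_groups,
    correlation_table,
    interaction_scan,
    normality_gate,
    run_table_suite,
)

RNG = np.random.default_rng(20240915)


class TestNormalityGate:
    def test_normal_sample_passes_untouched(self):
        x = RNG.normal(0, 1, 500)
        g = normality_gate(x)
        assert g["is_normal"] and not g["transform_applied"]

    def test_lognormal_sample_gets_log_transform(self):
        x = np.exp(RNG.normal(0, 1, 500))
        g = normality_gate(x)
        assert g["transform_applied"]
        assert g["is_normal"]
        assert np.allclose(np.sort(g["transformed_x"]), np.sort(np.log(x)))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            normality_gate(np.ones(10))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestTwoGroups:
    def test_identical_groups_not_significant(self):
        x = np.concatenate([np.arange(30.0), np.arange(30.0)])
        g = ["a"] * 30 + ["b"] * 30
        res = compare_two_groups(x, g)
        assert res.p > 0.99

    def test_strong_shift_detected(self):
        a = RNG.normal(0, 1, 50)
        b = RNG.normal(5, 1, 50)
        res = compare_two_groups(np.concatenate([a, b]),
                                 ["a"] * 50 + ["b"] * 50)
        assert res.p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_chi_squared_for_categorical(self):
        flag = [True] * 40 + [False] * 10 + [True] * 10 + [False] * 40
        grp = ["a"] * 50 + ["b"] * 50
        res = compare_categorical(flag, grp)
        assert res.test == "chi-squared" and res.p < 1e-6


class TestIsoformGroups:
    def _null_data(self, n=146, seed=0):
        rng = np.random.default_rng(seed)
        dips = rng.choice([str(d) for d in all_diplotypes()], size=n)
        # force every group to n >= 2
        labels = [str(d) for d in all_diplotypes()]
        dips[: 2 * len(labels)] = np.repeat(labels, 2)
        return rng.normal(20, 5, n), dips

    def test_bonferroni_threshold_value(self):
        x, d = self._null_data()
        iso = compare_isoform_groups(x, d)
        assert round(iso.threshold, 4) == 0.0033
        assert len(iso.pairwise) == 15

    def test_shifted_group_flags_fire(self):
        x, d = self._null_data(n=400, seed=3)
        x = x + np.where(np.asarray(d) == "Gc2/Gc2", 25.0, 0.0)
        iso = compare_isoform_groups(x, d)
        assert iso.kw_p < 1e-6
        hits = iso.pairwise[iso.pairwise["significant"]]
        assert not hits.empty
        assert (hits[["group1", "group2"]] == "Gc2/Gc2").any(axis=1).all()

    def test_missing_group_listed_in_error(self):
        x = np.arange(20.0)
        d = ["Gc1f/Gc1f"] * 20
        with pytest.raises(ValueError, match="Gc2/Gc2"):
            compare_isoform_groups(x, d)


class TestCorrelations:
    def test_self_and_anti_correlation(self):
        df = pd.DataFrame({"x": np.arange(50.0)})
        df["y"] = -df["x"]
        out = correlation_table(df, ["x"], ["x", "y"])
        r = out.set_index("metabolite")["r"]
        assert r["x"] == pytest.approx(1.0)
        assert r["y"] == pytest.approx(-1.0)

    def test_pairwise_complete_n(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, np.nan, 5],
                           "y": [2.0, 4, np.nan, 8, 10]})
        out = correlation_table(df, ["x"], ["y"])
        assert out.loc[0, "n"] == 3

    def test_generator_ipth_direction(self, large_derived):
        out = correlation_table(large_derived, ["ipth_pg_ml"],
                                ["total_25ohd_ng_ml"])
        assert out.loc[0, "r"] < 0


class TestInteractionScan:
    def test_single_category_rejected(self, small_derived):
        sub = small_derived[small_derived["bmi_category"] == "normal"]
        with pytest.raises(ValueError):
            interaction_scan(sub, "bmc_tb_z", "total_25ohd_ng_ml")

    def test_injected_opposite_slopes_detected(self, large_derived):
        res = interaction_scan(large_derived, "bmc_tb_z", "total_25ohd_ng_ml")
        assert res["p_interaction"] < 0.05
        assert res["beta_interaction"] < 0  # overweight slope below normal


class TestAdjustedRegression:
    def test_exact_linear_relation(self):
        n = 80
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "age_years": rng.uniform(5, 13, n),
            "sex": rng.choice(["M", "F"], n),
            "fm_z": rng.normal(0, 1, n),
            "lm_z": rng.normal(0, 1, n),
            "x": rng.normal(20, 5, n),
        })
        df["y"] = 2.0 * df["x"]
        res = adjusted_regression(df, "y", "x")
        assert res.beta == pytest.approx(2.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0)
        assert res.se < 1e-8

    def test_duplicated_predictor_flags_vif(self):
        n = 60
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({
            "x": x, "age_years": x + rng.normal(0, 0.01, n),
            "sex": rng.choice(["M", "F"], n),
            "fm_z": rng.normal(0, 1, n), "lm_z": rng.normal(0, 1, n),
            "y": rng.normal(0, 1, n),
        })
        res = adjusted_regression(df, "y", "x")
        assert res.vif_flag and max(res.vif.values()) >= 3

    def test_recovers_injected_normal_weight_slope(self, large_derived):
        nw = large_derived[large_derived["bmi_category"] == "normal"]
        res = adjusted_regression(nw, "bmc_tb_z", "total_25ohd_ng_ml")
        assert res.ci_low <= 0.030 <= res.ci_high
        assert not res.vif_flag

    def test_too_few_rows_rejected(self, small_derived):
        with pytest.raises(ValueError):
            adjusted_regression(small_derived.head(5), "bmc_tb_z",
                                "total_25ohd_ng_ml")


class TestTableSuite:
    def test_empty_cohort_structured_error(self):
        with pytest.raises(ValueError, match="empty"):
            run_table_suite(pd.DataFrame())

    def test_missing_panel_structured_error(self, small_cohort):
        with pytest.raises(ValueError, match="derive"):
            run_table_suite(small_cohort.drop(columns=["diplotype"]))

    def test_smoke_all_tables_populated(self, small_derived):
        rep = run_table_suite(small_derived)
        for name, table in rep.tables().items():
            assert not table.empty, name
        assert rep.n_total == len(small_derived)

    def test_stratified_regressions_use_stratum_n(self, small_derived):
        rep = run_table_suite(small_derived)
        reg = rep.regressions
        n_norm = (small_derived["bmi_category"] == "normal").sum()
        assert (reg.loc[reg["stratum"] == "normal", "n"] <= n_norm).all()

    def test_deterministic_report(self, small_derived, tmp_path):
        from vitdfree.io import write_report
        a = run_table_suite(small_derived)
        b = run_table_suite(small_derived)
        da, db = tmp_path / "a", tmp_path / "b"
        write_report(a, da)
        write_report(b, db)
        for f in sorted(p.name for p in da.iterdir()):
            assert (da / f).read_bytes() == (db / f).read_bytes()
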