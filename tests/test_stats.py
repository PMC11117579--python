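import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from _oracles import balanced_split_plot
from discmorph.stats import (
    absolute_error,
    classify_pcc,
    icc_absolute_agreement,
    paired_t,
    pearson_with_band,
    repeatability_report,
    simulate_ratio_table,
    split_plot_anova,
    tukey_hsd,
)


class TestPccBands:
    @pytest.mark.parametrize(
        "pcc, band",
        [
            (0.645, "Good"),
            (0.837, "Excellent"),
            (0.845, "Excellent"),
            (1.0, "Excellent"),
            (0.811, "Excellent"),
            (0.810, "Good"),      # gap value -> lower band
            (0.8095, "Good"),     # gap value -> lower band
            (0.809, "Good"),
            (0.610, "Good"),
            (0.6095, "Moderate"),  # gap value -> lower band
            (0.609, "Moderate"),
            (0.410, "Moderate"),
            (0.4095, "Fair"),      # gap value -> lower band
            (0.409, "Fair"),
            (0.210, "Fair"),
            (0.2095, "Poor"),      # gap value -> lower band
            (0.209, "Poor"),
            (0.0, "Poor"),
            (-0.5, "Poor"),
        ],
    )
    def test_cutpoints(self, pcc, band):
        assert classify_pcc(pcc) == band

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        pcc, band = pearson_with_band(x, x)
        assert pcc == pytest.approx(1.0)
        assert band == "Excellent"

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_band([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_invariant_under_positive_affine_transform(self, rng):
        x, y = rng.random(20), rng.random(20)
        p1, _ = pearson_with_band(x, y)
        p2, _ = pearson_with_band(3.0 * x + 7.0, y)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestPairedT:
    def test_identical_pairs(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        res = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.degenerate

    def test_matches_reference_implementation(self, rng):
        x, y = rng.normal(40, 5, 10), rng.normal(38, 5, 10)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t_stat == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_sign_flips_when_swapped(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.p_value == pytest.approx(b.p_value)


class TestAbsoluteError:
    def test_ten_percent_example(self):
        e, _ = absolute_error([40.0], [44.0])
        assert e[0] == pytest.approx(10.0)

    def test_zero_for_identical(self):
        e, summary = absolute_error([40.0, 35.0], [40.0, 35.0])
        assert (e == 0).all() and summary["mean"] == 0.0

    def test_asymmetric_by_definition(self):
        e_xy, _ = absolute_error([40.0], [50.0])
        e_yx, _ = absolute_error([50.0], [40.0])
        assert e_xy[0] != e_yx[0]

    def test_summary_matches_direct_recomputation(self, rng):
        x = rng.uniform(30, 50, 25)
        y = x + rng.normal(0, 3, 25)
        e, summary = absolute_error(x, y)
        ref = 100 * np.abs(x - y) / x
        assert np.allclose(e, ref)
        assert summary["mean"] == pytest.approx(ref.mean())
        assert summary["max"] == pytest.approx(ref.max())

    def test_zero_first_measurement_rejected(self):
        with pytest.raises(ValueError):
            absolute_error([0.0, 1.0], [1.0, 1.0])


class TestIcc:
    def test_identical_raters_give_one(self):
        table = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_absolute_agreement(table) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        table = rng.normal(0, 1, (200, 2))
        assert abs(icc_absolute_agreement(table)) < 0.15

    def test_worked_table_matches_reference(self):
        table = np.array(
            [[40.0, 42.0], [36.0, 37.0], [45.0, 44.0], [38.0, 40.0], [50.0, 48.0], [33.0, 35.0]]
        )
        import pingouin as pg

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 2),
                "rater": np.tile(["a", "b"], 6),
                "score": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_absolute_agreement(table) == pytest.approx(icc2, abs=1e-10)

    def test_missing_cells_rejected(self):
        table = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            icc_absolute_agreement(table)


class TestSplitPlotAnova:
    def test_matches_classical_balanced_decomposition(self):
        df = simulate_ratio_table(n_female=8, n_male=8, gender_effect=3.0, seed=5)
        ours = split_plot_anova(df)
        ref = balanced_split_plot(df, "ratio_percent", "gender", "disc_level", "subject_id")
        for effect, (ss, dof, F) in ref.items():
            assert ours.loc[effect, "sum_sq"] == pytest.approx(ss, abs=1e-8)
            assert ours.loc[effect, "df"] == dof
            if F is not None:
                assert ours.loc[effect, "F"] == pytest.approx(F, abs=1e-8)

    def test_location_invariance(self):
        df = simulate_ratio_table(seed=6)
        shifted = df.assign(ratio_percent=df["ratio_percent"] + 100.0)
        a, b = split_plot_anova(df), split_plot_anova(shifted)
        assert np.allclose(a["F"].dropna(), b["F"].dropna())

    def test_detects_strong_gender_shift(self):
        hits = 0
        n_sim = 200
        for i in range(n_sim):
            df = simulate_ratio_table(
                n_female=30, n_male=30, gender_effect=5.0,
                subject_sd=2.0, resid_sd=2.0, seed=50_000 + i,
            )
            if split_plot_anova(df).loc["gender", "p_value"] < 0.001:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_incomplete_subject_rejected(self):
        df = simulate_ratio_table(seed=7)
        with pytest.raises(ValueError):
            split_plot_anova(df.iloc[:-1])


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        g = {"a": np.arange(10.0), "b": np.arange(10.0), "c": np.arange(10.0)}
        res = tukey_hsd(g)
        assert not res["reject"].any()

    def test_two_groups_equal_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.6, 1, 15)
        res = tukey_hsd({"a": a, "b": b})
        _, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert res["p_adj"].iloc[0] == pytest.approx(p_ref, abs=1e-8)

    def test_matches_scipy_reference(self, rng):
        groups = [rng.normal(m, 1.0, 14) for m in (0.0, 0.0, 1.0)]
        res = tukey_hsd({"g0": groups[0], "g1": groups[1], "g2": groups[2]})
        ref = sps.tukey_hsd(*groups)
        for _, row in res.iterrows():
            i, j = int(row["group1"][1]), int(row["group2"][1])
            assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_only_shifted_group_flagged(self):
        rng = np.random.default_rng(9)
        good = 0
        n_sim = 200
        for _ in range(n_sim):
            g = {
                "a": rng.normal(0, 1, 20),
                "b": rng.normal(0, 1, 20),
                "c": rng.normal(2.0, 1, 20),
            }
            res = tukey_hsd(g)
            flagged = {
                frozenset((r["group1"], r["group2"]))
                for _, r in res.iterrows()
                if r["reject"]
            }
            if flagged == {frozenset(("a", "c")), frozenset(("b", "c"))}:
                good += 1
        assert good / n_sim >= 0.90

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestRepeatabilityReport:
    def test_report_consistency(self, rng):
        x = rng.uniform(30, 50, 21)
        y = x + rng.normal(0, 4, 21)
        rep = repeatability_report(x, y)
        assert rep.pcc_band == classify_pcc(rep.pcc)
        assert rep.abs_error_min <= rep.abs_error_mean <= rep.abs_error_max
        assert -1 <= rep.icc <= 1
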