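"""pH calibration, scalar estimators and nested statistics vs oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lysoquant import (
    ValidationError,
    aggregate_per_animal,
    dab_area_fraction,
    fit_ph_curve,
    fractionator_estimate,
    kruskal_dunn,
    nested_t,
    normalize_cytosolic_activity,
    percent_of_control,
    ratio_to_ph,
    simulate_grouped_measurements,
    simulate_ph_table,
    two_way_anova,
    unpaired_t,
)


class TestPhCalibration:
    def test_exact_linear_data_recovered_exactly(self):
        table = simulate_ph_table(-0.5, 4.0, noise_cv=0.0)
        curve = fit_ph_curve(table)
        assert curve.slope == pytest.approx(-0.5, abs=1e-12)
        assert curve.intercept == pytest.approx(4.0, abs=1e-12)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_standard_range_accepted(self):
        curve = fit_ph_curve(simulate_ph_table(-0.5, 4.0, noise_cv=0.0))
        assert curve.fit_range_ph == (3.5, 7.0)

    def test_single_level_rejected(self):
        bad = pd.DataFrame({"ph": [5.0] * 6, "ratio": [1.5] * 6})
        with pytest.raises(ValidationError):
            fit_ph_curve(bad)

    def test_narrow_span_rejected(self):
        bad = pd.DataFrame({"ph": [5.0, 5.2, 5.4], "ratio": [1.0, 0.9, 0.8]})
        with pytest.raises(ValidationError):
            fit_ph_curve(bad)

    def test_noisy_recovery_slope_within_five_percent(self):
        table = simulate_ph_table(-0.5, 4.0, noise_cv=0.01, seed=3)
        curve = fit_ph_curve(table)
        assert curve.slope == pytest.approx(-0.5, rel=0.05)

    def test_ratio_to_ph_inverts_curve(self):
        table = simulate_ph_table(-0.5, 4.0, noise_cv=0.0)
        curve = fit_ph_curve(table)
        assert ratio_to_ph(curve, 2.0) == pytest.approx(4.0, abs=1e-12)
        for ph in np.arange(3.5, 7.01, 0.5):
            assert ratio_to_ph(curve, float(curve.predict_ratio(ph))) == pytest.approx(
                ph, abs=1e-12
            )

    def test_extrapolation_flagged(self):
        curve = fit_ph_curve(simulate_ph_table(-0.5, 4.0, noise_cv=0.0))
        with pytest.warns(UserWarning, match="extrapolat"):
            ratio_to_ph(curve, curve.predict_ratio(2.5))


class TestScalarEstimators:
    def test_activity_normalization_arithmetic(self):
        assert normalize_cytosolic_activity(3.0, 2.0) == pytest.approx(1.5)
        assert normalize_cytosolic_activity(0.0, 2.0) == 0.0
        assert normalize_cytosolic_activity(2.0, 2.0) == 1.0
        with pytest.raises(ValidationError):
            normalize_cytosolic_activity(1.0, 0.0)

    def test_percent_of_control(self):
        out = percent_of_control([1.0, 2.0], control_mean=2.0)
        np.testing.assert_allclose(out, [50.0, 100.0])

    def test_fractionator_identities(self):
        assert fractionator_estimate(100, 1.0, 1.0, 1.0) == 100
        assert fractionator_estimate(100, 0.25, 1.0, 1.0) == 400
        assert fractionator_estimate(200, 0.25, 1.0, 1.0) == 2 * fractionator_estimate(
            100, 0.25, 1.0, 1.0
        )
        with pytest.raises(ValidationError):
            fractionator_estimate(100, 0.0)

    def test_dab_area_fraction_identities(self):
        # animal equal to its contralateral side and to the control mean
        assert dab_area_fraction(10, 100, 0.1, 1.0) == pytest.approx(100.0)
        assert dab_area_fraction(5, 100, 0.1, 1.0) == pytest.approx(50.0)
        # scale invariance in the areas
        a = dab_area_fraction(7, 50, 0.2, 0.7)
        b = dab_area_fraction(7 * 13, 50 * 13, 0.2, 0.7)
        assert a == pytest.approx(b, rel=1e-12)
        with pytest.raises(ValidationError):
            dab_area_fraction(1, 0, 0.1, 1.0)


def _balanced_2x2():
    """Hand-checkable 2x2 design, 2 observations per cell."""
    return pd.DataFrame(
        {
            "factor_a": ["x"] * 4 + ["y"] * 4,
            "factor_b": ["u", "u", "v", "v"] * 2,
            "value": [1.0, 2.0, 4.0, 6.0, 3.0, 5.0, 9.0, 11.0],
        }
    )


class TestTwoWayAnova:
    def test_constant_data_gives_zero_f(self):
        df = _balanced_2x2().assign(value=5.0)
        for res in two_way_anova(df):
            assert res.statistic == 0.0
            assert res.p_value == 1.0

    def test_hand_computed_sums_of_squares(self):
        # SSA=28.125, SSB=45.125, SSAB=3.125, SSE=6.5 (df=4) -> MSE=1.625
        res = {r.effect: r for r in two_way_anova(_balanced_2x2())}
        assert res["factor_a"].statistic == pytest.approx(28.125 / 1.625, abs=1e-10)
        assert res["factor_b"].statistic == pytest.approx(45.125 / 1.625, abs=1e-10)
        assert res["interaction"].statistic == pytest.approx(3.125 / 1.625, abs=1e-10)
        assert res["factor_a"].df == (1.0, 4.0)

    def test_matches_regression_route_on_balanced_data(self, rng):
        df = pd.DataFrame(
            {
                "factor_a": np.repeat(["x", "y"], 10),
                "factor_b": np.tile(np.repeat(["u", "v"], 5), 2),
                "value": rng.normal(size=20),
            }
        )
        bal = {r.effect: r.statistic for r in two_way_anova(df, method="balanced")}
        reg = {r.effect: r.statistic for r in two_way_anova(df, method="regression")}
        for k in bal:
            assert bal[k] == pytest.approx(reg[k], abs=1e-8)

    def test_unbalanced_data_falls_back_to_regression(self, rng):
        df = pd.DataFrame(
            {
                "factor_a": ["x"] * 5 + ["y"] * 7,
                "factor_b": ["u", "v", "u", "v", "u"] + ["v", "u", "v", "u", "v", "u", "v"],
                "value": rng.normal(size=12),
            }
        )
        res = two_way_anova(df)  # auto
        assert all(r.info["method"] == "regression_type2" for r in res)
        with pytest.raises(ValidationError):
            two_way_anova(df, method="balanced")

    def test_missing_design_cell_rejected_with_advice(self):
        df = _balanced_2x2()
        df = df[~((df.factor_a == "y") & (df.factor_b == "v"))]
        with pytest.raises(ValidationError, match="regression"):
            two_way_anova(df)

    def test_tukey_table_covers_all_cell_pairs(self):
        res = two_way_anova(_balanced_2x2(), tukey=True)
        ph = res[0].posthoc
        assert len(ph) == 6  # C(4,2) design-cell pairs
        assert ph["p_adjusted"].between(0, 1).all()


class TestNestedT:
    def test_identical_animal_means_give_zero_t(self):
        df = simulate_grouped_measurements(
            n_groups=2, animals_per_group=3, cells_per_animal=4,
            sd_between_animal=0.0, sd_within_animal=0.0, group_means=[2.0, 2.0],
        )
        res = nested_t(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_equals_unpaired_t_on_animal_means(self):
        df = simulate_grouped_measurements(seed=5, group_means=[0.0, 1.0])
        res = nested_t(df)
        pa = aggregate_per_animal(df)
        t, p = stats.ttest_ind(
            pa.loc[pa.group == "g0", "mean"], pa.loc[pa.group == "g1", "mean"]
        )
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.df == (14.0,)  # 8 + 8 - 2 animals

    def test_cell_level_noise_cannot_change_balanced_statistic(self, rng):
        df = simulate_grouped_measurements(
            seed=6, group_means=[0.0, 1.0], cells_per_animal=10
        )
        base = nested_t(df).statistic
        # add noise that cancels within each animal: animal means unchanged
        bump = np.zeros(len(df))
        bump[0::2] = 5.0
        bump[1::2] = -5.0
        noisy = df.assign(value=df["value"] + bump)
        assert nested_t(noisy).statistic == pytest.approx(base, abs=1e-10)

    def test_single_animal_group_rejected(self):
        df = simulate_grouped_measurements(n_groups=2, animals_per_group=1)
        with pytest.raises(ValidationError, match="animals"):
            nested_t(df)

    def test_nesting_is_conservative_under_animal_level_variance(self):
        # with strong between-animal variance, treating cells as independent
        # overstates evidence: naive cell-level p is smaller on average
        naive_p, nested_p = [], []
        for seed in range(60):
            df = simulate_grouped_measurements(
                n_groups=2, animals_per_group=4, cells_per_animal=10,
                sd_between_animal=3.0, sd_within_animal=0.5, seed=seed,
            )
            a = df.loc[df.group == "g0", "value"]
            b = df.loc[df.group == "g1", "value"]
            naive_p.append(stats.ttest_ind(a, b).pvalue)
            nested_p.append(nested_t(df).p_value)
        assert np.mean(naive_p) < np.mean(nested_p)


class TestUnpairedT:
    def test_identical_samples_give_zero(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        res = unpaired_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res.p_value < 1e-6

    def test_matches_direct_formula(self):
        a = np.array([1.2, 3.4, 2.2, 4.1])
        b = np.array([2.0, 5.5, 4.4])
        res = unpaired_t(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res.statistic == pytest.approx(t, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValidationError):
            unpaired_t([1.0, 1.0], [2.0, 2.0])


class TestAggregatePerAnimal:
    def test_one_cell_per_animal_is_identity(self):
        df = simulate_grouped_measurements(
            n_groups=1, animals_per_group=3, cells_per_animal=1, seed=2
        )
        out = aggregate_per_animal(df)
        np.testing.assert_allclose(np.sort(out["mean"]), np.sort(df["value"]))

    def test_simple_mean(self):
        df = pd.DataFrame(
            {"group": ["g"] * 2, "animal": ["a"] * 2, "value": [2.0, 4.0]}
        )
        out = aggregate_per_animal(df)
        assert out["mean"].iloc[0] == 3.0
        assert out["n_cells"].iloc[0] == 2

    def test_row_order_irrelevant(self):
        df = simulate_grouped_measurements(seed=9)
        shuffled = df.sample(frac=1.0, random_state=0)
        a = aggregate_per_animal(df).sort_values("animal").reset_index(drop=True)
        b = aggregate_per_animal(shuffled).sort_values("animal").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestKruskalDunn:
    def test_omnibus_matches_scipy(self, rng):
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 10),
                "value": rng.normal(size=30),
            }
        )
        res = kruskal_dunn(df)
        h, p = stats.kruskal(*[df.loc[df.group == g, "value"] for g in ("a", "b", "c")])
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)
        assert len(res.posthoc) == 3
        assert res.posthoc["p_adjusted"].between(0, 1).all()

    def test_separated_groups_detected(self):
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], 12),
                "value": np.concatenate([np.arange(12.0), np.arange(12.0) + 100]),
            }
        )
        res = kruskal_dunn(df)
        assert res.p_value < 0.01
        assert res.posthoc["p_adjusted"].iloc[0] < 0.05
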