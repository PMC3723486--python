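"""Interaction regression: OLS/logistic oracles, strata, ls-means."""

import numpy as np
import pandas as pd
import pytest

from gxepower import (
    BMIInteractionModel,
    CohortSpec,
    ObesityModel,
    beta_to_weight,
    classify_bmi,
    dichotomize_grs,
    lsmeans_by_group,
    simulate_cohort,
    stratified_effects,
)


def _tiny_dataset():
    """Six rows, full rank, hand-checkable."""
    return pd.DataFrame({
        "grs": [8.0, 10.0, 12.0, 9.0, 11.0, 13.0],
        "activity_binary": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
        "bmi": [26.1, 27.0, 27.8, 24.9, 25.2, 25.9],
    })


class TestOLSOracle:
    def test_coefficients_match_normal_equations(self):
        data = _tiny_dataset()
        model = BMIInteractionModel(data, covariates=(), center=None,
                                    min_cases=6)
        oracle = np.linalg.solve(
            model.exog.T @ model.exog, model.exog.T @ model.endog)
        fitted = model.fit()
        assert np.allclose(fitted.params.to_numpy(), oracle, atol=1e-10)

    def test_null_interaction_recovered(self):
        cohort = simulate_cohort(
            CohortSpec(n_participants=50_000, beta_ge=0.0, seed=31))
        res = BMIInteractionModel.from_cohort(cohort).fit()
        est, se, _ = res.term("grs:activity_binary")
        assert abs(est) < 3 * se

    def test_age_centered_before_squaring(self, base_cohort):
        model = BMIInteractionModel.from_cohort(base_cohort)
        assert "age_c_sq" in model.exog.columns
        assert abs(model.exog["age_c"].mean()) < 1e-8

    def test_single_center_term_dropped_with_warning(self, base_cohort):
        with pytest.warns(UserWarning, match="center"):
            model = BMIInteractionModel.from_cohort(base_cohort,
                                                    center="cohort_id")
        assert not any(c.startswith("center_") for c in model.exog.columns)

    def test_min_cases_enforced(self):
        with pytest.raises(ValueError, match="complete cases"):
            BMIInteractionModel(_tiny_dataset(), covariates=(), center=None)


class TestObesityLogistic:
    def test_or_matches_cross_product_ratio(self):
        # 2x2 table (exposed x obese/normal) = (30, 70, 20, 80)
        rows = []
        for exposed, obese, count in [(1, 1, 30), (1, 0, 70),
                                      (0, 1, 20), (0, 0, 80)]:
            rows += [{"grs": float(exposed),
                      "bmi": 32.0 if obese else 22.0}] * count
        model = ObesityModel(pd.DataFrame(rows), covariates=(), center=None)
        res = model.fit()
        or_table = res.odds_ratios()
        assert or_table.loc["grs", "OR"] == pytest.approx(
            (30 * 80) / (70 * 20), abs=1e-4)

    def test_zero_effect_gives_unit_or(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({
            "grs": rng.normal(11, 2, 4000),
            "bmi": np.where(rng.random(4000) < 0.3, 32.0, 22.0),
        })
        res = ObesityModel(data, covariates=(), center=None).fit()
        est, se, _ = res.term("grs")
        assert abs(est) < 3 * se

    def test_overweight_excluded_from_contrast(self):
        data = pd.DataFrame({
            "grs": np.tile([0.0, 1.0], 100),
            "bmi": np.tile([22.0, 27.0, 32.0, 22.0], 50),
        })
        model = ObesityModel(data, covariates=(), center=None)
        assert model.n_obese + model.n_normal == len(model.data)
        assert (classify_bmi(model.data["bmi"]) != "overweight").all()

    def test_complete_separation_diagnosed(self):
        data = pd.DataFrame({
            "grs": np.repeat([0.0, 1.0], 60),
            "bmi": np.repeat([22.0, 32.0], 60),
        })
        with pytest.raises(ValueError, match="separation"):
            ObesityModel(data, covariates=(), center=None).fit()

    @pytest.mark.parametrize("bmi,category", [
        (18.4, "underweight"), (18.5, "normal"), (24.999, "normal"),
        (25.0, "overweight"), (29.999, "overweight"), (30.0, "obese"),
    ])
    def test_half_open_classification_boundaries(self, bmi, category):
        assert classify_bmi([bmi]).iloc[0] == category


class TestWeightConversion:
    def test_linearity_before_rounding(self):
        a, b = 0.11, 0.07
        assert beta_to_weight(a + b) == pytest.approx(
            beta_to_weight(a) + beta_to_weight(b))

    def test_zero_maps_to_zero(self):
        assert beta_to_weight(0.0) == 0.0

    def test_height_must_be_positive(self):
        with pytest.raises(ValueError):
            beta_to_weight(0.1, height=0.0)


class TestStratifiedEffects:
    def test_slope_difference_matches_saturated_interaction(self, base_cohort):
        d = base_cohort.data
        table = stratified_effects(d, covariates=(), center=None)
        diff = table.loc[table["stratum"] == "difference", "beta_g"].iloc[0]
        res = BMIInteractionModel(d, covariates=(), center=None).fit()
        est, _, _ = res.term("grs:activity_binary")
        # saturated in activity: stratum slope difference == interaction beta
        assert diff == pytest.approx(est, abs=1e-10)

    def test_recovers_generating_interaction(self):
        cohort = simulate_cohort(CohortSpec(n_participants=100_000, seed=41))
        table = stratified_effects(cohort.data, covariates=(), center=None)
        row = table[table["stratum"] == "difference"].iloc[0]
        assert abs(row["beta_g"] - (-0.07)) < 3 * row["se"]

    def test_negative_interaction_orders_strata(self):
        # inactive-stratum genetic effect exceeds the active-stratum effect
        cohort = simulate_cohort(CohortSpec(n_participants=150_000, seed=43))
        table = stratified_effects(cohort.data, covariates=(), center=None)
        slopes = table.set_index("stratum")["beta_g"]
        assert slopes[0.0] > slopes[1.0]

    def test_small_stratum_omitted_with_warning(self):
        d = _tiny_dataset()
        big = pd.concat([d] * 20, ignore_index=True)
        big.loc[big.index[-3:], "activity_binary"] = 2.0
        with pytest.warns(UserWarning, match="omitted"):
            table = stratified_effects(big, covariates=(), center=None)
        assert 2.0 not in set(table["stratum"])


class TestLSMeans:
    @staticmethod
    def _prepared(n=60_000, seed=47):
        cohort = simulate_cohort(CohortSpec(n_participants=n, seed=seed))
        d = cohort.data.copy()
        d["grs_binary"] = dichotomize_grs(d["grs"], cut=11.2)
        return d

    def test_no_covariates_equals_raw_cell_means(self):
        d = self._prepared(n=5_000)
        out = lsmeans_by_group(d, "grs_binary", "activity_binary", covariates=())
        for (g, a), cell in [((0, 0), "g0_a0"), ((1, 1), "g1_a1")]:
            raw = d.loc[(d["grs_binary"] == g) & (d["activity_binary"] == a),
                        "bmi"].mean()
            assert out["cell_means"].loc[cell, "mean"] == pytest.approx(raw)

    def test_adjusted_means_recover_generating_cells(self):
        d = self._prepared()
        out = lsmeans_by_group(d, "grs_binary", "activity_binary")
        # high-GRS inactive cell mean must exceed low-GRS inactive cell mean
        cm = out["cell_means"]
        assert cm.loc["g1_a0", "mean"] > cm.loc["g0_a0", "mean"]
        for cell in cm.index:
            g, a = int(cell[1]), int(cell[4])
            sub = d[(d["grs_binary"] == g) & (d["activity_binary"] == a)]
            assert abs(cm.loc[cell, "mean"] - sub["bmi"].mean()) < 3 * cm.loc[cell, "se"]

    def test_interaction_widens_inactive_gap(self):
        # beta_GE < 0: high-vs-low GRS BMI gap larger among the inactive
        d = self._prepared(n=150_000, seed=49)
        out = lsmeans_by_group(d, "grs_binary", "activity_binary")
        gaps = out["grs_differences"]
        assert gaps["activity=0"]["difference"] > gaps["activity=1"]["difference"]

    def test_empty_cell_rejected(self):
        d = self._prepared(n=2_000)
        d = d[~((d["grs_binary"] == 1) & (d["activity_binary"] == 0))]
        with pytest.raises(ValueError, match="empty"):
            lsmeans_by_group(d, "grs_binary", "activity_binary", covariates=())
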