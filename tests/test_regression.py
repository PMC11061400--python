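"""Feature table assembly, exhaustive best-subset search, OLS inference."""

from math import comb

import numpy as np
import pandas as pd
import pytest

import strokesyn as ss
from strokesyn.regression import (
    PREDICTORS, build_feature_table, exhaustive_subset_search,
    fit_linear_model, predict_scores,
)

# the four coefficients and intercept of the published patient model
PUBLISHED = {"intercept": -200.24, "C_V_af": 133.49, "LI_PMC_un": 30.33,
             "F_r": 45.95, "C_V_r": 83.70}


def make_per_arm(subject_id, values_af, values_un, mvc_af=100.0, mvc_un=150.0):
    rows = []
    for arm, vals, mvc in (("affected", values_af, mvc_af),
                           ("unaffected", values_un, mvc_un)):
        rows.append({"subject_id": subject_id, "arm": arm, "mvc": mvc, **vals})
    return rows


IDX = dict(ssi=0.9, c_v=0.8, c_t=0.85, li_pmc=0.3, li_m1=0.25, li_s1=0.2)


class TestFeatureTable:
    def _table(self):
        per_arm = pd.DataFrame(
            make_per_arm("P01", IDX, dict(ssi=0.95, c_v=0.9, c_t=0.9,
                                          li_pmc=0.45, li_m1=0.3, li_s1=0.25))
            + make_per_arm("C01", IDX, IDX, mvc_af=120.0, mvc_un=120.0))
        subjects = pd.DataFrame([
            {"subject_id": "P01", "group": "patient", "age": 60.0,
             "days_post_stroke": 100.0, "fmul": 40},
            {"subject_id": "C01", "group": "control", "age": 55.0,
             "days_post_stroke": 999.0, "fmul": np.nan},
        ])
        return build_feature_table(per_arm, subjects)

    def test_exactly_21_predictor_columns(self):
        table = self._table()
        assert len(PREDICTORS) == 21
        assert [c for c in table.columns
                if c not in ("subject_id", "group", "FMul")] == list(PREDICTORS)

    def test_identical_arms_give_unit_ratios(self):
        table = self._table()
        ctl = table[table.subject_id == "C01"].iloc[0]
        for r in ("LI_PMC_r", "SSI_r", "C_V_r", "C_T_r", "F_r"):
            assert ctl[r] == pytest.approx(1.0)

    def test_ratio_hand_arithmetic(self):
        table = self._table()
        pat = table[table.subject_id == "P01"].iloc[0]
        assert pat["C_V_r"] == pytest.approx(0.9 / 0.8)
        assert pat["F_r"] == pytest.approx(1.5)
        assert pat["LI_PMC_r"] == pytest.approx(0.45 / 0.3)

    def test_controls_days_post_stroke_zeroed(self):
        table = self._table()
        assert table[table.subject_id == "C01"].iloc[0]["days_post_stroke"] == 0.0

    def test_zero_affected_value_propagates_missing(self):
        per_arm = pd.DataFrame(make_per_arm(
            "P02", dict(IDX, c_v=0.0), IDX))
        subjects = pd.DataFrame([{"subject_id": "P02", "group": "patient",
                                  "age": 50.0, "days_post_stroke": 30.0,
                                  "fmul": 30}])
        table = build_feature_table(per_arm, subjects)
        assert np.isnan(table.iloc[0]["C_V_r"])


class TestFitLinearModel:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"x": x, "FMul": 2.0 * x})
        res = fit_linear_model(table, ["x"])
        assert res.B[0] == pytest.approx(0.0, abs=1e-10)
        assert res.B[1] == pytest.approx(2.0)
        assert res.r2_adj == pytest.approx(1.0)

    def test_three_point_normal_equations(self):
        # x = {0,1,2}, y = {1,2,4}: Sxy = 3, Sxx = 2 -> slope 3/2;
        # intercept = ybar - slope*xbar = 7/3 - 3/2 = 5/6
        table = pd.DataFrame({"x": [0.0, 1.0, 2.0], "FMul": [1.0, 2.0, 4.0]})
        res = fit_linear_model(table, ["x"])
        assert res.B[1] == pytest.approx(1.5)
        assert res.B[0] == pytest.approx(5.0 / 6.0)

    def test_null_model_p_values_uniform(self):
        from scipy.stats import kstest
        pvals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            table = pd.DataFrame({"x": r.standard_normal(25),
                                  "FMul": r.standard_normal(25)})
            pvals.append(fit_linear_model(table, ["x"]).p_model)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_predictors_rejected(self):
        x = np.arange(12.0)
        table = pd.DataFrame({"a": x, "b": 2.0 * x, "FMul": x + 1.0})
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_model(table, ["a", "b"])


class TestExhaustiveSearch:
    def test_enumerates_all_5985_models(self, mini_cohort):
        cfg = ss.SimulationConfig(n_patients=12, n_controls=0, seed=31)
        profiles, truths = ss.generate_cohort(cfg)
        table = ss.implied_feature_frame(profiles, truths)
        res = exhaustive_subset_search(table, subset_size=4,
                                       predictors=PREDICTORS)
        assert comb(21, 4) == 5985
        assert res.n_models_evaluated == 5985

    def test_planted_subset_recovered_single_seed(self):
        cfg = ss.SimulationConfig(n_patients=30, n_controls=0, seed=0,
                                  fmul_noise_sd=0.5)
        profiles, truths = ss.generate_cohort(cfg)
        table = ss.implied_feature_frame(profiles, truths)
        res = exhaustive_subset_search(table, subset_size=4,
                                       predictors=PREDICTORS)
        assert set(res.selected) == {"C_V_af", "LI_PMC_un", "F_r", "C_V_r"}

    def test_duplicated_response_dominates(self):
        r = np.random.default_rng(2)
        cols = {f"x{i}": r.standard_normal(20) for i in range(8)}
        y = r.standard_normal(20)
        table = pd.DataFrame({**cols, "leak": y, "FMul": y})
        res = exhaustive_subset_search(table, subset_size=2,
                                       predictors=list(cols) + ["leak"])
        assert "leak" in res.selected

    def test_invariant_to_predictor_column_order(self):
        cfg = ss.SimulationConfig(n_patients=20, n_controls=0, seed=17)
        profiles, truths = ss.generate_cohort(cfg)
        table = ss.implied_feature_frame(profiles, truths)
        res1 = exhaustive_subset_search(table, predictors=PREDICTORS)
        res2 = exhaustive_subset_search(table, predictors=PREDICTORS[::-1])
        assert set(res1.selected) == set(res2.selected)

    def test_winner_beats_every_single_predictor(self):
        cfg = ss.SimulationConfig(n_patients=25, n_controls=0, seed=23)
        profiles, truths = ss.generate_cohort(cfg)
        table = ss.implied_feature_frame(profiles, truths).dropna()
        res = exhaustive_subset_search(table, predictors=PREDICTORS)
        for p in PREDICTORS:
            single = fit_linear_model(table, [p])
            assert res.r2_adj >= single.r2_adj - 1e-12

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({p: np.arange(4.0) for p in PREDICTORS}
                             | {"FMul": np.arange(4.0)})
        with pytest.raises(ValueError, match="rows"):
            exhaustive_subset_search(table)


class TestPredictScores:
    def test_published_coefficients_match_hand_arithmetic(self):
        """Applying the published model to a stored feature row reproduces
        the longhand linear combination."""
        from strokesyn.regression import RegressionResult
        row = pd.DataFrame([{"C_V_af": 0.82, "LI_PMC_un": 0.31,
                             "F_r": 1.42, "C_V_r": 1.18}])
        model = RegressionResult(
            selected=("C_V_af", "LI_PMC_un", "F_r", "C_V_r"),
            B=np.array([PUBLISHED["intercept"], PUBLISHED["C_V_af"],
                        PUBLISHED["LI_PMC_un"], PUBLISHED["F_r"],
                        PUBLISHED["C_V_r"]]),
            beta_std=np.zeros(4), p_coef=np.zeros(4), p_model=0.0,
            r2=0.0, r2_adj=0.0, n_obs=15)
        fitted, n_above = predict_scores(model, row)
        by_hand = (-200.24 + 133.49 * 0.82 + 30.33 * 0.31 + 45.95 * 1.42
                   + 83.70 * 1.18)
        assert fitted.iloc[0] == pytest.approx(by_hand, abs=1e-9)

    def test_fitted_patients_match_observed_within_residuals(self):
        cfg = ss.SimulationConfig(n_patients=20, n_controls=0, seed=19,
                                  fmul_noise_sd=0.5)
        profiles, truths = ss.generate_cohort(cfg)
        table = ss.implied_feature_frame(profiles, truths)
        res = exhaustive_subset_search(table, predictors=PREDICTORS)
        fitted, _ = predict_scores(res, table)
        resid = table["FMul"] - fitted
        assert np.sqrt(np.mean(resid**2)) < 3.0

    def test_count_above_threshold(self):
        from strokesyn.regression import RegressionResult
        model = RegressionResult(selected=("x",), B=np.array([0.0, 1.0]),
                                 beta_std=np.zeros(1), p_coef=np.zeros(1),
                                 p_model=0.0, r2=0.0, r2_adj=0.0, n_obs=5)
        table = pd.DataFrame({"x": [10.0, 65.0, 70.0, 61.0]})
        _, n_above = predict_scores(model, table, threshold=60.0)
        assert n_above == 3
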