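"""Design coding, OLS and IRLS-logistic inference against closed forms and
statsmodels oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as st

from mitoquant.regression import (
    CollinearityError,
    DEFAULT_LINEAR_FEATURES,
    DEFAULT_LINEAR_INTERACTIONS,
    ENDPOINTS,
    build_design,
    feature_screen,
    fit_linear,
    fit_logistic,
    fit_ratio_model,
    run_endpoint_models,
)
from mitoquant.simulate import (
    CohortEffectSpec,
    simulate_timelapse_cohort,
    simulate_transfer_cohort,
)


class TestBuildDesign:
    def test_intercept_only(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        d = build_design(df, features=[], response="y")
        assert d.columns == ["intercept"]
        assert d.X.shape == (3, 1)

    def test_binary_and_grade_codings(self):
        df = pd.DataFrame(
            {"gender": ["male", "female", "male"],
             "te_grade": ["C", "B", "A"],
             "oocyte_source": ["self", "donor", "self"]}
        )
        d = build_design(df, features=["gender", "te_grade", "oocyte_source"])
        assert list(d.X[:, 1]) == [1.0, 0.0, 1.0]
        assert list(d.X[:, 2]) == [1.0, 2.0, 3.0]
        assert list(d.X[:, 3]) == [0.0, 1.0, 0.0]

    def test_interaction_is_product_of_coded_columns(self):
        df = pd.DataFrame({"gender": ["male", "female", "male", "female"],
                           "t": [1.0, 2.0, 3.0, 4.0]})
        d = build_design(df, features=["gender", "t"], interactions=[("gender", "t")])
        assert d.columns[-1] == "gender:t"
        np.testing.assert_allclose(d.X[:, -1], [1.0, 0.0, 3.0, 0.0])

    def test_interaction_with_constant_flagged_collinear(self):
        df = pd.DataFrame({"f": [0.0, 1.0, 0.0, 1.0], "c": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(CollinearityError) as err:
            build_design(df, features=["f", "c"], interactions=[("f", "c")])
        assert len(err.value.columns) > 0

    def test_missing_rows_dropped_and_counted(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0], "y": [1.0, 2.0, np.nan]})
        d = build_design(df, features=["x"], response="y")
        assert d.n_used == 1 and d.n_dropped == 2

    def test_unknown_level_rejected(self):
        df = pd.DataFrame({"gender": ["male", "unknown"]})
        with pytest.raises(ValueError, match="unknown levels"):
            build_design(df, features=["gender"])


class TestLinear:
    def test_matches_normal_equation_closed_form(self, rng):
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        beta = np.array([1.0, -2.0, 0.5])
        y = X @ beta + rng.normal(size=n)
        df = pd.DataFrame({"x1": X[:, 1], "x2": X[:, 2], "y": y})
        res = fit_linear(build_design(df, ["x1", "x2"], response="y"))
        closed = np.linalg.solve(X.T @ X, X.T @ y)
        ours = np.array([t.estimate for t in res.terms])
        assert np.max(np.abs(ours - closed) / np.maximum(np.abs(closed), 1)) < 1e-10

    def test_single_covariate_matches_cov_over_var(self, rng):
        x = rng.normal(size=50)
        y = 2.0 + 0.7 * x + rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": y})
        res = fit_linear(build_design(df, ["x"], response="y"))
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.term("x").estimate == pytest.approx(slope, rel=1e-12)

    def test_inference_matches_statsmodels(self, rng):
        n = 80
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        df["y"] = 1 + df["a"] - 0.5 * df["b"] + rng.normal(size=n)
        d = build_design(df, ["a", "b"], response="y")
        ours = fit_linear(d)
        ref = sm.OLS(d.y, d.X).fit()
        np.testing.assert_allclose([t.se for t in ours.terms], ref.bse, rtol=1e-10)
        np.testing.assert_allclose([t.p_value for t in ours.terms], ref.pvalues,
                                   rtol=1e-9)
        ci = ref.conf_int()
        np.testing.assert_allclose([t.ci_low for t in ours.terms], ci[:, 0], rtol=1e-9)

    def test_exact_fit_flagged_degenerate_with_zero_se(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "y": 3.0 + 2.0 * x})
        res = fit_linear(build_design(df, ["x"], response="y"))
        assert res.degenerate
        assert res.term("x").estimate == pytest.approx(2.0)
        assert res.term("x").se == 0.0

    def test_underdetermined_fit_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="more observations"):
            fit_linear(build_design(df, ["x"], response="y"))

    def test_negative_teb_effect_detected_at_cohort_scale(self):
        """With the generating tEB coefficient negative, the fitted CI
        excludes zero on the negative side in nearly all seeded cohorts."""
        hits = 0
        runs = 40
        for seed in range(runs):
            records = simulate_timelapse_cohort(CohortEffectSpec(n=307, seed=seed))
            res = fit_ratio_model(records, features=DEFAULT_LINEAR_FEATURES)
            term = res.term("tEB")
            hits += term.ci_high < 0
        assert hits / runs >= 0.9


class TestLogistic:
    def test_two_by_two_matches_cross_product_odds_ratio(self):
        # exposure x outcome counts: a=40 d=30, b=20, c=10
        a, b, c, d = 40, 20, 10, 30
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
        df = pd.DataFrame({"x": x, "y": y})
        res = fit_logistic(build_design(df, ["x"], response="y"))
        term = res.term("x")
        assert term.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)
        assert term.se == pytest.approx(math.sqrt(1/a + 1/b + 1/c + 1/d), rel=1e-6)

    def test_intercept_only_recovers_success_fraction(self):
        y = np.array([1.0] * 7 + [0.0] * 13)
        df = pd.DataFrame({"y": y})
        res = fit_logistic(build_design(df, [], response="y"))
        p_hat = 1 / (1 + math.exp(-res.term("intercept").estimate))
        assert p_hat == pytest.approx(7 / 20, rel=1e-8)

    def test_matches_statsmodels_mle(self, rng):
        n = 400
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        eta = -0.3 + 0.8 * df["a"] - 0.4 * df["b"]
        df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        d = build_design(df, ["a", "b"], response="y")
        ours = fit_logistic(d)
        ref = sm.Logit(d.y, d.X).fit(disp=0)
        np.testing.assert_allclose([t.estimate for t in ours.terms], ref.params,
                                   atol=1e-8)
        np.testing.assert_allclose([t.se for t in ours.terms], ref.bse, rtol=1e-6)

    def test_deviance_path_non_increasing(self, rng):
        n = 300
        df = pd.DataFrame({"a": rng.normal(size=n)})
        df["y"] = (rng.random(n) < 0.5).astype(float)
        res = fit_logistic(build_design(df, ["a"], response="y"))
        path = np.array(res.deviance_path)
        assert (np.diff(path) <= 1e-9).all()

    def test_complete_separation_flagged_not_converged(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0) + 20])
        y = np.array([0.0] * 10 + [1.0] * 10)
        df = pd.DataFrame({"x": x, "y": y})
        res = fit_logistic(build_design(df, ["x"], response="y"))
        assert not res.converged

    def test_single_class_response_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="classes"):
            fit_logistic(build_design(df, ["x"], response="y"))

    def test_null_effect_calibration_small(self):
        """mtDNA effect simulated at OR = 1: Wald CI covers 1 at roughly the
        nominal rate over seeded replicates (coarse check; the acceptance
        suite runs the full calibration)."""
        cover = 0
        runs = 40
        for seed in range(runs):
            cohort = simulate_transfer_cohort(CohortEffectSpec(n=1000, seed=seed))
            models = run_endpoint_models(cohort)
            t = models.results["hcg_pos"].term("mtdna_ratio")
            cover += t.or_ci_low <= 1.0 <= t.or_ci_high
        assert cover / runs >= 0.85


class TestEndpointModels:
    def test_four_models_fit_with_interactions_in_secondary(self):
        cohort = simulate_transfer_cohort(CohortEffectSpec(n=1500, seed=2))
        models = run_endpoint_models(cohort)
        assert sorted(models.results) == sorted(ENDPOINTS)
        assert not models.errors
        assert set(models.interaction_results) == {"hcg_pos", "sac_pos"}
        aug = models.interaction_results["hcg_pos"]
        assert "te_grade:gender" in [t.name for t in aug.terms]

    def test_endpoint_failure_isolated(self):
        cohort = simulate_transfer_cohort(CohortEffectSpec(n=300, seed=3))
        frame = pd.DataFrame([vars(r) for r in cohort])
        frame["ongoing_14wk"] = False  # degenerate endpoint
        models = run_endpoint_models(frame)
        assert "ongoing_14wk" in models.errors
        assert "hcg_pos" in models.results


class TestFeatureScreen:
    def test_matrix_is_symmetric_with_unit_diagonal(self):
        records = simulate_timelapse_cohort(CohortEffectSpec(n=200, seed=5))
        screen = feature_screen(records)
        m = screen.matrix.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_teb_always_kept_as_timeline_relevant(self):
        records = simulate_timelapse_cohort(CohortEffectSpec(n=100, seed=6))
        screen = feature_screen(records, threshold=0.99)
        assert screen.selected == ["tEB"]

    def test_subset_filters_applied(self):
        records = simulate_timelapse_cohort(CohortEffectSpec(n=400, seed=7))
        screen = feature_screen(records, subset={"day_of_formation": 5,
                                                 "gender": "male"})
        n_expected = sum(1 for r in records
                         if r.day_of_formation == 5 and r.gender == "male")
        assert screen.n_records == n_expected

    def test_too_few_records_rejected(self):
        records = simulate_timelapse_cohort(CohortEffectSpec(n=5, seed=8))
        with pytest.raises(ValueError, match="fewer than 3"):
            feature_screen(records, subset={"day_of_formation": 99})
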