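import numpy as np
import pytest
from sklearn.metrics import mean_squared_error, r2_score

from hypercal.evaluation import (
    MetricsReport,
    compare_report,
    evaluate_predictions,
    fit_baselines,
    percent_change,
    r_squared,
    render_report_table,
    rmse,
    rpd,
)


class TestRmse:
    def test_identical_vectors(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_three_four_five(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(3.5355339, abs=1e-6)

    def test_single_element_is_absolute_error(self):
        assert rmse([2.0], [5.5]) == pytest.approx(3.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([2.0, 2.0], [1.0, 3.0])

    def test_agrees_with_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            y = rng.standard_normal(20)
            yhat = y + rng.normal(0, 0.5, 20)
            assert r_squared(y, yhat) == pytest.approx(r2_score(y, yhat), abs=1e-12)
            assert rmse(y, yhat) == pytest.approx(
                np.sqrt(mean_squared_error(y, yhat)), abs=1e-12)


class TestRpd:
    @pytest.mark.parametrize("rp2, expected", [(0.0, 1.0), (0.75, 2.0), (0.96, 5.0)])
    def test_closed_form(self, rp2, expected):
        assert rpd(rp2) == pytest.approx(expected, abs=1e-12)

    def test_r2_of_one_rejected(self):
        with pytest.raises(ValueError):
            rpd(1.0)

    def test_identity_with_sd_over_rmsep(self):
        """1/sqrt(1-R^2) == sd(y)/RMSE for any prediction vector."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = rng.standard_normal(30) * rng.uniform(0.5, 3)
            yhat = y + rng.normal(0, 0.4, 30)
            lhs = rpd(r_squared(y, yhat))
            rhs = y.std() / rmse(y, yhat)
            assert abs(lhs - rhs) < 1e-9


class TestPercentChange:
    def test_published_rp2_improvement(self):
        assert percent_change(0.9361, 0.9421, "increase") == pytest.approx(0.641, abs=5e-4)

    def test_published_rmsep_reduction(self):
        assert percent_change(0.1854, 0.1617, "decrease") == pytest.approx(12.78, abs=5e-3)

    def test_no_change(self):
        assert percent_change(3.0, 3.0, "increase") == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0, "increase")


class TestScaleTagging:
    def test_standardizing_targets_scales_rmse_by_sd(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(19, 28, 50)
        yhat = y + rng.normal(0, 0.3, 50)
        sd = y.std()
        raw = rmse(y, yhat)
        standardized = rmse((y - y.mean()) / sd, (yhat - y.mean()) / sd)
        assert raw == pytest.approx(standardized * sd, abs=1e-12)


class TestBaselines:
    def _linear_problem(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((80, 10))
        beta = rng.standard_normal(10)
        y = X @ beta + 25.0
        return X[:60], y[:60], X[60:], y[60:]

    def test_plsr_on_noiseless_linear_data(self):
        # rank-3 design with a noiseless linear target is exactly representable
        # by a 3-component PLSR
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((80, 3))
        loadings = rng.standard_normal((3, 10))
        X = scores @ loadings
        y = scores @ np.array([1.0, -2.0, 0.5]) + 25.0
        rep = fit_baselines(X[:60], y[:60], X[60:], y[60:], which=("PLSR",))[0]
        assert rep.rp2 >= 0.999

    def test_report_rows_are_complete(self):
        Xtr, ytr, Xte, yte = self._linear_problem(1)
        reports = fit_baselines(Xtr, ytr, Xte, yte)
        assert {r.model for r in reports} == {"PLSR", "PCA-PLSR", "SVR"}
        for r in reports:
            for fieldname in ("rc2", "rmsec", "rp2", "rmsep", "rpd"):
                assert np.isfinite(getattr(r, fieldname))
            assert (r.n_train, r.n_test) == (60, 20)

    def test_unknown_baseline_rejected(self):
        Xtr, ytr, Xte, yte = self._linear_problem(2)
        with pytest.raises(ValueError, match="unknown baseline"):
            fit_baselines(Xtr, ytr, Xte, yte, which=("GBM",))


class TestCompareReport:
    def _reports(self):
        return [
            MetricsReport("attention", rc2=0.9897, rmsec=0.0687, rp2=0.9872,
                          rmsep=0.076, rpd=6.27),
            MetricsReport("tuned", rc2=0.9976, rmsec=0.0327, rp2=0.9975,
                          rmsep=0.0337, rpd=14.16),
        ]

    def test_published_rc2_pair_recomputes_to_0798(self):
        rows = compare_report(self._reports(), [("attention", "tuned", "rc2", "increase")])
        assert rows[0]["percent_change"] == pytest.approx(0.798, abs=5e-4)

    def test_published_rp2_pair(self):
        rows = compare_report(self._reports(), [("attention", "tuned", "rp2", "increase")])
        assert rows[0]["percent_change"] == pytest.approx(1.04, abs=5e-3)

    def test_empty_pairs(self):
        assert compare_report(self._reports(), []) == []

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            compare_report(self._reports(), [("nope", "tuned", "rp2", "increase")])

    def test_render_contains_models_and_changes(self):
        reports = self._reports()
        rows = compare_report(reports, [("attention", "tuned", "rmsep", "decrease")])
        text = render_report_table(reports, rows)
        assert "tuned" in text and "rmsep" in text


class TestEvaluatePredictions:
    def test_quadruple_and_rpd(self):
        rng = np.random.default_rng(3)
        ytr = rng.uniform(19, 28, 40)
        yte = rng.uniform(19, 28, 20)
        rep = evaluate_predictions("m", ytr, ytr + rng.normal(0, 0.2, 40),
                                  yte, yte + rng.normal(0, 0.3, 20))
        assert rep.rc2 <= 1 and rep.rp2 <= 1
        assert rep.rpd == pytest.approx(1 / np.sqrt(1 - rep.rp2))
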