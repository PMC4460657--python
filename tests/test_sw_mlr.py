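import math

import numpy as np
import pandas as pd
import pytest

from gridqsar.sw_mlr import (
    QsarModel,
    contributions,
    f_statistic,
    fit_qsar,
    loo_q2,
    ols_fit,
    pred_r2,
    stepwise_forward,
)
from gridqsar.synthetic_data import make_planted_dataset


def normal_equations_oracle(x, y):
    """Independent OLS solve via the normal equations."""
    design = np.column_stack([np.ones(len(y)), x])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ beta
    sse = float(resid @ resid)
    sigma2 = sse / (len(y) - design.shape[1])
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return beta, np.sqrt(np.diag(cov)), sse


def brute_force_loo(x, y):
    """Literal n-refit leave-one-out PRESS."""
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        design = np.column_stack([np.ones(n - 1), x[keep]])
        beta = np.linalg.solve(design.T @ design, design.T @ y[keep])
        pred = np.concatenate([[1.0], x[i]]) @ beta
        press += (y[i] - pred) ** 2
    sst = np.sum((y - y.mean()) ** 2)
    return 1.0 - press / sst


class TestOlsFit:
    def test_exact_line(self):
        x = np.arange(10, dtype=float).reshape(-1, 1)
        y = 2 * x[:, 0] + 1
        fit = ols_fit(x, y)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.r2_se == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("seed,n,k", [(0, 20, 3), (1, 50, 5), (2, 100, 10)])
    def test_matches_normal_equations_oracle(self, seed, n, k):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        fit = ols_fit(x, y)
        beta, se, sse = normal_equations_oracle(x, y)
        np.testing.assert_allclose(fit.intercept, beta[0], atol=1e-10)
        np.testing.assert_allclose(fit.coefficients, beta[1:], atol=1e-10)
        np.testing.assert_allclose(fit.coef_se, se[1:], atol=1e-10)
        np.testing.assert_allclose(fit.sse, sse, atol=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 4))
        y = x @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(size=30)
        fit = ols_fit(x, y)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.coefficients, res.params[1:], atol=1e-10)
        np.testing.assert_allclose(fit.r2, res.rsquared, atol=1e-10)
        np.testing.assert_allclose(fit.coef_se, res.bse[1:], atol=1e-10)

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 2))
        x = np.column_stack([x, x[:, 0]])  # duplicate column
        with pytest.raises(ValueError, match="rank deficient"):
            ols_fit(x, rng.normal(size=20), column_names=["a", "b", "a_copy"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="n > k"):
            ols_fit(np.ones((3, 3)), np.ones(3))


class TestStepwiseForward:
    def test_planted_columns_all_selected(self):
        matrix, acts, truth = make_planted_dataset(
            n_compounds=40, n_descriptors=50, k_informative=3, noise_sd=0.2, seed=17
        )
        y = np.array([a.pIC50 for a in acts])
        selected, fit, trace = stepwise_forward(matrix.data, y)
        assert set(truth.informative) <= set(selected)

    def test_single_perfect_candidate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(15, 1))
        df = pd.DataFrame(x, columns=["S_1"])
        selected, fit, _ = stepwise_forward(df, 3.0 * x[:, 0] + 1.0)
        assert selected == ["S_1"]
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_infinite_f_enter_selects_nothing(self, planted):
        matrix, acts, _ = planted
        y = np.array([a.pIC50 for a in acts])
        selected, fit, _ = stepwise_forward(matrix.data, y, f_enter=math.inf)
        assert selected == [] and fit is None

    def test_accepted_steps_meet_threshold(self, planted):
        matrix, acts, _ = planted
        y = np.array([a.pIC50 for a in acts])
        f_enter = 6.0
        _, _, trace = stepwise_forward(matrix.data, y, f_enter=f_enter)
        assert trace
        assert all(step["F_add"] >= f_enter for step in trace)

    def test_max_terms_guard(self, planted):
        matrix, acts, _ = planted
        y = np.array([a.pIC50 for a in acts])
        n = len(y)
        selected, _, _ = stepwise_forward(matrix.data, y, f_enter=0.1, max_terms=999)
        assert len(selected) <= n // 4

    def test_coefficient_recovery_noiseless(self):
        matrix, acts, truth = make_planted_dataset(
            n_compounds=40, n_descriptors=30, k_informative=3, noise_sd=0.0, seed=23
        )
        y = np.array([a.pIC50 for a in acts])
        selected, fit, _ = stepwise_forward(matrix.data, y)
        assert set(selected) == set(truth.informative)
        for name, beta in zip(selected, fit.coefficients):
            assert beta == pytest.approx(truth.coefficients[name], abs=1e-6)
        assert fit.intercept == pytest.approx(truth.intercept, abs=1e-6)


class TestLooQ2:
    def test_noiseless_is_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 2))
        y = x @ np.array([1.0, -1.0]) + 2.0
        q2, q2_se = loo_q2(x, y)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        assert q2_se == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        q2, _ = loo_q2(x, y)
        assert q2 == pytest.approx(brute_force_loo(x, y), abs=1e-10)

    @pytest.mark.parametrize("seed", [10, 11, 12, 13])
    def test_q2_below_r2(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(20, 3))
        y = x @ np.array([1.0, 0.5, -0.5]) + rng.normal(scale=0.5, size=20)
        fit = ols_fit(x, y)
        q2, _ = loo_q2(x, y)
        assert q2 <= fit.r2


class TestPredR2:
    def _model(self, mean_y=5.0):
        return QsarModel(
            selected=["S_1"], coefficients={"S_1": 2.0}, coef_se={"S_1": 0.0},
            intercept=1.0, n_train=10, training_mean_y=mean_y,
        )

    def test_perfect_prediction(self):
        model = self._model()
        x = pd.DataFrame({"S_1": [0.0, 1.0, 2.0]})
        y = 1.0 + 2.0 * x["S_1"].to_numpy()
        pr2, se = pred_r2(model, x, y)
        assert pr2 == pytest.approx(1.0) and se == pytest.approx(0.0)

    def test_training_mean_prediction_gives_zero(self):
        # model that predicts exactly the training mean everywhere
        model = QsarModel(
            selected=["S_1"], coefficients={"S_1": 0.0}, coef_se={"S_1": 0.0},
            intercept=5.0, n_train=10, training_mean_y=5.0,
        )
        x = pd.DataFrame({"S_1": [1.0, 2.0, 3.0]})
        y = np.array([4.0, 5.0, 7.0])
        pr2, _ = pred_r2(model, x, y)
        assert pr2 == pytest.approx(0.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(9)
        model = self._model(mean_y=4.2)
        x = pd.DataFrame({"S_1": rng.normal(size=8)})
        y = rng.normal(loc=5.0, size=8)
        y_hat = 1.0 + 2.0 * x["S_1"].to_numpy()
        expected = 1.0 - np.sum((y - y_hat) ** 2) / np.sum((y - 4.2) ** 2)
        pr2, se = pred_r2(model, x, y)
        assert pr2 == pytest.approx(expected, abs=1e-12)
        assert se == pytest.approx(np.sqrt(np.sum((y - y_hat) ** 2) / 8), abs=1e-12)

    def test_degenerate_test_set(self):
        model = self._model(mean_y=5.0)
        x = pd.DataFrame({"S_1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="degenerate"):
            pred_r2(model, x, np.array([5.0, 5.0]))


class TestFStatistic:
    def test_paper_values(self):
        # printed F 130.3822 from printed (rounded) r2 -> sub-percent agreement
        f = f_statistic(0.9751, n=27, k=6)
        assert f == pytest.approx(130.3822, rel=0.005)

    def test_hand_computed(self):
        assert f_statistic(0.5, n=12, k=1) == pytest.approx(10.0)

    def test_zero_r2(self):
        assert f_statistic(0.0, n=12, k=1) == 0.0

    def test_r2_one_raises(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, n=12, k=1)


class TestContributions:
    def _model(self, coefficients):
        return QsarModel(
            selected=list(coefficients), coefficients=coefficients,
            coef_se={k: 0.0 for k in coefficients}, intercept=0.0,
        )

    def test_single_descriptor_is_100(self):
        rng = np.random.default_rng(12)
        x = pd.DataFrame({"S_1": rng.normal(size=10)})
        c = contributions(self._model({"S_1": -3.0}), x)
        assert c["S_1"] == pytest.approx(-100.0)

    def test_equal_weight_signs(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=10)
        x = pd.DataFrame({"S_1": base, "E_1": base * 2.0})
        c = contributions(self._model({"S_1": 2.0, "E_1": -1.0}), x)
        assert c["S_1"] == pytest.approx(50.0)
        assert c["E_1"] == pytest.approx(-50.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_magnitudes_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(15, 4)), columns=["S_1", "S_2", "E_1", "E_2"])
        coeffs = dict(zip(x.columns, rng.normal(size=4)))
        c = contributions(self._model(coeffs), x)
        assert sum(abs(v) for v in c.values()) == pytest.approx(100.0)

    def test_zero_variance_raises(self):
        x = pd.DataFrame({"S_1": [1.0] * 5})
        with pytest.raises(ValueError):
            contributions(self._model({"S_1": 1.0}), x)


class TestPredict:
    def test_zero_vector_returns_intercept(self, published_model):
        x = {name: 0.0 for name in published_model.selected}
        assert published_model.predict(x) == pytest.approx(5.0198, abs=1e-12)

    def test_unit_e337(self, published_model):
        x = {name: 0.0 for name in published_model.selected}
        x["E_337"] = 1.0
        assert published_model.predict(x) == pytest.approx(5.3187, abs=1e-10)

    def test_linearity(self, published_model):
        rng = np.random.default_rng(21)
        names = published_model.selected
        x1 = dict(zip(names, rng.normal(size=6)))
        x2 = dict(zip(names, rng.normal(size=6)))
        both = {k: x1[k] + x2[k] for k in names}
        b = published_model.intercept
        assert published_model.predict(both) - b == pytest.approx(
            (published_model.predict(x1) - b) + (published_model.predict(x2) - b), abs=1e-9
        )

    def test_missing_descriptor_raises(self, published_model):
        with pytest.raises(KeyError, match="E_337"):
            published_model.predict({"S_335": 0.0})


class TestQsarModelIO:
    def test_json_round_trip(self, tmp_path, published_model):
        path = tmp_path / "model.json"
        published_model.training_ranges = {n: (-1.0, 1.0) for n in published_model.selected}
        published_model.to_json(path)
        back = QsarModel.from_json(path)
        assert back.selected == published_model.selected
        assert back.coefficients == published_model.coefficients
        assert back.intercept == published_model.intercept
        assert back.r2 == published_model.r2
        assert back.training_ranges == published_model.training_ranges

    def test_fit_qsar_metadata(self, planted):
        matrix, acts, _ = planted
        y = np.array([a.pIC50 for a in acts])
        model = fit_qsar(matrix.data, y)
        assert model.k == len(model.selected) > 0
        assert 0 <= model.r2 <= 1
        assert model.q2 <= model.r2
        assert model.n_train == len(y)
        for name in model.selected:
            lo, hi = model.training_ranges[name]
            assert lo <= hi
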