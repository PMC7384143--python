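import numpy as np
import pytest

from leafprod.transfer import (inverse_logistic, fit_transfer,
                               predict_transfer, evaluate_transfer,
                               cross_region_validate, TransferModel)

# published China GPP~length transfer parameters, reused as generating truth
K, ALPHA, R = 11.602, 1.470, 0.002


class TestInverseLogistic:
    def test_printed_parameter_evaluation(self):
        assert inverse_logistic(5.0, K, ALPHA, R)[()] == pytest.approx(596.0, abs=0.1)

    def test_zero_crossing_at_closed_form_root(self):
        x0 = K / (1 + np.exp(ALPHA))
        assert inverse_logistic(x0, K, ALPHA, R)[()] == pytest.approx(0.0, abs=1e-9)

    def test_domain_boundaries_are_nan(self):
        y = inverse_logistic(np.array([-1.0, 0.0, K, K + 1]), K, ALPHA, R)
        assert np.isnan(y).all()

    def test_mutual_inverse_of_forward_logistic(self):
        y = np.linspace(50, 2000, 200)
        x = K / (1 + np.exp(ALPHA - R * y))  # forward logistic
        np.testing.assert_allclose(inverse_logistic(x, K, ALPHA, R), y,
                                   rtol=1e-10)


class TestFitTransfer:
    def test_noiseless_parameter_recovery(self):
        x = np.linspace(2.0, 11.0, 500)
        y = inverse_logistic(x, K, ALPHA, R)
        m = fit_transfer(x, y)
        assert m.params["K"] == pytest.approx(K, rel=1e-3)
        assert m.params["alpha"] == pytest.approx(ALPHA, rel=1e-3)
        assert m.params["r"] == pytest.approx(R, rel=1e-3)
        assert m.r2 == pytest.approx(1.0, abs=1e-9)

    def test_linear_form_exact(self):
        x = np.linspace(1, 10, 50)
        m = fit_transfer(x, 100 + 50 * x, form="linear")
        assert m.params["a"] == pytest.approx(100.0)
        assert m.params["b"] == pytest.approx(50.0)

    def test_nonpositive_traits_excluded_and_counted(self):
        x = np.concatenate([[0.0, -1.0], np.linspace(2, 11, 100)])
        y = inverse_logistic(np.clip(x, 0.5, None), K, ALPHA, R)
        m = fit_transfer(x, y)
        assert m.n_excluded >= 2
        assert m.n == 100

    def test_json_exchange_surface(self):
        x = np.linspace(2, 11, 100)
        m = fit_transfer(x, inverse_logistic(x, K, ALPHA, R))
        clone = TransferModel.from_json(m.to_json())
        assert clone.params == m.params
        np.testing.assert_allclose(predict_transfer(clone, x),
                                   predict_transfer(m, x))


class TestPredictTransfer:
    def test_out_of_domain_warns_and_returns_nan(self):
        m = TransferModel("length", "GPP", "inv_logistic",
                          {"K": K, "alpha": ALPHA, "r": R}, 100, 1.0)
        with pytest.warns(UserWarning, match="outside"):
            y = predict_transfer(m, np.array([5.0, 12.0]))
        assert np.isfinite(y[0]) and np.isnan(y[1])


class TestEvaluateTransfer:
    def test_hand_computed_se(self):
        ev = evaluate_transfer([1.0, 9.0], [0.0, 10.0])
        assert ev.se == pytest.approx(np.sqrt(2.0))
        assert ev.se_pct == pytest.approx(100 * np.sqrt(2) / 10)

    def test_perfect_prediction(self):
        y = np.linspace(0, 100, 20)
        ev = evaluate_transfer(y, y)
        assert ev.se == 0.0 and ev.se_pct == 0.0 and ev.r2 == 1.0

    def test_constant_offset_algebra(self, rng):
        y = rng.normal(size=40)
        c = 3.7
        ev = evaluate_transfer(y + c, y)
        assert ev.se == pytest.approx(abs(c) * np.sqrt(40 / 39))

    def test_scale_covariance(self, rng):
        y = rng.uniform(0, 100, 50)
        e = y + rng.normal(0, 5, 50)
        ev1 = evaluate_transfer(e, y)
        ev2 = evaluate_transfer(3 * e, 3 * y)
        assert ev2.se == pytest.approx(3 * ev1.se)
        assert ev2.se_pct == pytest.approx(ev1.se_pct)


class TestCrossRegion:
    def test_self_consistency_zero_noise(self):
        import pandas as pd
        x = np.linspace(2, 11, 300)
        y = inverse_logistic(x, K, ALPHA, R)
        m = fit_transfer(x, y)
        cells = pd.DataFrame({"mean_length": x, "GPP": y})
        ev, paired = cross_region_validate(m, cells, "mean_length", "GPP")
        assert ev.slope == pytest.approx(1.0, abs=1e-6)
        assert ev.se == pytest.approx(0.0, abs=1e-6)
        assert len(paired) == 300

    def test_permuted_traits_destroy_predictions(self, rng):
        import pandas as pd
        x = rng.uniform(2, 11, 500)
        y = inverse_logistic(x, K, ALPHA, R) + rng.normal(0, 100, 500)
        m = fit_transfer(x, y)
        cells = pd.DataFrame({"mean_length": rng.permutation(x), "GPP": y})
        ev, _ = cross_region_validate(m, cells, "mean_length", "GPP")
        assert ev.r2 < 0.05

    def test_domain_exclusion_improves_per_cell_sse(self, rng):
        # refit after dropping x >= K never raises SSE per remaining cell
        x = np.concatenate([np.linspace(2, 11.4, 300),
                            np.array([11.7, 11.9, 12.5])])
        y_in = inverse_logistic(np.clip(x, None, 11.0), K, ALPHA, R)
        y = y_in + rng.normal(0, 80, x.size)
        m = fit_transfer(x, y)
        assert m.params["K"] > 0
        yh = predict_transfer(m, x[x < m.params["K"]])
        assert np.isfinite(yh).all()
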