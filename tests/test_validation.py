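import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qsarws.errors import UndefinedStatisticError
from qsarws.regression import fit_ols, q2_loo
from qsarws.validation import (
    ccc,
    external_stats,
    golbraikh_tropsha,
    internal_stats,
    q2_lmo,
    validate_model,
    y_scramble,
)


class TestInternalStats:
    def test_perfect_fit(self, rng):
        X = rng.normal(size=(20, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        r2, r2_adj, rmse, mae = internal_stats(fit_ols(X, y))
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-10)
        assert mae == pytest.approx(0.0, abs=1e-10)

    def test_hand_arithmetic_on_planted_residuals(self):
        # residual vector (1, -1, 0) injected directly: RMSE = sqrt(2/3),
        # MAE = 2/3 by hand arithmetic
        from qsarws.regression import MLRModel

        e = np.array([1.0, -1.0, 0.0])
        fit_line = np.array([1.0, 2.0, 3.0])
        model = MLRModel(
            descriptor_names=["x0"],
            coefficients=np.array([1.0]),
            intercept=2.0,
            n_train=3,
            fitted_values=fit_line,
            residuals=e,
            X_train=np.array([[-1.0], [0.0], [1.0]]),
            y_train=fit_line + e,
        )
        _, _, rmse, mae = internal_stats(model)
        assert rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert mae == pytest.approx(2.0 / 3.0)

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            p = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(0, 1, n)
            r2, r2_adj, *_ = internal_stats(fit_ols(X, y))
            assert r2_adj <= r2 + 1e-12


class TestQ2Lmo:
    def test_noiseless_is_one(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + 0.5
        assert q2_lmo(X, y, iterations=50, seed=0) == pytest.approx(1.0, abs=1e-6)

    def test_on_average_below_q2_loo(self, rng):
        diffs = []
        for _ in range(50):
            X = rng.normal(size=(40, 2))
            y = X @ np.array([1.0, -1.0]) + rng.normal(0, 1.0, 40)
            diffs.append(q2_loo(X, y) - q2_lmo(X, y, iterations=30, seed=1))
        assert np.mean(diffs) > 0

    def test_seed_reproducible(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        assert q2_lmo(X, y, iterations=20, seed=5) == q2_lmo(
            X, y, iterations=20, seed=5
        )


class TestYScramble:
    def test_strong_model_scrambles_to_noise(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + rng.normal(0, 0.2, 60)
        q2_yscr, r2_yscr = y_scramble(X, y, iterations=200, seed=0)
        assert r2_yscr < 0.1
        assert q2_yscr < 0.05

    def test_seed_reproducible(self, rng):
        X = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        assert y_scramble(X, y, iterations=10, seed=3) == y_scramble(
            X, y, iterations=10, seed=3
        )


class TestExternalStats:
    def _fitted(self, rng, n=40, p=3):
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + rng.normal(0, 0.3, n)
        return fit_ols(X, y), beta

    def test_perfect_predictions(self, rng):
        model, beta = self._fitted(rng)
        Xp = rng.normal(size=(10, 3))
        yp = model.predict(Xp)  # exact agreement by construction
        stats = external_stats(model, Xp, yp)
        for key in ("Q2_F1", "Q2_F2", "Q2_F3", "CCC_pr", "R2_pr"):
            assert stats[key] == pytest.approx(1.0, abs=1e-10)

    def test_training_mean_predictor_zeroes_qf1(self, rng):
        # if every external prediction equals the training mean, the Q2_F1
        # numerator equals its denominator exactly
        model, _ = self._fitted(rng)
        y_ext = rng.normal(size=8)
        ybar = model.y_train.mean()
        rss = np.sum((ybar - y_ext) ** 2)
        q2f1 = 1.0 - rss / np.sum((y_ext - ybar) ** 2)
        assert q2f1 == pytest.approx(0.0, abs=1e-12)

    def test_formula_oracles_on_random_toys(self, rng):
        for _ in range(200):
            model, _ = self._fitted(rng, n=int(rng.integers(20, 50)))
            Xp = rng.normal(size=(int(rng.integers(5, 15)), 3))
            yp = model.predict(Xp) + rng.normal(0, 0.5, len(Xp))
            s = external_stats(model, Xp, yp)
            yh = model.predict(Xp)
            y_tr = model.y_train
            rss = np.sum((yh - yp) ** 2)
            assert s["Q2_F1"] == pytest.approx(
                1 - rss / np.sum((yp - y_tr.mean()) ** 2), abs=1e-10
            )
            assert s["Q2_F2"] == pytest.approx(
                1 - rss / np.sum((yp - yp.mean()) ** 2), abs=1e-10
            )
            assert s["Q2_F3"] == pytest.approx(
                1
                - (rss / len(yp))
                / (np.sum((y_tr - y_tr.mean()) ** 2) / len(y_tr)),
                abs=1e-10,
            )
            assert s["Q2_F2"] <= s["Q2_F1"] + 1e-12

    def test_constant_external_response_raises(self, rng):
        model, _ = self._fitted(rng)
        Xp = rng.normal(size=(5, 3))
        with pytest.raises(UndefinedStatisticError):
            external_stats(model, Xp, np.full(5, 2.0))


class TestCCC:
    def test_identical_vectors(self):
        assert ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_anticorrelated_hand_value(self):
        # cross-deviation sum is -2, denominator 2 + 2 + 0 = 4
        assert ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_against_varying_is_zero(self):
        assert ccc([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_equal_constants_agree_perfectly(self):
        assert ccc([2, 2, 2], [2, 2, 2]) == 1.0

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=3, max_size=20
        ).filter(lambda v: len(set(v)) > 1)
    )
    def test_symmetric(self, v):
        w = v[::-1]
        assert ccc(v, w) == pytest.approx(ccc(w, v), abs=1e-12)

    def test_bounded_by_pearson(self, rng):
        for _ in range(100):
            x = rng.normal(size=20)
            y = 0.5 * x + rng.normal(0, 1, 20) + rng.normal()
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc(x, y)) <= abs(r) + 1e-12


class TestGolbraikhTropsha:
    def test_perfect_predictions_pass(self, rng):
        y = rng.normal(size=20) + 5
        gt = golbraikh_tropsha(y, y, Q2_LOO=0.9, R2=0.9, R2_pr=0.9)
        assert gt.k == pytest.approx(1.0)
        assert gt.k_prime == pytest.approx(1.0)
        assert abs(gt.R2_0 - gt.R2_0_prime) == pytest.approx(0.0, abs=1e-12)
        assert gt.overall

    def test_doubled_predictions_fail_slope(self, rng):
        y = np.abs(rng.normal(size=20)) + 1
        gt = golbraikh_tropsha(y, 2 * y, Q2_LOO=0.9, R2=0.9, R2_pr=0.9)
        assert gt.k == pytest.approx(0.5)
        assert gt.k_prime == pytest.approx(2.0)
        assert not gt.passes["slope_in_band"]

    def test_anticorrelated_fails_overall(self, rng):
        y = np.linspace(1, 5, 12)
        gt = golbraikh_tropsha(y, y[::-1], Q2_LOO=0.9, R2=0.9, R2_pr=0.9)
        assert not gt.overall


class TestValidateModel:
    def test_full_battery_on_planted_model(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.3, 60)
        model = fit_ols(X[:45], y[:45])
        report = validate_model(
            model,
            X_pred=X[45:],
            y_pred=y[45:],
            lmo_iterations=30,
            yscr_iterations=30,
            seed=0,
        )
        assert report.R2 > 0.9 and report.Q2_LOO > 0.9
        assert report.external["R2_pr"] > 0.8
        assert report.gt is not None and report.gt.overall
        assert report.R2_adj <= report.R2
        assert report.Q2_Yscr < 0.1
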