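import numpy as np
import pandas as pd
import pytest

from contamdrivers.plsr_core import (backward_select, collinearity_screen,
                                     loo_q2, model_quality, nipals_fit,
                                     permutation_test, residual_autocorrelation,
                                     select_components, vip, wrc)


def standardized(M):
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)


class TestNipalsFit:
    def test_first_weight_is_normalized_xty(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = nipals_fit(X, y, 1)
        Xs, ys = standardized(X), standardized(y)
        expected = Xs.T @ ys
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(model.weights[:, 0], expected, atol=1e-10)

    def test_full_components_match_ols(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=30)
        model = nipals_fit(X, y, 5)
        Xs, ys = standardized(X), standardized(y)
        b_ols = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        np.testing.assert_allclose(model.coefficients, b_ols, atol=1e-8)

    def test_orthogonal_y_gives_no_fit(self):
        # y orthogonal to both centered columns
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]] * 3)
        y = np.tile([1.0, 1.0, -1.0, -1.0], 3)
        y = y - np.linalg.lstsq(standardized(X), y, rcond=None)[0] @ standardized(X).T
        model = nipals_fit(X, y, 2)
        assert model.r2y[-1] if model.n_components else 0.0 == pytest.approx(0.0, abs=1e-8)

    def test_score_orthogonality_and_weight_norms(self, rng):
        X = rng.normal(size=(25, 6))
        y = X[:, 0] + rng.normal(size=25)
        model = nipals_fit(X, y, 4)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8
        np.testing.assert_allclose(np.linalg.norm(model.weights, axis=0),
                                   np.ones(model.n_components), atol=1e-10)

    def test_r2y_nondecreasing(self, rng):
        X = rng.normal(size=(24, 5))
        y = rng.normal(size=24)
        model = nipals_fit(X, y, 4)
        assert np.all(np.diff(model.r2y) >= -1e-12)

    def test_zero_variance_column_named(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            nipals_fit(X, rng.normal(size=20), 2)

    def test_a_exceeding_rank_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        X[:, 3] = X[:, 0] + X[:, 1]
        with pytest.raises(ValueError, match="rank"):
            nipals_fit(X, rng.normal(size=20), 4)

    def test_predict_roundtrip(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 3.0
        model = nipals_fit(X, y, 4)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)


class TestLooQ2:
    def test_perfect_linear_single_predictor(self, rng):
        X = rng.normal(size=(24, 1))
        y = 2.0 * X[:, 0]
        q2, _ = loo_q2(X, y, 1)
        assert q2[0] >= 0.999

    def test_perfect_linear_full_components(self, rng):
        X = rng.normal(size=(24, 3))
        y = X @ np.array([2.0, -1.0, 0.5])
        q2, _ = loo_q2(X, y, 3)
        assert q2[-1] >= 0.999

    def test_pure_noise_mean_q2_negative(self, rng):
        vals = []
        for _ in range(100):
            X = rng.normal(size=(24, 5))
            y = rng.normal(size=24)
            q2, _ = loo_q2(X, y, 2)
            vals.append(q2[-1])
        assert np.mean(vals) < 0

    def test_q2_never_exceeds_one(self, rng):
        X = rng.normal(size=(20, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        q2, press = loo_q2(X, y, 3)
        assert np.all(q2 <= 1.0)
        assert np.all(press >= 0.0)


class TestSelectComponents:
    def test_one_factor_data(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=5)) + 0.01 * rng.normal(size=(30, 5))
        y = t + 0.01 * rng.normal(size=30)
        assert select_components(X, y) == 1

    def test_a_max_one(self, rng):
        X = rng.normal(size=(20, 4))
        y = X[:, 0] + rng.normal(size=20)
        assert select_components(X, y, a_max=1) == 1

    def test_smallest_within_tolerance_of_min(self, rng):
        # the rule: smallest A whose PRESS is within 5% of the minimum
        X = rng.normal(size=(30, 5))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0, 0.0]) + 0.3 * rng.normal(size=30)
        q2, press = loo_q2(X, y, 4)
        expected = int(np.flatnonzero(press <= 1.05 * press.min())[0]) + 1
        assert select_components(X, y, a_max=4) == expected


class TestVIPAndWRC:
    def test_single_predictor_vip_one(self, rng):
        X = rng.normal(size=(20, 1))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        model = nipals_fit(X, y, 1)
        assert vip(model)[0] == pytest.approx(1.0)

    def test_identical_predictors_equal_vip_wrc(self, rng):
        base = rng.normal(size=24)
        X = np.column_stack([base, base, rng.normal(size=24)])
        y = base + 0.1 * rng.normal(size=24)
        model = nipals_fit(X, y, 2)
        v, w = vip(model), wrc(model)
        assert v[0] == pytest.approx(v[1], rel=1e-8)
        assert w[0] == pytest.approx(w[1], rel=1e-8)

    def test_vip_sum_of_squares_identity(self, rng):
        for p in (3, 6, 10):
            X = rng.normal(size=(25, p))
            y = X @ rng.normal(size=p) + rng.normal(size=25)
            model = nipals_fit(X, y, min(4, p))
            assert np.sum(vip(model) ** 2) == pytest.approx(p, abs=1e-8)

    def test_wrc_formula_single_component(self, rng):
        X = rng.normal(size=(20, 4))
        y = X[:, 0] + rng.normal(size=20)
        model = nipals_fit(X, y, 1)
        expected = model.coefficients * model.weights[:, 0] ** 2
        np.testing.assert_allclose(wrc(model), expected, atol=1e-12)
        assert np.all(np.sign(wrc(model)) == np.sign(model.coefficients))

    def test_strongest_driver_has_largest_wrc(self, rng):
        X = rng.normal(size=(40, 5))
        y = 3.0 * X[:, 2] + 0.5 * X[:, 0]
        model = nipals_fit(X, y, 2)
        assert np.argmax(np.abs(wrc(model))) == 2


class TestBackwardSelect:
    def test_no_drop_when_all_vips_pass(self, rng):
        base = rng.normal(size=30)
        X = pd.DataFrame({"a": base + 0.2 * rng.normal(size=30),
                          "b": -base + 0.2 * rng.normal(size=30)})
        y = base
        model, trace = backward_select(X, y)
        assert trace.steps == ()
        assert set(model.predictor_names) == {"a", "b"}

    def test_noise_column_eliminated(self, rng):
        eliminated = 0
        n_runs = 40
        for _ in range(n_runs):
            t = rng.normal(size=26)
            X = pd.DataFrame({
                "s1": t + 0.1 * rng.normal(size=26),
                "s2": -t + 0.1 * rng.normal(size=26),
                "s3": t * 0.8 + 0.1 * rng.normal(size=26),
                "junk": rng.normal(size=26),
            })
            y = t + 0.05 * rng.normal(size=26)
            model, _ = backward_select(X, y)
            eliminated += "junk" not in model.predictor_names
        assert eliminated / n_runs >= 0.95

    def test_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(24, 6)),
                         columns=list("abcdef"))
        y = X["a"].to_numpy() + 0.5 * rng.normal(size=24)
        m1, t1 = backward_select(X, y)
        m2, t2 = backward_select(X, y)
        assert t1 == t2
        assert m1.predictor_names == m2.predictor_names

    def test_final_vips_above_threshold(self, rng):
        X = pd.DataFrame(rng.normal(size=(24, 8)),
                         columns=[f"x{j}" for j in range(8)])
        y = X["x0"].to_numpy() - X["x3"].to_numpy() + 0.3 * rng.normal(size=24)
        model, trace = backward_select(X, y, vip_threshold=0.7)
        if len(model.predictor_names) > 2:
            assert np.all(vip(model) >= 0.7)
        assert trace.final_predictors == model.predictor_names


class TestPermutation:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(20, 3))
        y = X[:, 0] + 0.5 * rng.normal(size=20)
        r1 = permutation_test(X, y, n_perm=99, seed=11)
        r2 = permutation_test(X, y, n_perm=99, seed=11)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_q2, r2.null_q2)

    def test_strong_signal_small_p(self, rng):
        X = rng.normal(size=(24, 4))
        y = 2.0 * X[:, 1] - X[:, 2] + 0.2 * rng.normal(size=24)
        res = permutation_test(X, y, n_perm=199, seed=0)
        assert res.p_value <= 0.05

    def test_p_lower_bound(self, rng):
        X = rng.normal(size=(20, 3))
        y = X[:, 0]
        res = permutation_test(X, y, n_perm=99, seed=3)
        assert res.p_value >= 1.0 / (99 + 1)
        assert 0.0 < res.p_value <= 1.0

    def test_min_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            permutation_test(rng.normal(size=(20, 3)), rng.normal(size=20),
                             n_perm=50, seed=0)


class TestResidualDiagnostics:
    def test_acf0_is_one_and_df(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + 0.3 * rng.normal(size=30)
        model = nipals_fit(X, y, 2)
        out = residual_autocorrelation(model, X, y, max_lag=5)
        assert out["acf"][0] == pytest.approx(1.0)
        assert len(out["acf"]) == 6
        assert out["max_lag"] == 5

    def test_ljung_box_calibration(self, rng):
        # white-noise residuals: rejection at 5% should be near nominal
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            from statsmodels.stats.diagnostic import acorr_ljungbox
            resid = rng.normal(size=200)
            p = acorr_ljungbox(resid, lags=[5])["lb_pvalue"].iloc[0]
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_ar1_power(self, rng):
        X = rng.normal(size=(100, 2))
        detect = 0
        for _ in range(30):
            eps = np.zeros(100)
            innov = rng.normal(size=100)
            for t in range(1, 100):
                eps[t] = 0.8 * eps[t - 1] + innov[t]
            y = X[:, 0] + eps
            model = nipals_fit(X, y, 1)
            out = residual_autocorrelation(model, X, y, max_lag=5)
            detect += out["p_value"] < 0.05
        assert detect / 30 >= 0.9


class TestCollinearity:
    def test_duplicate_column_flagged(self, rng):
        base = rng.normal(size=24)
        X = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=24)})
        flagged = collinearity_screen(X)
        assert len(flagged) == 1
        assert flagged.iloc[0]["r"] == pytest.approx(1.0)
        assert {flagged.iloc[0]["var_a"], flagged.iloc[0]["var_b"]} == {"a", "b"}

    def test_constructed_pair_at_09(self, rng):
        a = rng.normal(size=2000)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=2000)
        X = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=2000)})
        flagged = collinearity_screen(X, threshold=0.8)
        assert len(flagged) == 1
        assert abs(flagged.iloc[0]["r"]) == pytest.approx(0.9, abs=0.03)

    def test_independent_noise_rarely_flagged(self, rng):
        n_flagged = 0
        for _ in range(100):
            X = pd.DataFrame(rng.normal(size=(24, 4)))
            n_flagged += len(collinearity_screen(X, threshold=0.8))
        assert n_flagged / 100 < 0.05


class TestQualityGate:
    def test_gate(self):
        assert model_quality(0.84, 0.65) == "good"
        assert model_quality(0.58, 0.26) == "poor"
        assert model_quality(0.9, 0.3) == "poor"
        assert model_quality(0.6, 0.5) == "poor"
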