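"""The PLS1 engine: scaling, NIPALS, cross-validation, VIP, back-transformation."""

import numpy as np
import pandas as pd
import pytest

from tocopls.pls import (
    ModelFitStats,
    adjusted_r2,
    autoscale,
    fit_pls,
    fold_assignments,
    pls_fit,
    press_from_folds,
    q_squared,
    select_components,
    unstandardized_coefficients,
    vip,
)


def _random_instance(rng, n=None, p=None, noise=1.0):
    n = n or int(rng.integers(10, 30))
    p = p or int(rng.integers(1, min(6, n - 2)))
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestAutoscale:
    def test_columns_standardized_and_round_trip(self, rng):
        X, y = _random_instance(rng, n=20, p=4)
        Xs, ys, sc = autoscale(X, y)
        assert np.allclose(Xs.mean(0), 0, atol=1e-12)
        assert np.allclose(Xs.std(0, ddof=1), 1, atol=1e-12)
        assert np.allclose(ys.std(ddof=1), 1, atol=1e-12)
        assert np.allclose(sc.inverse_x(Xs), X, atol=1e-10)
        assert np.allclose(sc.inverse_y(ys), y, atol=1e-10)

    def test_known_parameters(self):
        X = np.array([[1.0, 10.0], [3.0, 30.0], [5.0, 20.0]])
        _, _, sc = autoscale(X, np.array([1.0, 2.0, 3.0]))
        assert sc.x_mean == pytest.approx([3.0, 20.0])
        assert sc.x_sd == pytest.approx([2.0, 10.0])

    def test_constant_column_error_names_column(self):
        X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            autoscale(X, np.array([1.0, 2.0, 3.0]))


class TestFitPLS:
    def test_single_predictor_equals_simple_regression(self, rng):
        X, y = _random_instance(rng, n=25, p=1)
        Xs, ys, _ = autoscale(X, y)
        model = fit_pls(Xs, ys, A=1)
        slope = float(Xs.ravel() @ ys / (Xs.ravel() @ Xs.ravel()))
        assert model.coef_std[0] == pytest.approx(slope, rel=1e-12)

    def test_full_components_equal_least_squares(self, rng):
        """Oracle equivalence: full-rank PLS reproduces the normal equations."""
        for _ in range(30):
            X, y = _random_instance(rng)
            n, p = X.shape
            Xs, ys, _ = autoscale(X, y)
            model = fit_pls(Xs, ys, A=p)
            design = np.column_stack([np.ones(n), Xs])
            beta = np.linalg.lstsq(design, ys, rcond=None)[0]
            assert np.allclose(Xs @ model.coef_std, design @ beta, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X, y = _random_instance(rng, n=30, p=5)
        Xs, ys, _ = autoscale(X, y)
        model = fit_pls(Xs, ys, A=4)
        gram = model.T.T @ model.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_deflation_conserves_variance(self, rng):
        X, y = _random_instance(rng, n=24, p=5)
        Xs, ys, _ = autoscale(X, y)
        model = fit_pls(Xs, ys, A=3)
        X_hat = model.T @ model.P.T
        residual = Xs - X_hat
        explained = sum(
            np.linalg.norm(np.outer(model.T[:, a], model.P[:, a])) ** 2
            for a in range(model.A)
        )
        assert explained + np.linalg.norm(residual) ** 2 == pytest.approx(
            np.linalg.norm(Xs) ** 2, rel=1e-10
        )

    def test_rank_truncation_warns(self, rng):
        base = rng.normal(size=(15, 1))
        X = np.hstack([base, base, base]) + 0.0
        X += 1e-13 * rng.normal(size=X.shape)
        y = base.ravel() + 0.1 * rng.normal(size=15)
        Xs, ys, _ = autoscale(X, y)
        with pytest.warns(UserWarning, match="truncated"):
            fit_pls(Xs, ys, A=3)


class TestCrossValidation:
    def test_fold_assignments_are_balanced_and_deterministic(self):
        a1 = fold_assignments(42, 7, seed=9)
        a2 = fold_assignments(42, 7, seed=9)
        assert np.array_equal(a1, a2)
        counts = np.bincount(a1)
        assert counts.min() == counts.max() == 6

    def test_noiseless_q2_near_one(self, rng):
        X, y = _random_instance(rng, n=30, p=3, noise=0.0)
        Xs, ys, _ = autoscale(X, y)
        assert q_squared(Xs, ys, A=3, seed=1) > 0.999

    def test_equals_brute_force_fold_recomputation(self, rng):
        """Independent fold-by-fold oracle on a 10 x 3 instance."""
        X, y = _random_instance(rng, n=10, p=3)
        Xs, ys, _ = autoscale(X, y)
        assign = fold_assignments(10, 5, seed=4)
        press = 0.0
        for f in np.unique(assign):
            test, train = assign == f, assign != f
            Xt, yt = Xs[train], ys[train]
            xm, ym = Xt.mean(0), yt.mean()
            m = fit_pls(Xt - xm, yt - ym, A=2)
            press += float(
                ((ys[test] - (ym + (Xs[test] - xm) @ m.coef_std)) ** 2).sum()
            )
        expected = 1.0 - press / float(((ys - ys.mean()) ** 2).sum())
        assert q_squared(Xs, ys, A=2, assign=assign) == pytest.approx(
            expected, rel=1e-12
        )

    def test_permuted_response_q2_nonpositive_on_average(self, rng):
        q2s = []
        for i in range(20):
            X = rng.normal(size=(40, 6))
            y = rng.normal(size=40)
            Xs, ys, _ = autoscale(X, y)
            q2s.append(q_squared(Xs, ys, A=1, seed=i))
        assert np.mean(q2s) < 0

    def test_q2_below_r2_in_expectation(self, rng):
        gaps = []
        for i in range(20):
            X, y = _random_instance(rng, n=30, p=4, noise=2.0)
            Xs, ys, _ = autoscale(X, y)
            m = fit_pls(Xs, ys, A=2)
            gaps.append(m.r2 - q_squared(Xs, ys, A=2, seed=i))
        assert np.mean(gaps) > 0


class TestSelectComponents:
    def test_two_factor_design_recovered(self, rng):
        hits = 0
        for i in range(10):
            n = 150
            f1, f2 = rng.normal(size=n), rng.normal(size=n)
            X = np.column_stack(
                [f1 + 0.1 * rng.normal(size=n) for _ in range(5)]
                + [f2 + 0.1 * rng.normal(size=n)]
            )
            y = f1 + f2 + 0.05 * rng.normal(size=n)
            Xs, ys, _ = autoscale(X, y)
            hits += select_components(Xs, ys, seed=i) == 2
        assert hits >= 9

    def test_pure_noise_single_component(self, rng):
        chosen = []
        for i in range(20):
            X = rng.normal(size=(60, 10))
            y = rng.normal(size=60)
            Xs, ys, _ = autoscale(X, y)
            chosen.append(select_components(Xs, ys, seed=i))
        assert np.mean([a == 1 for a in chosen]) >= 0.8

    def test_deterministic_given_seed(self, rng):
        X, y = _random_instance(rng, n=40, p=6)
        Xs, ys, _ = autoscale(X, y)
        assert select_components(Xs, ys, seed=7) == select_components(
            Xs, ys, seed=7
        )


class TestVIP:
    def test_single_predictor_vip_is_one(self, rng):
        X, y = _random_instance(rng, n=20, p=1)
        Xs, ys, _ = autoscale(X, y)
        model = fit_pls(Xs, ys, A=1)
        assert model.vips[0] == pytest.approx(1.0)

    def test_mean_squared_vip_is_one(self, rng):
        for _ in range(10):
            X, y = _random_instance(rng, n=25, p=5)
            Xs, ys, _ = autoscale(X, y)
            model = fit_pls(Xs, ys, A=3)
            assert (model.vips**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_informative_predictor_outranks_noise(self, rng):
        x1 = rng.normal(size=50)
        X = np.column_stack([x1, rng.normal(size=50)])
        y = 2 * x1 + 0.1 * rng.normal(size=50)
        Xs, ys, _ = autoscale(X, y)
        model = fit_pls(Xs, ys, A=2)
        assert model.vips[0] > 1 > model.vips[1]


class TestAdjustedR2:
    def test_published_model_size(self):
        # inverting the formula at n=42, k=10 reproduces the printed 0.60
        assert adjusted_r2(0.6976, 42, 10) == pytest.approx(0.60, abs=5e-4)

    def test_k_zero_identity_and_upper_bound(self, rng):
        assert adjusted_r2(0.5, 30, 0) == pytest.approx(0.5)
        for _ in range(10):
            r2 = rng.uniform(0, 1)
            n, k = int(rng.integers(10, 50)), int(rng.integers(1, 8))
            assert adjusted_r2(r2, n, k) <= r2

    def test_zero_r2_nonpositive(self):
        assert adjusted_r2(0.0, 42, 10) <= 0

    def test_saturated_model_undefined(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.8, 42, 41)
        with pytest.raises(ValueError):
            ModelFitStats(42, 77, 0.80).adjusted


class TestUnstandardized:
    def test_prediction_parity(self, rng):
        X, y = _random_instance(rng, n=25, p=4)
        model = pls_fit(X, y, A=3)
        b, b0 = unstandardized_coefficients(model)
        direct = b0 + X @ b
        assert np.allclose(direct, model.predict(X), atol=1e-10)

    def test_unit_doubling_halves_coefficient(self, rng):
        X, y = _random_instance(rng, n=25, p=3)
        m1 = pls_fit(X, y, A=3)
        X2 = X.copy()
        X2[:, 0] *= 2
        m2 = pls_fit(X2, y, A=3)
        b1, _ = unstandardized_coefficients(m1)
        b2, _ = unstandardized_coefficients(m2)
        assert b2[0] == pytest.approx(b1[0] / 2, rel=1e-8)
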