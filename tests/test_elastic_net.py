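import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

import emanet.elastic_net as enet
from emanet.elastic_net import (ConvergenceError, ElasticNetLogistic, classify,
                                fit, fit_path, kkt_residuals, lambda_max,
                                lambda_path, predict_probability)


def make_problem(seed, n=60, p=5, beta_scale=1.0):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, p))
    beta = r.normal(scale=beta_scale, size=p)
    y = (r.random(n) < expit(0.3 + X @ beta)).astype(float)
    if y.sum() in (0, n):  # pragma: no cover - keep both classes
        y[0] = 1 - y[0]
    return X, y


def penalized_objective(X, y, lam, alpha, b0, b):
    eta = b0 + X @ b
    nll = np.mean(np.logaddexp(0, eta) - y * eta)
    return nll + lam * ((1 - alpha) / 2 * np.sum(b**2) + alpha * np.sum(np.abs(b)))


class TestFit:
    def test_null_model_at_lambda_max(self):
        X, y = make_problem(0)
        lam = lambda_max(X, y, 0.7)
        f = fit(X, y, lam * 1.0001, 0.7)
        assert np.all(f.coef == 0.0)
        assert f.intercept == pytest.approx(logit(y.mean()), abs=1e-8)

    def test_unpenalized_matches_irls_mle(self):
        import statsmodels.api as sm

        X, y = make_problem(1, n=80, p=3)
        f = fit(X, y, 0.0, 0.5)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(np.r_[f.intercept, f.coef], ref.params, atol=1e-4)

    def test_pure_ridge_matches_generic_optimizer(self):
        X, y = make_problem(2, n=50, p=3)
        Xs, mean, scale, _ = enet.standardize(X)
        lam = 0.1
        f = fit(Xs, y, lam, 0.0)

        def obj(w):
            return penalized_objective(Xs, y, lam, 0.0, w[0], w[1:])

        res = minimize(obj, np.zeros(4), method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(np.r_[f.intercept, f.coef], res.x, atol=1e-4)

    def test_single_class_rejected(self):
        X, _ = make_problem(3)
        with pytest.raises(ValueError, match="both classes"):
            fit(X, np.zeros(X.shape[0]), 0.1, 0.5)

    def test_missing_values_rejected(self):
        X, y = make_problem(4)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit(X, y, 0.1, 0.5)

    def test_zero_variance_column_dropped(self):
        X, y = make_problem(5)
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            f = fit(X, y, 0.05, 0.5)
        assert f.coef[2] == 0.0 and f.dropped_features == ["x2"]

    def test_solution_improves_on_null_start(self):
        # the solver's step-halving safeguard keeps the objective monotone
        # across outer iterations; externally, every fit must end at or below
        # the null-model objective it starts from
        for seed in range(5):
            X, y = make_problem(600 + seed, n=70, p=8)
            Xs, *_ = enet.standardize(X)
            for lam, alpha in [(0.2, 0.1), (0.05, 0.5), (0.01, 1.0)]:
                f = fit(Xs, y, lam, alpha)
                b0 = f.intercept + float(f.coef @ f.feature_means)
                obj = penalized_objective(Xs, y, lam, alpha, b0, f.coef_std)
                null = penalized_objective(Xs, y, lam, alpha, logit(y.mean()),
                                           np.zeros(X.shape[1]))
                assert obj <= null + 1e-12

    def test_warm_equals_cold_start(self):
        X, y = make_problem(7, n=60, p=6)
        lams = lambda_path(X, y, 0.8, n_lambda=10, ratio=0.05)
        warm = fit_path(X, y, 0.8, lams)
        for lam, fw in zip(lams, warm):
            fc = fit(X, y, lam, 0.8)
            assert np.allclose(fw.coef, fc.coef, atol=1e-6)

    def test_kkt_conditions_hold(self):
        for seed in range(10):
            X, y = make_problem(100 + seed, n=60, p=10)
            for alpha in (0.1, 0.5, 1.0):
                lam = 0.3 * lambda_max(X, y, alpha)
                f = fit(X, y, lam, alpha, tol=1e-10)
                assert kkt_residuals(f, X, y).max() < 1e-6

    def test_convergence_error_carries_last_iterate(self):
        X, y = make_problem(8)
        with pytest.raises(ConvergenceError) as err:
            fit(X, y, 0.01, 0.5, max_sweeps=2)
        assert err.value.last_fit is not None


class TestLambdaPath:
    def test_first_entry_gives_null_model(self):
        X, y = make_problem(9)
        lams = lambda_path(X, y, 0.5, n_lambda=5, ratio=0.1)
        f = fit(X, y, lams[0], 0.5)
        assert np.all(f.coef == 0.0)

    def test_strictly_decreasing(self):
        X, y = make_problem(10)
        lams = lambda_path(X, y, 0.3, n_lambda=30, ratio=0.01)
        assert np.all(np.diff(lams) < 0)

    def test_doubling_alpha_halves_lambda_max(self):
        X, y = make_problem(11)
        assert lambda_max(X, y, 0.8) == pytest.approx(lambda_max(X, y, 0.4) / 2)

    def test_ridge_surrogate_documented(self):
        X, y = make_problem(12)
        assert lambda_max(X, y, 0.0) == pytest.approx(lambda_max(X, y, 0.001))


class TestPredict:
    def test_hand_arithmetic(self):
        f = fit(*make_problem(13, n=40, p=2), 0.1, 0.5)
        row = np.array([[0.7, -1.2]])
        expected = expit(f.intercept + 0.7 * f.coef[0] - 1.2 * f.coef[1])
        assert predict_probability(f, row)[0] == pytest.approx(expected, abs=1e-12)

    def test_null_fit_probabilities_constant_and_threshold_inclusive(self):
        X, y = make_problem(14)
        y = (np.arange(len(y)) % 2).astype(float)  # ybar = 0.5 -> intercept 0
        f = fit(X, y, 10 * lambda_max(X, y, 1.0), 1.0)
        p = predict_probability(f, X)
        assert np.allclose(p, 0.5)
        assert np.all(classify(f, X, threshold=0.5) == 1)

    def test_monotone_in_positive_coefficient(self):
        X, y = make_problem(15, n=80, p=2, beta_scale=2.0)
        f = fit(X, y, 0.01, 0.5)
        j = int(np.argmax(np.abs(f.coef)))
        base = np.zeros((1, 2))
        lo, hi = base.copy(), base.copy()
        lo[0, j], hi[0, j] = -1.0, 1.0
        plo, phi = predict_probability(f, lo)[0], predict_probability(f, hi)[0]
        assert (phi > plo) == (f.coef[j] > 0)

    def test_column_mismatch_names_columns(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(40, 2)), columns=["a", "b"])
        y = (np.arange(40) % 2).astype(float)
        f = fit(X, y, 0.1, 0.5)
        with pytest.raises(ValueError, match="missing.*'b'"):
            predict_probability(f, X.rename(columns={"b": "c"}))

    def test_json_round_trip(self):
        X, y = make_problem(16)
        f = fit(X, y, 0.05, 0.5)
        back = enet.ElasticNetFit.from_json(f.to_json())
        np.testing.assert_allclose(back.coef, f.coef)
        assert back.lam == f.lam and back.feature_names == f.feature_names


class TestReferenceImplementation:
    def test_agreement_with_sklearn_saga(self):
        from sklearn.linear_model import LogisticRegression

        failures = []
        for seed in range(20):
            X, y = make_problem(200 + seed, n=60, p=10)
            Xs, *_ = enet.standardize(X)
            alpha = (0.1, 0.5, 1.0)[seed % 3]
            lam = 0.5 * lambda_max(Xs, y, max(alpha, 0.001))
            ours = fit(Xs, y, lam, alpha, tol=1e-10)
            ref = LogisticRegression(
                penalty="elasticnet", solver="saga", l1_ratio=alpha,
                C=1.0 / (len(y) * lam), max_iter=200_000, tol=1e-10,
            ).fit(Xs, y)
            dist = np.max(np.abs(np.r_[ours.intercept, ours.coef]
                                 - np.r_[ref.intercept_, ref.coef_[0]]))
            if dist > 1e-3:
                failures.append((seed, dist))
        assert not failures


class TestEstimatorFacade:
    def test_fit_predict_api(self):
        X, y = make_problem(17)
        clf = ElasticNetLogistic(lam=0.05, alpha=0.5).fit(X, y)
        assert clf.coef_.shape == (1, X.shape[1])
        assert set(np.unique(clf.predict(X))) <= {0, 1}
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert 0.0 <= clf.score(X, y) <= 1.0

    def test_get_set_params(self):
        clf = ElasticNetLogistic()
        clf.set_params(lam=0.2, alpha=0.9)
        assert clf.get_params()["lam"] == 0.2
        with pytest.raises(ValueError):
            clf.set_params(nope=1)

    def test_works_in_sklearn_cv(self):
        from sklearn.model_selection import cross_val_score

        X, y = make_problem(18, n=90, p=4, beta_scale=2.0)
        scores = cross_val_score(ElasticNetLogistic(lam=0.02, alpha=0.5), X, y, cv=3)
        assert len(scores) == 3
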