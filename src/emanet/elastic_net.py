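"""Elastic-net penalized logistic regression by coordinate descent.

The model minimizes

    -(1/n) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
        + lambda * [ (1 - alpha)/2 * ||beta||_2^2 + alpha * ||beta||_1 ]

with p_i = logistic(beta0 + x_i' beta), the intercept unpenalized, and the
predictors z-scored internally (unit sample variance); returned coefficients
are back-transformed to the original scale.  The solver is the standard
iteratively reweighted least squares outer loop with cyclic coordinate
descent and soft-thresholding on the weighted quadratic approximation,
active-set cycling between full sweeps, and warm starts along a
log-spaced descending lambda path.

A step-halving safeguard keeps the penalized objective non-increasing across
outer iterations (the unguarded quadratic approximation is not strictly
monotone).  Probability weights are floored at 1e-5 to keep the working
response finite near fitted probabilities of 0 or 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

MAX_SWEEPS = 100_000
WEIGHT_FLOOR = 1e-5


class ConvergenceError(RuntimeError):
    """Raised when coordinate descent exhausts its sweep cap.

    Carries the last iterate in ``last_fit``.
    """

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass
class ElasticNetFit:
    """A fitted elastic-net logistic model.

    Coefficients are on the original predictor scale; ``coef_std`` holds the
    standardized-scale coefficients used for penalties, KKT checks and
    variable importance.
    """

    intercept: float
    coef: np.ndarray
    lam: float
    alpha: float
    feature_names: list
    feature_means: np.ndarray
    feature_scales: np.ndarray
    coef_std: np.ndarray
    n_iterations: int
    converged: bool
    deviance: float
    dropped_features: list = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "lambda": self.lam,
            "alpha": self.alpha,
            "feature_names": list(self.feature_names),
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "coef_std": self.coef_std.tolist(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "deviance": self.deviance,
            "dropped_features": list(self.dropped_features),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ElasticNetFit":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coef=np.array(d["coef"]),
            lam=d["lambda"],
            alpha=d["alpha"],
            feature_names=d["feature_names"],
            feature_means=np.array(d["feature_means"]),
            feature_scales=np.array(d["feature_scales"]),
            coef_std=np.array(d["coef_std"]),
            n_iterations=d["n_iterations"],
            converged=d["converged"],
            deviance=d["deviance"],
            dropped_features=d["dropped_features"],
        )


@njit(cache=False)
def _objective(X, y, lam, alpha, beta0, beta):
    n = X.shape[0]
    eta = beta0 + X @ beta
    # log(1 + exp(eta)) - y*eta, computed stably
    nll = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0:
            nll += e + np.log1p(np.exp(-e)) - y[i] * e
        else:
            nll += np.log1p(np.exp(e)) - y[i] * e
    pen = 0.0
    for j in range(beta.size):
        pen += 0.5 * (1.0 - alpha) * beta[j] ** 2 + alpha * abs(beta[j])
    return nll / n + lam * pen


@njit(cache=False)
def _cd_inner(X, w, z, lam, alpha, beta0, beta, active_only, active, tol, sweep_cap):
    """Coordinate descent on the weighted least-squares approximation.

    Updates ``beta``/``active`` in place; returns (beta0, sweeps, converged).
    ``z`` is the working response, ``w`` the observation weights; weighted
    sums are normalized by n to match the mean-loss objective.
    """
    n, p = X.shape
    r = z - beta0 - X @ beta  # residual on the working response
    wsum = w.sum()
    sweeps = 0
    for sweep in range(sweep_cap):
        sweeps += 1
        max_delta = 0.0
        # intercept (unpenalized)
        d0 = (w * r).sum() / wsum
        beta0 += d0
        r -= d0
        if abs(d0) > max_delta:
            max_delta = abs(d0)
        for j in range(p):
            if active_only and not active[j]:
                continue
            xj = X[:, j]
            wxx = 0.0
            wxr = 0.0
            for i in range(n):
                wxx += w[i] * xj[i] * xj[i]
                wxr += w[i] * xj[i] * r[i]
            num = wxr / n + beta[j] * (wxx / n)
            denom = wxx / n + lam * (1.0 - alpha)
            thr = lam * alpha
            if num > thr:
                new = (num - thr) / denom
            elif num < -thr:
                new = (num + thr) / denom
            else:
                new = 0.0
            d = new - beta[j]
            if d != 0.0:
                beta[j] = new
                r += -d * xj
                if abs(d) > max_delta:
                    max_delta = abs(d)
            active[j] = beta[j] != 0.0
        if max_delta < tol:
            return beta0, sweeps, True
    return beta0, sweeps, False


@njit(cache=False)
def _irls_cd(X, y, lam, alpha, beta0_init, beta_init, tol, sweep_cap):
    """Full solver on standardized predictors.

    Returns (beta0, beta, total_sweeps, converged).
    """
    n, p = X.shape
    beta0 = beta0_init
    beta = beta_init.copy()
    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        active[j] = beta[j] != 0.0
    total_sweeps = 0
    obj = _objective(X, y, lam, alpha, beta0, beta)
    converged = False
    for outer in range(200):
        eta = beta0 + X @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = prob * (1.0 - prob)
        for i in range(n):
            if w[i] < WEIGHT_FLOOR:
                w[i] = WEIGHT_FLOOR
        z = eta + (y - prob) / w
        b0_prev = beta0
        b_prev = beta.copy()
        # active-set pass, then a full sweep to admit new coordinates
        if active.any():
            beta0, s1, _ = _cd_inner(X, w, z, lam, alpha, beta0, beta, True, active, tol, sweep_cap)
            total_sweeps += s1
        beta0, s2, ok = _cd_inner(X, w, z, lam, alpha, beta0, beta, False, active, tol, sweep_cap)
        total_sweeps += s2
        if total_sweeps > sweep_cap:
            break
        new_obj = _objective(X, y, lam, alpha, beta0, beta)
        # step-halving safeguard: back off toward the previous iterate
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 50:
            beta0 = 0.5 * (beta0 + b0_prev)
            for j in range(p):
                beta[j] = 0.5 * (beta[j] + b_prev[j])
            new_obj = _objective(X, y, lam, alpha, beta0, beta)
            halvings += 1
        obj = new_obj
        delta = abs(beta0 - b0_prev)
        for j in range(p):
            if abs(beta[j] - b_prev[j]) > delta:
                delta = abs(beta[j] - b_prev[j])
        if delta < tol:
            converged = True
            break
    return beta0, beta, total_sweeps, converged


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns (ddof=1); returns (Xs, means, scales, zero-variance mask)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    zero_var = scales <= 0
    safe = np.where(zero_var, 1.0, scales)
    return (X - means) / safe, means, safe, zero_var


def _as_matrix(X):
    try:
        names = list(X.columns)
        return X.to_numpy(dtype=float), names
    except AttributeError:
        X = np.asarray(X, dtype=float)
        return X, [f"x{j}" for j in range(X.shape[1])]


def fit(X, y, lam: float, alpha: float, tol: float = 1e-7,
        beta0_init: float | None = None, beta_std_init: np.ndarray | None = None,
        max_sweeps: int = MAX_SWEEPS) -> ElasticNetFit:
    """Fit elastic-net logistic regression at one (lambda, alpha) pair.

    ``beta_std_init`` (standardized scale) supports warm starts along a
    lambda path.  Raises :class:`ConvergenceError` at the sweep cap and
    ValueError for a single-class outcome.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if Xm.ndim != 2 or Xm.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    if np.isnan(Xm).any():
        raise ValueError("X contains missing values; impute before fitting")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
        raise ValueError("y must contain both classes, coded 0/1")
    if not (0.0 <= alpha <= 1.0) or lam < 0:
        raise ValueError("require lambda >= 0 and alpha in [0, 1]")
    Xs, means, scales, zero_var = standardize(Xm)
    dropped = [names[j] for j in np.nonzero(zero_var)[0]]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}")
        Xs[:, zero_var] = 0.0
    ybar = y.mean()
    b0 = float(np.log(ybar / (1 - ybar))) if beta0_init is None else beta0_init
    b = np.zeros(Xm.shape[1]) if beta_std_init is None else np.asarray(beta_std_init, float).copy()
    beta0, beta_std, sweeps, converged = _irls_cd(Xs, y, lam, alpha, b0, b, tol, max_sweeps)
    beta_std = np.where(zero_var, 0.0, beta_std)
    # snap float dust to exact zero so lam >= lam_max yields an exactly-null
    # model (constant probabilities, ties handled as ties downstream)
    beta_std[np.abs(beta_std) < 1e-12] = 0.0
    coef = beta_std / scales
    intercept = beta0 - float(coef @ means)
    eta = intercept + Xm @ coef
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    deviance = -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    result = ElasticNetFit(
        intercept=float(intercept), coef=coef, lam=lam, alpha=alpha,
        feature_names=names, feature_means=means, feature_scales=scales,
        coef_std=beta_std, n_iterations=int(sweeps), converged=bool(converged),
        deviance=deviance, dropped_features=dropped,
    )
    if not converged:
        raise ConvergenceError(
            f"coordinate descent did not converge in {sweeps} sweeps "
            f"(lambda={lam:g}, alpha={alpha:g})", last_fit=result)
    return result


def lambda_max(X, y, alpha: float) -> float:
    """Smallest penalty at which all slope coefficients are zero.

    lambda_max = max_j |(1/n) sum_i x_ij (y_i - ybar)| / alpha on z-scored
    predictors.  For alpha = 0 the ridge path has no finite lambda_max; the
    conventional surrogate evaluates the formula at alpha = 0.001.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    Xs, _, _, _ = standardize(Xm)
    g = np.abs(Xs.T @ (y - y.mean())) / y.size
    a = max(alpha, 0.001)
    return float(g.max() / a)


def lambda_path(X, y, alpha: float, n_lambda: int = 100, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced descending lambda sequence from lambda_max to ratio*lambda_max."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    lmax = lambda_max(X, y, alpha)
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def fit_path(X, y, alpha: float, lambdas, tol: float = 1e-7) -> list:
    """Warm-started fits along a descending lambda sequence."""
    fits = []
    b0, b = None, None
    for lam in lambdas:
        f = fit(X, y, lam, alpha, tol=tol, beta0_init=b0, beta_std_init=b)
        fits.append(f)
        b0 = f.intercept + float(f.coef @ f.feature_means)  # back to standardized scale
        b = f.coef_std
    return fits


def predict_probability(fit_: ElasticNetFit, X) -> np.ndarray:
    """Predicted attempt probabilities logistic(beta0 + x'beta)."""
    Xm, names = _as_matrix(X)
    if names != list(fit_.feature_names):
        missing = set(fit_.feature_names) - set(names)
        extra = set(names) - set(fit_.feature_names)
        if missing or extra:
            raise ValueError(f"column mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        # same set, different order: align
        idx = [names.index(c) for c in fit_.feature_names]
        Xm = Xm[:, idx]
    eta = fit_.intercept + Xm @ fit_.coef
    return 1.0 / (1.0 + np.exp(-eta))


def classify(fit_: ElasticNetFit, X, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: positive iff probability >= threshold (inclusive)."""
    return (predict_probability(fit_, X) >= threshold).astype(int)


def kkt_residuals(fit_: ElasticNetFit, X, y) -> np.ndarray:
    """Per-coordinate KKT residuals of the penalized likelihood at the fit.

    On the standardized scale: for beta_j = 0 the residual is
    max(0, |g_j| - lambda*alpha); otherwise
    |g_j + lambda*alpha*sign(beta_j) + lambda*(1-alpha)*beta_j|.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    Xs, _, _, _ = standardize(Xm)
    eta = fit_.intercept + Xm @ fit_.coef
    p = 1.0 / (1.0 + np.exp(-eta))
    g = Xs.T @ (p - y) / y.size
    res = np.empty(g.size)
    for j in range(g.size):
        bj = fit_.coef_std[j]
        if bj == 0.0:
            res[j] = max(0.0, abs(g[j]) - fit_.lam * fit_.alpha)
        else:
            res[j] = abs(g[j] + fit_.lam * fit_.alpha * np.sign(bj) + fit_.lam * (1 - fit_.alpha) * bj)
    return res


try:  # soft dependency: full sklearn interop when it is installed
    from sklearn.base import BaseEstimator as _BaseEstimator
    from sklearn.base import ClassifierMixin as _ClassifierMixin
except ImportError:  # pragma: no cover
    _BaseEstimator = object

    class _ClassifierMixin:
        pass


class ElasticNetLogistic(_ClassifierMixin, _BaseEstimator):
    """sklearn-style estimator facade over :func:`fit`.

    Parameters
    ----------
    lam : overall shrinkage penalty (lambda >= 0).
    alpha : L1/L2 mixing in [0, 1]; 1 = lasso, 0 = ridge.
    threshold : classification cut on predicted probability (inclusive).
    tol : convergence tolerance on coefficient change per sweep.

    Fitted attributes follow the sklearn convention (trailing underscore):
    ``intercept_``, ``coef_``, ``classes_``, ``fit_`` (the full
    :class:`ElasticNetFit` record).
    """

    def __init__(self, lam: float = 0.0, alpha: float = 0.5,
                 threshold: float = 0.5, tol: float = 1e-7):
        self.lam = lam
        self.alpha = alpha
        self.threshold = threshold
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"lam": self.lam, "alpha": self.alpha,
                "threshold": self.threshold, "tol": self.tol}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        self.fit_ = fit(X, y, self.lam, self.alpha, tol=self.tol)
        self.intercept_ = self.fit_.intercept
        self.coef_ = self.fit_.coef.reshape(1, -1)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.coef_.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        p = predict_probability(self.fit_, X)
        return np.column_stack([1 - p, p])

    def decision_function(self, X) -> np.ndarray:
        p = predict_probability(self.fit_, X)
        return np.log(p / (1 - p))

    def predict(self, X) -> np.ndarray:
        return classify(self.fit_, X, threshold=self.threshold)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
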