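"""Model designs, repeated stratified cross-validation, variable importance.

Three primary designs predict the post-discharge attempt outcome:

* ``baseline`` -- the 20 SITB history predictors (participants lacking the
  baseline survey are excluded from this design only);
* ``mean`` -- the per-item means of the three EMA items (3 predictors);
* ``dynamic`` -- 24 time-series features x 3 items (72 predictors);

plus two secondary designs, ``mean+missingness`` and ``dynamic+missingness``,
which append percentage compliance.

Hyperparameters (lambda, alpha) are selected by repeated stratified k-fold
cross-validation: the full grid is fit on each training portion (with
standardization, and for the baseline design imputation, inside the fold),
held-out AUC is averaged over resamples, and the winning pair's held-out
metric distribution is reported.  Performance is therefore estimated from
the same resamples used for selection, which is mildly optimistic; that is
the convention this pipeline mirrors, and a nested-CV mode would be the
honest alternative.

With ~9 events among 83 participants, unstratified 5-fold splits can easily
produce folds with no positive case, so folds are stratified by outcome by
default (per-fold positive counts differ by at most one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import elastic_net as enet
from .baseline_features import BaselineKNNImputer
from .dynamic_features import DynamicFeatureExtractor, ITEMS
from .metrics import MetricBundle, auc, metric_bundle

MODEL_LABELS = ("baseline", "mean", "dynamic", "mean+missingness", "dynamic+missingness")


@dataclass
class CvScheme:
    """Resampling plan: k folds x r repeats, stratified by outcome."""

    n_folds: int = 5
    n_repeats: int = 3
    stratified: bool = True
    seed: int = 0

    @classmethod
    def loo(cls, seed: int = 0) -> "CvScheme":
        """Leave-one-out: one fold per participant, unstratified, single pass."""
        return cls(n_folds=0, n_repeats=1, stratified=False, seed=seed)

    @property
    def is_loo(self) -> bool:
        return self.n_folds == 0

    def splits(self, y: np.ndarray):
        """Yield (train_idx, test_idx) for every resample, deterministically."""
        y = np.asarray(y, dtype=int)
        n = y.size
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7_919]))
        if self.is_loo:
            for i in range(n):
                idx = np.arange(n)
                yield np.delete(idx, i), np.array([i])
            return
        for _ in range(self.n_repeats):
            fold_of = np.empty(n, dtype=int)
            if self.stratified:
                for cls_ in (1, 0):
                    members = np.nonzero(y == cls_)[0]
                    members = rng.permutation(members)
                    fold_of[members] = np.arange(members.size) % self.n_folds
            else:
                fold_of = rng.permutation(np.arange(n) % self.n_folds)
            for f in range(self.n_folds):
                test = np.nonzero(fold_of == f)[0]
                train = np.nonzero(fold_of != f)[0]
                yield train, test


@dataclass
class FeatureMatrix:
    """Participants x predictors design with outcome labels."""

    X: pd.DataFrame
    y: np.ndarray
    label: str
    needs_imputation: bool = False

    @property
    def participant_ids(self) -> list:
        return list(self.X.index)


@dataclass
class CvReport:
    """Selected hyperparameters plus held-out metric distribution."""

    label: str
    selected_lambda: float
    selected_alpha: float
    resample_metrics: list  # MetricBundle per resample
    mean: dict
    iqr: dict  # metric -> (q1, q3)
    final_fit: enet.ElasticNetFit = field(repr=False, default=None)
    importance: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "model": self.label,
            "selected": {"lambda": self.selected_lambda, "alpha": self.selected_alpha},
            "mean": self.mean,
            "iqr": {k: list(v) for k, v in self.iqr.items()},
            "resamples": [m.as_dict() for m in self.resample_metrics],
            "importance": (self.importance.reset_index().to_dict(orient="records")
                           if self.importance is not None else None),
        }

    def tidy_metrics(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.resample_metrics):
            for name, v in m.as_dict().items():
                rows.append({"model": self.label, "resample": i, "metric": name, "value": v})
        return pd.DataFrame(rows)


def make_design(cohort, model: str, min_completed: int = 3,
                feature_percentile: float = 90.0) -> FeatureMatrix:
    """Assemble the predictor table for one of the five model designs.

    ``cohort`` needs ``series`` (EmaSeries, already inclusion-filtered or
    not -- the filter is applied here), ``baseline`` (DataFrame) and
    ``outcomes`` (id -> 0/1).  The baseline design excludes participants
    whose baseline row is entirely missing; missing baseline cells are left
    NaN for within-fold imputation downstream.
    """
    from .ema_data import apply_inclusion_filter

    if model not in MODEL_LABELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_LABELS}")
    included, _ = apply_inclusion_filter(cohort.series, min_completed=min_completed)
    with_missing = model.endswith("+missingness")
    base_model = model.split("+")[0]
    needs_imputation = False
    if base_model == "baseline":
        table = cohort.baseline.loc[[s.participant_id for s in included
                                     if s.participant_id in cohort.baseline.index]]
        observed = ~table.isna().all(axis=1)
        if (~observed).any():
            warnings.warn(
                f"excluding {int((~observed).sum())} participant(s) without a baseline survey")
        X = table.loc[observed]
        needs_imputation = bool(X.isna().any().any())
        included = [s for s in included if s.participant_id in X.index]
    else:
        extractor = DynamicFeatureExtractor(
            percentile=feature_percentile, include_mean=True, include_compliance=True)
        wide = extractor.fit_transform(included)
        if base_model == "mean":
            cols = [f"{item}__mean" for item in ITEMS]
        else:
            from .dynamic_features import FEATURE_NAMES

            cols = [f"{item}__{feat}" for item in ITEMS for feat in FEATURE_NAMES]
        X = wide[cols].copy()
        if with_missing:
            X["compliance"] = wide["compliance"]
    if with_missing and base_model == "baseline":
        raise ValueError("the missingness secondary models augment the EMA designs only")
    y = np.array([cohort.outcomes[pid] for pid in X.index], dtype=int)
    return FeatureMatrix(X=X, y=y, label=model, needs_imputation=needs_imputation)


def default_alpha_grid() -> np.ndarray:
    return np.round(np.linspace(0.0, 1.0, 11), 2)


def cross_validate(design: FeatureMatrix, scheme: CvScheme | None = None,
                   alpha_grid=None, lambda_grid=None, n_lambda: int = 50,
                   lambda_ratio: float = 0.05, knn_k: int = 5,
                   na_policy: str = "drop", threshold: float = 0.5,
                   selection_metric: str = "auc", tol: float = 1e-7,
                   global_impute: bool = False) -> CvReport:
    """Joint hyperparameter selection and performance estimation.

    For every resample the full (alpha, lambda) grid is fit on the training
    portion (warm starts along each alpha's lambda path) and scored on the
    held-out portion; the pair maximizing the mean held-out AUC (accuracy
    behind ``selection_metric="accuracy"``) wins, with ties broken toward
    the largest lambda and then the largest alpha (prefer sparsity).  The
    final model refits all data at the winning pair.

    ``lambda_grid=None`` builds a per-alpha path from the full design so the
    same grid is scored in every resample.  ``na_policy`` controls fold
    summaries: "drop" averages over defined values, "zero" counts flagged
    metrics as 0.
    """
    scheme = scheme or CvScheme()
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("alpha grid is empty")
    if na_policy not in ("drop", "zero"):
        raise ValueError("na_policy must be 'drop' or 'zero'")
    if selection_metric not in ("auc", "accuracy"):
        raise ValueError("selection_metric must be 'auc' or 'accuracy'")
    y = np.asarray(design.y, dtype=int)
    if y.sum() < 2 and scheme.stratified:
        raise ValueError("stratified CV needs at least 2 positive outcomes")
    X_full = design.X
    if design.needs_imputation and global_impute:
        X_full = BaselineKNNImputer(k=knn_k).fit_transform(X_full)
        design = FeatureMatrix(X_full, y, design.label, needs_imputation=False)

    # shared lambda grid per alpha, anchored on the full design
    X_anchor = X_full.fillna(X_full.mean()) if design.needs_imputation else X_full
    if lambda_grid is None:
        lambdas_by_alpha = [
            enet.lambda_path(X_anchor, y, a, n_lambda=n_lambda, ratio=lambda_ratio)
            for a in alpha_grid]
    else:
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        if lambda_grid.size == 0:
            raise ValueError("lambda grid is empty")
        lambdas_by_alpha = [np.sort(lambda_grid)[::-1] for _ in alpha_grid]

    splits = list(scheme.splits(y))
    n_lam = len(lambdas_by_alpha[0])
    probs = [[[None] * n_lam for _ in alpha_grid] for _ in splits]
    for r, (train, test) in enumerate(splits):
        X_tr, X_te = X_full.iloc[train], X_full.iloc[test]
        y_tr = y[train]
        if design.needs_imputation:
            imputer = BaselineKNNImputer(k=knn_k).fit(X_tr)
            X_tr = imputer.transform(X_tr)
            X_te = imputer.transform(X_te)
        for ai, a in enumerate(alpha_grid):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fits = _fit_path_tolerant(X_tr, y_tr, a, lambdas_by_alpha[ai], tol)
            for li, f in enumerate(fits):
                probs[r][ai][li] = enet.predict_probability(f, X_te)

    # mean held-out selection score per grid pair
    best = None
    for ai, a in enumerate(alpha_grid):
        for li in range(n_lam):
            vals = []
            for r, (_, test) in enumerate(splits):
                p = probs[r][ai][li]
                if selection_metric == "auc":
                    v = auc(p, y[test])
                else:
                    v = float(np.mean((p >= threshold).astype(int) == y[test]))
                if not np.isnan(v):
                    vals.append(v)
            score = float(np.mean(vals)) if vals else -np.inf
            lam = lambdas_by_alpha[ai][li]
            key = (score, lam, a)  # ties -> largest lambda, then largest alpha
            if best is None or key > best[0]:
                best = (key, ai, li)
    (score, lam_sel, a_sel), ai_sel, li_sel = best

    bundles = []
    for r, (_, test) in enumerate(splits):
        bundles.append(metric_bundle(probs[r][ai_sel][li_sel], y[test], threshold=threshold))
    mean_summary, iqr_summary = summarize_bundles(bundles, na_policy=na_policy)

    X_final = X_full
    if design.needs_imputation:
        X_final = BaselineKNNImputer(k=knn_k).fit_transform(X_full)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        final = _fit_tolerant(X_final, y, lam_sel, a_sel, tol)
    importance = variable_importance(final)
    return CvReport(
        label=design.label, selected_lambda=float(lam_sel), selected_alpha=float(a_sel),
        resample_metrics=bundles, mean=mean_summary, iqr=iqr_summary,
        final_fit=final, importance=importance)


def _fit_tolerant(X, y, lam, alpha, tol):
    try:
        return enet.fit(X, y, lam, alpha, tol=tol)
    except enet.ConvergenceError as err:  # pragma: no cover - cap rarely hit
        warnings.warn(str(err))
        return err.last_fit


def _fit_path_tolerant(X, y, alpha, lambdas, tol):
    fits = []
    b0, b = None, None
    for lam in lambdas:
        try:
            f = enet.fit(X, y, lam, alpha, tol=tol, beta0_init=b0, beta_std_init=b)
        except enet.ConvergenceError as err:  # pragma: no cover
            f = err.last_fit
        fits.append(f)
        b0 = f.intercept + float(f.coef @ f.feature_means)
        b = f.coef_std
    return fits


def summarize_bundles(bundles, na_policy: str = "drop") -> tuple[dict, dict]:
    """Mean and IQR (25th-75th percentile) per metric over resamples."""
    mean_summary, iqr_summary = {}, {}
    for name in MetricBundle.metric_names():
        vals = np.array([getattr(m, name) for m in bundles], dtype=float)
        if na_policy == "zero":
            vals = np.nan_to_num(vals, nan=0.0)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            mean_summary[name] = np.nan
            iqr_summary[name] = (np.nan, np.nan)
        else:
            mean_summary[name] = float(np.mean(vals))
            iqr_summary[name] = (float(np.quantile(vals, 0.25)), float(np.quantile(vals, 0.75)))
    return mean_summary, iqr_summary


def variable_importance(fit: enet.ElasticNetFit) -> pd.DataFrame:
    """Coefficient importance scaled 0-100 with signs reported alongside.

    score_j = 100 |beta_j| / max_k |beta_k| on the standardized scale, so
    the scores are invariant to rescaling any original predictor column.
    All-zero coefficient vectors score 0 everywhere, with a warning.
    """
    b = np.asarray(fit.coef_std, dtype=float)
    amax = np.abs(b).max() if b.size else 0.0
    if amax == 0.0:
        warnings.warn("all coefficients are zero; importance undefined, reporting zeros")
        scores = np.zeros_like(b)
    else:
        scores = 100.0 * np.abs(b) / amax
    return pd.DataFrame(
        {"importance": scores, "sign": np.sign(b).astype(int),
         "coef_std": b, "coef": fit.coef},
        index=pd.Index(fit.feature_names, name="predictor"),
    ).sort_values("importance", ascending=False, kind="mergesort")
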