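"""Baseline self-injurious thoughts and behaviors (SITB) predictors.

The baseline design has 20 predictors: for each of four behavior classes
(suicidal thoughts, suicide plan, suicide attempt, nonsuicidal self-injury)
five characteristics -- lifetime presence (0/1), past-year / past-month /
past-week frequency counts, and self-rated likelihood of future engagement
on a 0 (not at all) to 4 (very likely) scale.

Sporadic missing entries are completed by k-nearest-neighbor imputation:
distances are Euclidean on z-scored columns observed in both rows, rescaled
by the number of shared columns, and each missing cell is replaced by the
mean of its column over the k nearest rows that observe it.  Rows with all
20 values missing cannot be imputed and are excluded with a warning (a
participant who skipped the baseline survey simply drops out of the baseline
model).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

BEHAVIORS = ("thoughts", "plan", "attempt", "nssi")
CHARACTERISTICS = ("lifetime", "freq_year", "freq_month", "freq_week", "likelihood")
BASELINE_COLUMNS = tuple(f"{b}_{c}" for b in BEHAVIORS for c in CHARACTERISTICS)


def validate_baseline(table: pd.DataFrame) -> None:
    """Check ranges: binary lifetime flags, nonnegative counts, likelihood 0-4."""
    missing_cols = [c for c in BASELINE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"baseline table lacks columns: {missing_cols}")
    problems = []
    for b in BEHAVIORS:
        col = table[f"{b}_lifetime"].dropna()
        if not col.isin([0, 1]).all():
            problems.append(f"{b}_lifetime not binary")
        for c in ("freq_year", "freq_month", "freq_week"):
            if (table[f"{b}_{c}"].dropna() < 0).any():
                problems.append(f"{b}_{c} has negative counts")
        lk = table[f"{b}_likelihood"].dropna()
        if ((lk < 0) | (lk > 4)).any():
            problems.append(f"{b}_likelihood outside 0-4")
    if problems:
        raise ValueError("invalid baseline table: " + "; ".join(problems))


class BaselineKNNImputer:
    """k-nearest-neighbor imputation transformer for the baseline table.

    sklearn-style: ``fit`` stores the reference rows and column statistics,
    ``transform`` fills the missing cells of any table with the same columns.
    Distance between a target row and a candidate row is the Euclidean norm
    over the z-scored columns both observe, divided by sqrt(number of shared
    columns), so rows sharing few columns are not spuriously close.  Distance
    ties are broken by position after a stable sort, i.e. by lowest
    participant id for an id-sorted table, which makes imputed values
    independent of row order.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k}

    def set_params(self, **params):
        for key, v in params.items():
            if key != "k":
                raise ValueError(f"invalid parameter {key!r}")
            self.k = v
        return self

    def fit(self, X: pd.DataFrame, y=None):
        X = X.sort_index(kind="mergesort")
        self.columns_ = list(X.columns)
        ref = X.to_numpy(dtype=float)
        all_missing = np.isnan(ref).all(axis=1)
        if all_missing.any():
            dropped = list(X.index[all_missing])
            warnings.warn(f"excluding fully-missing baseline rows: {dropped}")
            ref = ref[~all_missing]
        self.dropped_rows_ = list(X.index[all_missing])
        self.reference_ = ref
        self.reference_index_ = list(X.index[~all_missing])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.means_ = np.nanmean(ref, axis=0)
            self.scales_ = np.nanstd(ref, axis=0, ddof=1)
        self.scales_ = np.where(self.scales_ > 0, self.scales_, 1.0)
        observed = (~np.isnan(ref)).sum(axis=0)
        short = [c for c, n in zip(self.columns_, observed) if n < self.k]
        if short:
            raise ValueError(f"columns with fewer than k={self.k} observed values: {short}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.columns_:
            raise ValueError("column mismatch with fitted table")
        values = X.to_numpy(dtype=float)
        all_missing = np.isnan(values).all(axis=1)
        if all_missing.any():
            warnings.warn(f"excluding fully-missing baseline rows: {list(X.index[all_missing])}")
        out = values[~all_missing].copy()
        index = X.index[~all_missing]
        zref = (self.reference_ - self.means_) / self.scales_
        for i in range(out.shape[0]):
            miss = np.isnan(out[i])
            if not miss.any():
                continue
            zrow = (out[i] - self.means_) / self.scales_
            obs_row = ~np.isnan(zrow)
            # shared-column-rescaled distance to every reference row
            shared = obs_row & ~np.isnan(zref)
            n_shared = shared.sum(axis=1)
            diff = np.where(shared, zref - zrow, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.sqrt((diff**2).sum(axis=1) / n_shared)
            dist[n_shared == 0] = np.inf
            order = np.argsort(dist, kind="mergesort")  # stable: ties by position
            for j in np.nonzero(miss)[0]:
                donors = [r for r in order
                          if not np.isnan(self.reference_[r, j]) and np.isfinite(dist[r])]
                if len(donors) < 1:
                    raise ValueError(f"no donors for cell ({X.index[i]}, {self.columns_[j]})")
                take = donors[: self.k]
                out[i, j] = float(np.mean(self.reference_[take, j]))
        return pd.DataFrame(out, index=index, columns=self.columns_)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def knn_impute(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Complete a baseline table by kNN imputation (see :class:`BaselineKNNImputer`).

    Self-imputation is excluded: when the table being transformed is the
    fitted table itself, each row's nearest neighbors are the *other* rows.
    """
    imputer = BaselineKNNImputer(k=k).fit(table)
    # transform against the reference minus the row itself
    values = table.sort_index(kind="mergesort")
    values = values.loc[imputer.reference_index_]
    arr = values.to_numpy(dtype=float)
    out = arr.copy()
    means, scales = imputer.means_, imputer.scales_
    zref = (arr - means) / scales
    for i in range(arr.shape[0]):
        miss = np.isnan(arr[i])
        if not miss.any():
            continue
        zrow = zref[i]
        shared = ~np.isnan(zrow) & ~np.isnan(zref)
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, zref - zrow, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1) / n_shared)
        dist[n_shared == 0] = np.inf
        dist[i] = np.inf  # never a donor to itself
        order = np.argsort(dist, kind="mergesort")
        for j in np.nonzero(miss)[0]:
            donors = [r for r in order if not np.isnan(arr[r, j]) and np.isfinite(dist[r])]
            if len(donors) < 1:
                raise ValueError(f"no donors for cell ({values.index[i]}, {values.columns[j]})")
            out[i, j] = float(np.mean(arr[donors[: k]][:, j]))
    result = pd.DataFrame(out, index=values.index, columns=values.columns)
    return result


def missing_percent(table: pd.DataFrame) -> float:
    """Percentage of missing cells among rows with any observed value."""
    values = table.to_numpy(dtype=float)
    values = values[~np.isnan(values).all(axis=1)]
    if values.size == 0:
        return 0.0
    return round(100.0 * float(np.isnan(values).mean()), 2)


def read_baseline_table(path) -> pd.DataFrame:
    """Read the 21-column baseline CSV (participant_id + 20 predictors)."""
    df = pd.read_csv(path, dtype={"participant_id": str}).set_index("participant_id")
    validate_baseline(df)
    return df[list(BASELINE_COLUMNS)]
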