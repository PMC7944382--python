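"""Per-participant time-series features of momentary suicidal thinking.

Each EMA item (desire to die, intent to die, ability to resist the urge) is a
short, irregularly observed integer series on the 0-9 response scale.  This
module turns one such series into 24 named descriptors covering magnitude
(mean, median, min, max, range), spread (sd, variance, coefficient of
variation), shape (skewness, kurtosis, floor/ceiling shares, percentage of
unique values), instability (MSSD, RMSSD, successive-difference summaries,
maximum change, probability of acute change, shares of increases/decreases),
and temporal structure (lag-1 autocorrelation, linear trend slope).

Successive differences are taken between consecutive *completed* prompts in
time order; missing prompts are skipped, never imputed.  An optional
``max_gap`` censors differences spanning more than that many scheduled
prompts.

Features that are undefined on a given series (e.g. autocorrelation of a
constant series, any successive-difference feature with fewer than two
observations) are set to 0.0 and recorded in the vector's ``flags``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ITEMS = ("desire", "intent", "resist_urge")

FEATURE_NAMES = (
    "n_obs",
    "mean",
    "median",
    "min",
    "max",
    "range",
    "sd",
    "variance",
    "coef_variation",
    "skewness",
    "kurtosis",
    "puv",
    "prop_floor",
    "prop_ceiling",
    "mssd",
    "rmssd",
    "mean_abs_succ_diff",
    "sd_succ_diff",
    "max_change",
    "pac",
    "prob_increase",
    "prob_decrease",
    "lag1_autocorr",
    "trend_slope",
)

SCALE_MIN, SCALE_MAX = 0, 9


@dataclass
class DynamicFeatureVector:
    """The 24 features for one item of one participant.

    ``values`` maps feature name -> real value; ``flags`` names the features
    that were undefined on this series and therefore zero-filled.
    """

    participant_id: str
    item: str
    values: dict
    flags: set = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)


def successive_changes(values, max_gap: int | None = None, gaps=None) -> np.ndarray:
    """Lag-1 differences d_t = x_{t+1} - x_t between consecutive completed responses.

    ``gaps`` optionally gives, for each difference, the number of scheduled
    prompts it spans; differences with gap > max_gap are censored.
    Returns an empty array for fewer than two observations.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return np.array([], dtype=float)
    d = np.diff(x)
    if max_gap is not None and gaps is not None:
        g = np.asarray(gaps)
        if g.size != d.size:
            raise ValueError("gaps must have one entry per difference")
        d = d[g <= max_gap]
    return d


def mssd(values) -> float:
    """Mean square successive difference: sum(d_t^2) / (m - 1).

    The classical instability index -- the variance of observation-to-next
    changes about zero.  Undefined (NaN) for fewer than two observations.
    """
    d = successive_changes(values)
    if d.size == 0:
        return np.nan
    return float(np.sum(d**2) / d.size)


def pac(values, percentile: float = 90.0, change_scale: str = "absolute",
        threshold: float | None = None) -> float:
    """Probability of acute change: acute changes / total changes.

    An acute change is a successive change at or above the stated percentile
    (linear-interpolation quantile) of a reference change distribution --
    absolute changes by default, signed if requested.  When ``threshold`` is
    None the reference is the participant's *own* change distribution; the
    cohort pipeline instead passes a threshold precomputed from the pooled
    change distribution of the whole sample (see
    :class:`DynamicFeatureExtractor`), under which PAC genuinely measures how
    often a participant shifts by an amount that is extreme for the study
    population rather than sitting near 10% by construction.

    A series whose changes are all exactly zero has no acute change and
    scores 0 under the own-distribution rule (without this rule the
    inclusive threshold would score a constant series as 1).  NaN for fewer
    than two observations.
    """
    d = successive_changes(values)
    if d.size == 0:
        return np.nan
    if change_scale == "absolute":
        d = np.abs(d)
    elif change_scale != "signed":
        raise ValueError("change_scale must be 'absolute' or 'signed'")
    if threshold is None:
        if np.all(d == 0):
            return 0.0
        threshold = np.quantile(d, percentile / 100.0)  # linear interpolation
    return float(np.mean(d >= threshold))


def pooled_change_threshold(series_values, percentile: float = 90.0,
                            change_scale: str = "absolute") -> float:
    """Percentile of the change distribution pooled over many series."""
    chunks = []
    for values in series_values:
        d = successive_changes(values)
        if d.size:
            chunks.append(np.abs(d) if change_scale == "absolute" else d)
    if not chunks:
        return np.nan
    return float(np.quantile(np.concatenate(chunks), percentile / 100.0))


def _lag1_autocorr(x: np.ndarray) -> float:
    """Pearson correlation of (x_t, x_{t+1}) pairs; NaN if either margin is constant."""
    if x.size < 3:
        return np.nan
    a, b = x[:-1], x[1:]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _trend_slope(x: np.ndarray) -> float:
    """Least-squares slope of response on completed-prompt order (0, 1, ...)."""
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0 if x.size >= 2 else np.nan
    t = np.arange(x.size, dtype=float)
    return float(np.polyfit(t, x, 1)[0])


def compute_features(values, percentile: float = 90.0,
                     pac_threshold: float | None = None) -> tuple[dict, set]:
    """All 24 features for one observed series; returns (values, undefined-flags).

    ``pac_threshold`` switches PAC from the own-distribution percentile rule
    to a fixed (e.g. cohort-pooled) acute-change threshold.
    """
    x = np.asarray(values, dtype=float)
    m = x.size
    out: dict = {}
    flags: set = set()

    def put(name, v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[name] = 0.0
            flags.add(name)
        else:
            out[name] = float(v)

    put("n_obs", float(m))
    if m == 0:
        for name in FEATURE_NAMES[1:]:
            put(name, None)
        return out, flags
    put("mean", np.mean(x))
    put("median", np.median(x))
    put("min", np.min(x))
    put("max", np.max(x))
    put("range", np.ptp(x))
    sd = np.std(x, ddof=1) if m >= 2 else np.nan
    put("sd", sd)
    put("variance", sd**2 if m >= 2 else np.nan)
    mean = np.mean(x)
    put("coef_variation", sd / mean if (m >= 2 and mean != 0) else np.nan)
    put("skewness", stats.skew(x) if (m >= 3 and np.ptp(x) > 0) else np.nan)
    put("kurtosis", stats.kurtosis(x) if (m >= 4 and np.ptp(x) > 0) else np.nan)
    put("puv", np.unique(x).size / m)
    put("prop_floor", np.mean(x == SCALE_MIN))
    put("prop_ceiling", np.mean(x == SCALE_MAX))

    d = successive_changes(x)
    if d.size == 0:
        for name in (
            "mssd",
            "rmssd",
            "mean_abs_succ_diff",
            "sd_succ_diff",
            "max_change",
            "pac",
            "prob_increase",
            "prob_decrease",
        ):
            put(name, None)
    else:
        ms = np.sum(d**2) / d.size
        put("mssd", ms)
        put("rmssd", np.sqrt(ms))
        put("mean_abs_succ_diff", np.mean(np.abs(d)))
        put("sd_succ_diff", np.std(d, ddof=1) if d.size >= 2 else np.nan)
        put("max_change", np.max(np.abs(d)))
        put("pac", pac(x, percentile=percentile, threshold=pac_threshold))
        put("prob_increase", np.mean(d > 0))
        put("prob_decrease", np.mean(d < 0))
    put("lag1_autocorr", _lag1_autocorr(x))
    put("trend_slope", _trend_slope(x))
    return out, flags


def extract_features(series, item: str, percentile: float = 90.0,
                     pac_threshold: float | None = None) -> DynamicFeatureVector:
    """Extract the 24-feature vector for one EMA item of one participant.

    Operates on the item's completed (non-missing) responses in time order.
    """
    if item not in ITEMS:
        raise ValueError(f"unknown item {item!r}; expected one of {ITEMS}")
    x = series.item_values(item)
    values, flags = compute_features(x, percentile=percentile, pac_threshold=pac_threshold)
    return DynamicFeatureVector(series.participant_id, item, values, flags)


def mean_model_features(series) -> dict:
    """Arithmetic mean of completed responses for each of the three items."""
    out = {}
    for item in ITEMS:
        x = series.item_values(item)
        out[f"{item}__mean"] = float(np.mean(x)) if x.size else np.nan
    return out


class DynamicFeatureExtractor:
    """Transformer from a collection of :class:`~emanet.ema_data.EmaSeries`
    to a wide participants x features table.

    sklearn-style: ``transform(cohort)`` returns a DataFrame with one row per
    participant and 72 columns named ``item__feature`` (24 features x 3
    items), plus ``<item>__mean`` mean-model columns and ``compliance``.

    ``pac_mode`` selects the acute-change threshold convention:

    * ``"pooled"`` (default) -- ``fit`` learns, per item, the stated
      percentile of the change distribution pooled over the whole cohort;
      each participant's PAC is their share of changes at or above that
      common threshold.  A participant with many population-extreme shifts
      then scores high, which is the behavior the feature is meant to have.
    * ``"within"`` -- the threshold is each participant's own percentile,
      making PAC a shape statistic of the individual change distribution
      (it hovers near ``1 - percentile/100`` whenever ties are rare).
    """

    def __init__(self, percentile: float = 90.0, pac_mode: str = "pooled",
                 include_mean: bool = True, include_compliance: bool = True):
        self.percentile = percentile
        self.pac_mode = pac_mode
        self.include_mean = include_mean
        self.include_compliance = include_compliance

    def get_params(self, deep: bool = True) -> dict:
        return {
            "percentile": self.percentile,
            "pac_mode": self.pac_mode,
            "include_mean": self.include_mean,
            "include_compliance": self.include_compliance,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, cohort, y=None):
        if self.pac_mode not in ("pooled", "within"):
            raise ValueError("pac_mode must be 'pooled' or 'within'")
        self.pac_thresholds_ = {}
        if self.pac_mode == "pooled":
            cohort = list(cohort)
            for item in ITEMS:
                self.pac_thresholds_[item] = pooled_change_threshold(
                    (s.item_values(item) for s in cohort), percentile=self.percentile)
        return self

    def transform(self, cohort):
        import pandas as pd

        if not hasattr(self, "pac_thresholds_"):
            raise RuntimeError("extractor not fitted; call fit or fit_transform first")
        rows = []
        for series in cohort:
            row = {"participant_id": series.participant_id}
            for item in ITEMS:
                fv = extract_features(series, item, percentile=self.percentile,
                                      pac_threshold=self.pac_thresholds_.get(item))
                for name in FEATURE_NAMES:
                    row[f"{item}__{name}"] = fv.values[name]
            if self.include_mean:
                row.update(mean_model_features(series))
            if self.include_compliance:
                row["compliance"] = series.compliance_percent()
            rows.append(row)
        return pd.DataFrame(rows).set_index("participant_id")

    def fit_transform(self, cohort, y=None):
        return self.fit(cohort).transform(cohort)
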