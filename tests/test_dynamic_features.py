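import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emanet.dynamic_features import (FEATURE_NAMES, DynamicFeatureExtractor,
                                     compute_features, extract_features,
                                     mean_model_features, mssd, pac,
                                     pooled_change_threshold, successive_changes)

from conftest import make_series

TOY = [0, 0, 9, 9, 0]


def brute_force_features(x):
    """Naive-loop recomputation of every feature, independent of the library path."""
    x = [float(v) for v in x]
    m = len(x)
    out = {"n_obs": float(m)}
    out["mean"] = sum(x) / m
    out["median"] = float(np.median(x))
    out["min"], out["max"] = min(x), max(x)
    out["range"] = max(x) - min(x)
    if m >= 2:
        var = sum((v - out["mean"]) ** 2 for v in x) / (m - 1)
        out["variance"], out["sd"] = var, var**0.5
    else:
        out["variance"] = out["sd"] = 0.0
    out["coef_variation"] = out["sd"] / out["mean"] if (m >= 2 and out["mean"] != 0) else 0.0
    if m >= 3 and out["range"] > 0:
        mu = out["mean"]
        s_pop = (sum((v - mu) ** 2 for v in x) / m) ** 0.5
        out["skewness"] = sum((v - mu) ** 3 for v in x) / m / s_pop**3
    else:
        out["skewness"] = 0.0
    if m >= 4 and out["range"] > 0:
        mu = out["mean"]
        s2 = sum((v - mu) ** 2 for v in x) / m
        out["kurtosis"] = sum((v - mu) ** 4 for v in x) / m / s2**2 - 3.0
    else:
        out["kurtosis"] = 0.0
    out["puv"] = len(set(x)) / m
    out["prop_floor"] = sum(v == 0 for v in x) / m
    out["prop_ceiling"] = sum(v == 9 for v in x) / m
    d = [x[i + 1] - x[i] for i in range(m - 1)]
    if d:
        out["mssd"] = sum(v * v for v in d) / len(d)
        out["rmssd"] = out["mssd"] ** 0.5
        out["mean_abs_succ_diff"] = sum(abs(v) for v in d) / len(d)
        out["sd_succ_diff"] = (
            (sum((v - sum(d) / len(d)) ** 2 for v in d) / (len(d) - 1)) ** 0.5
            if len(d) >= 2 else 0.0)
        out["max_change"] = max(abs(v) for v in d)
        ad = sorted(abs(v) for v in d)
        if all(v == 0 for v in ad):
            out["pac"] = 0.0
        else:
            thr = float(np.quantile(ad, 0.9))
            out["pac"] = sum(v >= thr for v in ad) / len(ad)
        out["prob_increase"] = sum(v > 0 for v in d) / len(d)
        out["prob_decrease"] = sum(v < 0 for v in d) / len(d)
    else:
        for k in ("mssd", "rmssd", "mean_abs_succ_diff", "sd_succ_diff",
                  "max_change", "pac", "prob_increase", "prob_decrease"):
            out[k] = 0.0
    if m >= 3 and len(set(x[:-1])) > 1 and len(set(x[1:])) > 1:
        out["lag1_autocorr"] = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    else:
        out["lag1_autocorr"] = 0.0
    if m >= 2 and out["range"] > 0:
        t = list(range(m))
        tbar, xbar = sum(t) / m, out["mean"]
        out["trend_slope"] = (sum((ti - tbar) * (xi - xbar) for ti, xi in zip(t, x))
                              / sum((ti - tbar) ** 2 for ti in t))
    else:
        out["trend_slope"] = 0.0 if m >= 2 else 0.0
    return out


class TestSuccessiveChanges:
    def test_definition(self):
        assert successive_changes(TOY).tolist() == [0, 9, 0, -9]

    def test_constant(self):
        assert successive_changes([5, 5, 5]).tolist() == [0, 0]

    def test_single_observation_empty(self):
        assert successive_changes([4]).size == 0

    def test_max_gap_censors_long_spans(self):
        d = successive_changes([1, 5, 2], max_gap=1, gaps=[1, 3])
        assert d.tolist() == [4]


class TestMssd:
    def test_toy(self):
        assert mssd(TOY) == pytest.approx(40.5)

    def test_constant_zero(self):
        assert mssd([4, 4, 4, 4]) == 0.0

    def test_translation_invariance(self):
        assert mssd([1, 3, 2, 5]) == pytest.approx(mssd([3, 5, 4, 7]))

    def test_short_series_flagged_missing(self):
        assert np.isnan(mssd([7]))


class TestPac:
    def test_toy(self):
        # abs changes {0,9,0,9}; P90 = 9; two of four qualify
        assert pac(TOY) == pytest.approx(0.5)

    def test_constant_series_zero(self):
        assert pac([4, 4, 4, 4]) == 0.0

    def test_at_least_one_change_meets_inclusive_threshold(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, rng.integers(3, 15))
            if np.ptp(np.diff(x)) == 0 and (np.diff(x) == 0).all():
                continue
            p = pac(x)
            assert p >= 1 / (x.size - 1) - 1e-12

    def test_fixed_threshold_counts_exceedances(self):
        assert pac([0, 0, 9, 9, 0], threshold=5.0) == pytest.approx(0.5)
        assert pac([0, 1, 0, 1, 0], threshold=5.0) == 0.0

    def test_pooled_threshold_across_series(self):
        t = pooled_change_threshold([[0, 0, 0, 0], [0, 9, 0, 9]])
        assert t == pytest.approx(np.quantile([0, 0, 0, 9, 9, 9], 0.9))


class TestExtractFeatures:
    def test_toy_values(self, toy_series):
        fv = extract_features(toy_series, "desire")
        assert fv["puv"] == pytest.approx(0.4)
        assert fv["max_change"] == 9
        assert fv["n_obs"] == 5
        assert fv["mean"] == pytest.approx(3.6)
        assert fv["mssd"] == pytest.approx(40.5)
        assert fv["pac"] == pytest.approx(0.5)

    def test_monotone_line(self):
        s = make_series("M", [1, 2, 3, 4, 5])
        fv = extract_features(s, "desire")
        assert fv["prob_increase"] == 1.0
        assert fv["prob_decrease"] == 0.0
        assert fv["trend_slope"] == pytest.approx(1.0)

    def test_reflection_invariance(self):
        a = make_series("A", [1, 4, 0, 7, 2])
        b = make_series("B", [8, 5, 9, 2, 7])  # 9 - x
        fa = extract_features(a, "desire")
        fb = extract_features(b, "desire")
        for name in ("sd", "mssd", "pac", "max_change"):
            assert fa[name] == pytest.approx(fb[name])

    def test_translation_changes_location_not_spread(self):
        a = make_series("A", [1, 3, 2, 4, 1])
        b = make_series("B", [3, 5, 4, 6, 3])
        fa, fb = extract_features(a, "desire"), extract_features(b, "desire")
        for name in ("mean", "median", "min", "max"):
            assert fb[name] == pytest.approx(fa[name] + 2)
        for name in ("sd", "variance", "mssd", "rmssd", "pac", "max_change",
                     "prob_increase", "prob_decrease"):
            assert fb[name] == pytest.approx(fa[name])

    def test_permutation_sensitivity(self):
        ordered = make_series("O", [0, 1, 2, 7, 8, 9])
        shuffled = make_series("S", [7, 0, 9, 1, 8, 2])
        fo, fs = extract_features(ordered, "desire"), extract_features(shuffled, "desire")
        assert fo["mean"] == pytest.approx(fs["mean"])
        assert fo["sd"] == pytest.approx(fs["sd"])
        assert fo["mssd"] != pytest.approx(fs["mssd"])

    def test_missing_prompts_skipped(self):
        s = make_series("G", [0, None, None, 9, 9, None, 0])
        fv = extract_features(s, "desire")
        assert fv["n_obs"] == 4
        # diffs between consecutive completed prompts: 9, 0, -9
        assert fv["mssd"] == pytest.approx((81 + 0 + 81) / 3)

    def test_all_missing_item_flagged(self):
        s = make_series("E", [None, None, None])
        fv = extract_features(s, "desire")
        assert fv["n_obs"] == 0
        assert len(fv.flags) == len(FEATURE_NAMES) - 1

    def test_oracle_equivalence_on_random_series(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 40))
            x = rng.integers(0, 10, m)
            got, _ = compute_features(x)
            want = brute_force_features(x)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-10), name

    @given(st.lists(st.integers(0, 9), min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_bounded_features_stay_in_range(self, xs):
        f, _ = compute_features(np.array(xs, dtype=float))
        for name in ("puv", "pac", "prob_increase", "prob_decrease",
                     "prop_floor", "prop_ceiling"):
            assert 0.0 <= f[name] <= 1.0
        assert f["prob_increase"] + f["prob_decrease"] <= 1.0 + 1e-12
        assert f["mssd"] >= 0 and f["rmssd"] >= 0 and f["sd"] >= 0
        assert f["min"] <= f["mean"] <= f["max"]
        assert f["max_change"] >= 0


class TestMeanModelAndExtractor:
    def test_mean_model_ignores_missing(self):
        s = make_series("X", [0, None, 9, None, 9, 0])
        means = mean_model_features(s)
        assert means["desire__mean"] == pytest.approx(4.5)
        assert means["resist_urge__mean"] == pytest.approx(4.5)

    def test_wide_table_shape(self, small_cohort):
        from emanet.ema_data import apply_inclusion_filter

        included, _ = apply_inclusion_filter(small_cohort.series)
        wide = DynamicFeatureExtractor().fit_transform(included)
        assert wide.shape[0] == len(included)
        # 72 dynamic + 3 mean-model (shared columns with the dynamic set) + compliance
        assert wide.shape[1] == 73
        assert "compliance" in wide.columns

    def test_transform_requires_fit(self, small_cohort):
        with pytest.raises(RuntimeError):
            DynamicFeatureExtractor().transform(small_cohort.series[:2])

    def test_get_set_params_roundtrip(self):
        ex = DynamicFeatureExtractor()
        ex.set_params(percentile=85.0, pac_mode="within")
        assert ex.get_params()["percentile"] == 85.0
        with pytest.raises(ValueError):
            ex.set_params(bogus=1)
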