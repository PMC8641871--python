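"""Smoothing, global-fit metrics, season intervals/deltas, composite score."""
import numpy as np
import pandas as pd
import pytest

from gravidnet import (
    AbundanceCurve,
    DegenerateSeasonError,
    ValidationError,
    build_baseline,
    composite_score,
    evaluate_curves,
    extract_intervals,
    global_fit,
    predict_curve,
    season_deltas,
    season_length,
    smooth_curve,
)


def curve(values, start="2016-01-01", loc="c", smoothed=False):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return AbundanceCurve(loc, dates, values, smoothed=smoothed)


def bump_year(peak_day=200, width=45.0, start="2016-01-01"):
    """One calendar year with a smooth mid-season bump, zero at the edges."""
    doy = np.arange(1, 367 if start == "2016-01-01" else 366, dtype=float)
    vals = np.exp(-0.5 * ((doy - peak_day) / width) ** 2)
    vals[vals < 1e-4] = 0.0
    return curve(vals, start=start)


class TestPredictCurve:
    def test_window_count_and_zero_model(self, rng, simple_scaler):
        from conftest import random_weather

        series = random_weather(rng, 100)
        model = build_baseline(90, seed=0)
        model.set_weights([np.zeros_like(w) for w in model.get_weights()])
        out = predict_curve(model, series, simple_scaler, delta=90)
        assert len(out) == 11
        assert (out.values == 0).all()
        assert out.dates[0] == series.dates[89]

    def test_matches_single_sample_forward_passes(self, rng, simple_scaler):
        from conftest import random_weather
        from gravidnet import ArchitectureSpec, build_model, make_windows

        series = random_weather(rng, 30)
        spec = ArchitectureSpec(variant="GRU", delta=12, conv_filters=4, units=3)
        model = build_model(spec, seed=5)
        out = predict_curve(model, series, simple_scaler, delta=12)
        ws = make_windows(series, simple_scaler, delta=12)
        singles = np.array([model.predict(ws.x[i:i + 1])[0] for i in range(len(ws))])
        np.testing.assert_allclose(out.values, np.clip(singles, 0, None), rtol=1e-12)

    def test_baseline_negatives_clamped(self, rng, simple_scaler):
        from conftest import random_weather

        series = random_weather(rng, 30)
        model = build_baseline(12, seed=0)
        weights = model.get_weights()
        weights[1][:] = -100.0  # strongly negative bias
        model.set_weights(weights)
        out = predict_curve(model, series, simple_scaler, delta=12)
        assert (out.values == 0).all()


class TestSmoothing:
    def test_cubic_polynomial_is_preserved(self):
        t = np.arange(60, dtype=float)
        cubic = 5.0 + 0.3 * t + 0.02 * t**2 - 0.0002 * t**3
        assert (cubic > 0).all()
        out = smooth_curve(curve(cubic))
        np.testing.assert_allclose(out.values, cubic, atol=1e-8)

    def test_constant_preserved(self):
        out = smooth_curve(curve(np.full(30, 5.0)))
        np.testing.assert_allclose(out.values, 5.0)

    def test_interior_matches_per_window_cubic_fit(self, rng):
        vals = rng.random(40) * 3
        out = smooth_curve(curve(vals))
        t = np.arange(-5, 6, dtype=float)
        for i in range(5, 35):
            coef = np.polynomial.polynomial.polyfit(t, vals[i - 5:i + 6], 3)
            assert out.values[i] == pytest.approx(max(0.0, coef[0]), abs=1e-10)

    def test_negatives_clamped_to_zero(self):
        vals = np.zeros(30)
        vals[14] = 10.0  # a spike forces negative side lobes in the cubic fit
        out = smooth_curve(curve(vals))
        assert (out.values >= 0).all()
        assert out.values.min() == 0.0

    def test_positive_scaling_commutes(self, rng):
        vals = rng.random(50) + 1.0
        a = 3.7
        s1 = smooth_curve(curve(a * vals)).values
        s2 = smooth_curve(curve(vals)).values
        if (savgol := s2).min() > 0:  # clamp inactive: exact linearity
            np.testing.assert_allclose(s1, a * s2, rtol=1e-10)

    def test_short_curve_rejected(self):
        with pytest.raises(Exception):
            smooth_curve(curve(np.ones(10)))


class TestGlobalFit:
    def test_perfect_prediction(self, rng):
        vals = rng.random(50) + 0.5
        fit = global_fit(vals, vals.copy())
        assert (fit.r2_plus, fit.nrmse, fit.rel_auc) == (1.0, 0.0, 0.0)
        assert fit.r == pytest.approx(1.0, abs=1e-12)

    def test_constant_curves_hand_computation(self):
        fit = global_fit(np.full(4, 2.0), np.full(4, 3.0))
        assert fit.undefined  # R+2 and r undefined for a constant reference
        assert fit.nrmse == pytest.approx(0.5)
        assert fit.rel_auc == pytest.approx(-0.5)

    def test_mean_predictor_scores_zero(self, rng):
        vals = rng.random(60)
        fit = global_fit(vals, np.full(60, vals.mean()))
        assert fit.r2_plus == 0.0

    def test_matches_textbook_implementations(self, rng):
        """Agreement with scikit-learn R^2 and scipy Pearson r to 1e-10."""
        from scipy.stats import pearsonr
        from sklearn.metrics import r2_score

        for _ in range(200):
            ref = rng.random(30) + 0.2
            pred = ref + rng.normal(0, 0.3, 30)
            fit = global_fit(ref, pred)
            assert fit.r2_plus == pytest.approx(max(0.0, r2_score(ref, pred)), abs=1e-10)
            assert fit.r == pytest.approx(pearsonr(ref, pred).statistic, abs=1e-10)
            assert fit.nrmse == pytest.approx(
                np.sqrt(np.mean((ref - pred) ** 2)) / ref.mean(), abs=1e-12)

    def test_zero_reference_rejected_for_rel_auc(self):
        with pytest.raises(ValidationError):
            global_fit(np.zeros(10), np.ones(10))


class TestIntervals:
    def test_always_above(self):
        iv = extract_intervals(np.full(20, 9.0), threshold=5.0)
        assert iv.intervals == ((0, 19),) and not iv.not_reached

    def test_never_above(self):
        iv = extract_intervals(np.ones(20), threshold=5.0)
        assert iv.intervals == () and iv.not_reached

    def test_merge_rule_hand_trace(self):
        vals = [0, 0, 9, 9, 0, 9, 9, 9, 0]
        iv = extract_intervals(np.array(vals, float), threshold=5.0,
                               max_gap=2, min_dwell=2)
        assert iv.intervals == ((2, 7),)

    def test_dwell_discards_short_runs(self):
        vals = np.zeros(30)
        vals[5:8] = 9.0   # 3 days, below dwell
        vals[15:25] = 9.0  # 10 days, kept
        iv = extract_intervals(vals, threshold=5.0, max_gap=3, min_dwell=5)
        assert iv.intervals == ((15, 24),)

    def test_season_length_at_20_percent(self):
        iv = extract_intervals(bump_year().values, 0.2 * bump_year().values.max())
        assert season_length(iv) == iv.intervals[-1][1] - iv.intervals[0][0]


class TestSeasonDeltas:
    def test_identical_intervals_zero_deltas(self):
        ref = extract_intervals(bump_year().values, 0.3)
        d = season_deltas(ref, ref, mean_season_length=150.0)
        assert all(v == 0.0 for v in d.d_on + d.d_off)
        assert d.unmatched_reference == d.unmatched_prediction == 0

    def test_five_day_shift_scaled_by_200(self):
        base = bump_year().values
        shifted = np.roll(base, 5)
        for frac in (0.2, 0.4, 0.6, 0.8):
            thr = frac * base.max()
            d = season_deltas(extract_intervals(base, thr),
                              extract_intervals(shifted, thr),
                              mean_season_length=200.0)
            assert d.d_on == (pytest.approx(0.025),)
            assert d.d_off == (pytest.approx(0.025),)

    def test_two_reference_one_prediction(self):
        doy = np.arange(1, 366, dtype=float)
        double = (np.exp(-0.5 * ((doy - 120) / 20) ** 2)
                  + np.exp(-0.5 * ((doy - 260) / 20) ** 2))
        single = np.exp(-0.5 * ((doy - 125) / 20) ** 2)
        thr = 0.5
        d = season_deltas(extract_intervals(double, thr),
                          extract_intervals(single, thr), 150.0)
        assert len(d.d_on) == 1
        assert d.unmatched_reference == 1 and d.unmatched_prediction == 0
        # matched to the nearer (first) reference interval
        assert abs(d.d_on[0]) < 10 / 150.0

    def test_degenerate_season_length(self):
        iv = extract_intervals(np.full(10, 9.0), 5.0)
        with pytest.raises(DegenerateSeasonError):
            season_deltas(iv, iv, 0.0)


class TestCompositeScore:
    def _report(self, ref_curves, pred_curves):
        return evaluate_curves(ref_curves, {"m": pred_curves})

    def test_perfect_prediction_scores_zero(self):
        ref = {"a": bump_year()}
        report = self._report(ref, {"a": bump_year()})
        assert composite_score(report, "m") == 0.0

    def test_score_increases_with_error(self, rng):
        ref = {"a": bump_year()}
        noisy_vals = np.clip(bump_year().values
                             + rng.normal(0, 0.1, 366), 0, None)
        very_noisy = np.clip(bump_year().values
                             + rng.normal(0, 0.35, 366), 0, None)
        s_small = composite_score(self._report(ref, {"a": curve(noisy_vals)}), "m")
        s_large = composite_score(self._report(ref, {"a": curve(very_noisy)}), "m")
        assert 0.0 < s_small < s_large

    def test_report_row_counts_and_aggregates(self, small_benchmark):
        """One global-fit row per model-location-year; aggregates equal
        brute-force means over rows."""
        locs = small_benchmark.split.test_locations
        refs = {l: small_benchmark.abundance[l] for l in locs}
        preds = {"self": refs, "shift": {
            l: AbundanceCurve(l, refs[l].dates, np.roll(refs[l].values, 3),
                              smoothed=False) for l in locs}}
        years = [2015, 2016]
        report = evaluate_curves(refs, preds, years=years)
        assert len(report.global_rows) == 2 * len(locs) * len(years)
        g = report.global_rows.query("model == 'shift' and ~undefined")
        agg = report.aggregates("shift")
        assert agg["mean_r2_plus"] == pytest.approx(g["r2_plus"].mean())
        assert agg["mean_abs_rel_auc"] == pytest.approx(g["rel_auc"].abs().mean())

    def test_empty_report_rejected(self):
        report = evaluate_curves({}, {})
        with pytest.raises(ValidationError):
            composite_score(report, "m")

    def test_ranking_follows_r2_when_other_terms_tied(self):
        """Two models differing only in curve shape fidelity rank by R+2."""
        ref = {"a": bump_year()}
        good = bump_year().values * 1.0
        t = np.arange(366, dtype=float)
        warped = np.interp(t, t, bump_year(peak_day=203).values)
        r_good = self._report(ref, {"a": curve(good)})
        r_warp = self._report(ref, {"a": curve(warped)})
        s_good = composite_score(r_good, "m")
        s_warp = composite_score(r_warp, "m")
        assert s_good < s_warp
        assert (r_good.aggregates("m")["mean_r2_plus"]
                > r_warp.aggregates("m")["mean_r2_plus"])
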