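"""Post-processing and scoring of predicted abundance curves.

Raw daily network outputs are smoothed with a window-11, order-3
Savitzky-Golay filter (the central point of each local cubic fit), negatives
clamped to zero. Smoothed curves are scored per location-year against the
reference with four global-fit metrics,

    R+^2      = max(0, 1 - SS_res / SS_tot)          (nonnegative R^2)
    NRMSE     = RMSE / mean(reference)
    RelAUC    = (AUC_ref - AUC_pred) / AUC_ref       (trapezoidal AUC)
    r         = Pearson correlation,

and with season-timing metrics: at thresholds of 20/40/60/80% of the
reference peak, intervals where a curve stably remains above the threshold
are extracted (runs merged across gaps shorter than ``max_gap`` days, merged
runs shorter than ``min_dwell`` days discarded), matched greedily between
prediction and reference by nearest onset, and the onset/offset differences
D_on, D_off are scaled by the location's mean 20%-threshold season length.
A composite score S (lower is better) aggregates the means and standard
deviations of all error terms plus a penalty for thresholds the prediction
never reached.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import DegenerateSeasonError, InsufficientHistoryError, ValidationError
from .networks import Model
from .weather import AbundanceCurve, ScalerParams, WeatherSeries, make_windows

SMOOTH_WINDOW = 11
SMOOTH_ORDER = 3
DEFAULT_THRESHOLDS = (20, 40, 60, 80)  # percent of reference peak
MIN_DWELL = 7   # days a merged run must last to count as "stably above"
MAX_GAP = 7     # runs separated by shorter gaps are merged
NOT_REACHED_WEIGHT = 1.0  # lambda in the composite score


# ---------------------------------------------------------------------------
# Prediction and smoothing
# ---------------------------------------------------------------------------

def predict_curve(model: Model, weather: WeatherSeries, scaler: ScalerParams,
                  delta: int = 90) -> AbundanceCurve:
    """Raw (unsmoothed) daily abundance curve via the sliding window.

    One prediction per admissible day; negative raw outputs (possible only
    for the linear baseline) are clamped at zero.
    """
    windows = make_windows(weather, scaler, targets=None, delta=delta)
    values = np.clip(model.predict(windows.x), 0.0, None)
    return AbundanceCurve(weather.location_id, windows.t0, values, smoothed=False)


def smooth_curve(curve: AbundanceCurve) -> AbundanceCurve:
    """Savitzky-Golay (window 11, order 3) smoothing with zero clamping."""
    if len(curve) < SMOOTH_WINDOW:
        raise InsufficientHistoryError(
            f"curve of length {len(curve)} is shorter than the {SMOOTH_WINDOW}-day window")
    smoothed = savgol_filter(curve.values, SMOOTH_WINDOW, SMOOTH_ORDER, mode="interp")
    return AbundanceCurve(curve.location_id, curve.dates,
                          np.clip(smoothed, 0.0, None), smoothed=True)


# ---------------------------------------------------------------------------
# Global fit metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GlobalFit:
    r2_plus: float
    nrmse: float
    rel_auc: float
    r: float
    undefined: bool = False


def global_fit(reference: np.ndarray | AbundanceCurve,
               predicted: np.ndarray | AbundanceCurve) -> GlobalFit:
    """Compute (R+^2, NRMSE, RelAUC, r) for a pair of equal-length curves.

    A constant reference makes R+^2 and r undefined; such pairs are flagged
    and excluded from aggregates.
    """
    ref = np.asarray(reference.values if isinstance(reference, AbundanceCurve)
                     else reference, dtype=float)
    pred = np.asarray(predicted.values if isinstance(predicted, AbundanceCurve)
                      else predicted, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1 or ref.size < 2:
        raise ValidationError("curves must be equal-length 1-D arrays of size >= 2")
    resid = ref - pred
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    rmse = float(np.sqrt(np.mean(resid**2)))
    auc_ref = float(np.trapezoid(ref))
    if auc_ref == 0.0:
        raise ValidationError("reference curve is identically zero; RelAUC undefined")
    rel_auc = (auc_ref - float(np.trapezoid(pred))) / auc_ref
    nrmse = rmse / float(ref.mean())
    if ss_tot == 0.0:
        return GlobalFit(np.nan, nrmse, rel_auc, np.nan, undefined=True)
    r2_plus = max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    sd_pred = pred.std()
    if sd_pred == 0.0:
        r = np.nan
        undefined = True
    else:
        r = float(np.corrcoef(ref, pred)[0, 1])
        undefined = False
    return GlobalFit(r2_plus, nrmse, rel_auc, r, undefined)


def pooled_r2_plus(reference: np.ndarray, predicted: np.ndarray) -> float:
    """Nonnegative R^2 over a pooled output vector (whole-subset skill)."""
    ref = np.asarray(reference, float)
    pred = np.asarray(predicted, float)
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("constant reference")
    return max(0.0, 1.0 - float(np.sum((ref - pred) ** 2)) / ss_tot)


# ---------------------------------------------------------------------------
# Season intervals and deltas
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SeasonIntervals:
    """Stable above-threshold intervals, closed and 0-based within the year."""

    threshold: float
    intervals: tuple[tuple[int, int], ...]
    not_reached: bool

    def __post_init__(self):
        last = -1
        for i, j in self.intervals:
            if i > j or i <= last:
                raise ValidationError("intervals must be sorted and disjoint")
            last = j
        if self.not_reached != (len(self.intervals) == 0):
            raise ValidationError("not_reached must mirror emptiness")


def extract_intervals(curve: np.ndarray | AbundanceCurve, threshold: float,
                      min_dwell: int = MIN_DWELL, max_gap: int = MAX_GAP) -> SeasonIntervals:
    """Maximal runs of days with value >= threshold, merged across gaps
    shorter than ``max_gap`` days; merged runs shorter than ``min_dwell``
    days are discarded."""
    values = np.asarray(curve.values if isinstance(curve, AbundanceCurve) else curve,
                        dtype=float)
    above = values >= threshold
    runs: list[list[int]] = []
    start = None
    for t, flag in enumerate(above):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            runs.append([start, t - 1])
            start = None
    if start is not None:
        runs.append([start, len(values) - 1])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < max_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kept = tuple((i, j) for i, j in merged if j - i + 1 >= min_dwell)
    return SeasonIntervals(float(threshold), kept, not_reached=not kept)


def season_length(intervals: SeasonIntervals) -> float:
    """l_S = max(offset) - min(onset) over the (20%-threshold) intervals."""
    if intervals.not_reached:
        return 0.0
    return float(intervals.intervals[-1][1] - intervals.intervals[0][0])


@dataclasses.dataclass(frozen=True)
class SeasonDeltas:
    d_on: tuple[float, ...]
    d_off: tuple[float, ...]
    unmatched_reference: int
    unmatched_prediction: int


def _match_intervals(ref: Sequence[tuple[int, int]],
                     pred: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of predicted to reference intervals by
    nearest onset, closest pairs first; ties go to the earlier reference
    interval. Closest-first ordering prevents an early predicted interval
    from claiming a distant reference while a nearer prediction goes
    unmatched."""
    candidates = sorted(
        (abs(p[0] - r[0]), m, n)
        for m, r in enumerate(ref) for n, p in enumerate(pred))
    ref_taken: set[int] = set()
    pred_taken: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, m, n in candidates:
        if m not in ref_taken and n not in pred_taken:
            ref_taken.add(m)
            pred_taken.add(n)
            pairs.append((m, n))
    return sorted(pairs)


def season_deltas(ref: SeasonIntervals, pred: SeasonIntervals,
                  mean_season_length: float) -> SeasonDeltas:
    """Scaled onset/offset differences for matched interval pairs."""
    if mean_season_length <= 0:
        raise DegenerateSeasonError("mean season length must be positive")
    pairs = _match_intervals(ref.intervals, pred.intervals)
    d_on = tuple((pred.intervals[n][0] - ref.intervals[m][0]) / mean_season_length
                 for m, n in pairs)
    d_off = tuple((pred.intervals[n][1] - ref.intervals[m][1]) / mean_season_length
                  for m, n in pairs)
    return SeasonDeltas(d_on, d_off,
                        unmatched_reference=len(ref.intervals) - len(pairs),
                        unmatched_prediction=len(pred.intervals) - len(pairs))


# ---------------------------------------------------------------------------
# Report and composite score
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetricReport:
    """Tidy per-location-year metric tables for one or more models."""

    global_rows: pd.DataFrame   # model, location, year, r2_plus, nrmse, rel_auc, r, undefined
    season_rows: pd.DataFrame   # model, location, year, threshold, d_on, d_off (matched pairs)
    event_rows: pd.DataFrame    # model, location, year, threshold, unmatched_*, not_reached

    def models(self) -> list[str]:
        return sorted(self.global_rows["model"].unique())

    def aggregates(self, model: str) -> dict:
        g = self.global_rows.query("model == @model and ~undefined")
        if g.empty:
            raise ValidationError(f"no defined global-fit rows for {model}")
        agg = {
            "mean_r2_plus": g["r2_plus"].mean(),
            "mean_nrmse": g["nrmse"].mean(),
            "mean_abs_rel_auc": g["rel_auc"].abs().mean(),
            "mean_r": g["r"].mean(),
        }
        s = self.season_rows.query("model == @model")
        e = self.event_rows.query("model == @model")
        for t in sorted(e["threshold"].unique()) if not e.empty else []:
            st = s[s["threshold"] == t]
            agg[f"mean_d_on_{int(t)}"] = st["d_on"].mean() if not st.empty else 0.0
            agg[f"sd_d_on_{int(t)}"] = st["d_on"].std(ddof=0) if not st.empty else 0.0
            agg[f"mean_d_off_{int(t)}"] = st["d_off"].mean() if not st.empty else 0.0
            agg[f"sd_d_off_{int(t)}"] = st["d_off"].std(ddof=0) if not st.empty else 0.0
        agg["frac_not_reached"] = float(e["not_reached"].mean()) if not e.empty else 0.0
        return agg


def composite_score(report: MetricReport, model: str,
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                    not_reached_weight: float = NOT_REACHED_WEIGHT) -> float:
    """Composite score S; zero for perfect predictions, lower is better.

    S = (1 - mean R+^2) + mean NRMSE + mean |RelAUC| + (1 - mean r)
        + (1/8) * sum_T (|mean D_on,T| + sd(D_on,T) + |mean D_off,T| + sd(D_off,T))
        + lambda * fraction of (location-year, threshold) cases the
          prediction never reached.
    """
    if report.global_rows.empty:
        raise ValidationError("empty report")
    agg = report.aggregates(model)
    s = (1.0 - agg["mean_r2_plus"]) + agg["mean_nrmse"] + agg["mean_abs_rel_auc"] \
        + (1.0 - agg["mean_r"])
    season_term = 0.0
    for t in thresholds:
        season_term += abs(agg.get(f"mean_d_on_{int(t)}", 0.0)) \
            + agg.get(f"sd_d_on_{int(t)}", 0.0) \
            + abs(agg.get(f"mean_d_off_{int(t)}", 0.0)) \
            + agg.get(f"sd_d_off_{int(t)}", 0.0)
    s += season_term / (2.0 * len(thresholds))
    s += not_reached_weight * agg["frac_not_reached"]
    return float(s)


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------

def _year_pairs(reference: AbundanceCurve, predicted: AbundanceCurve,
                years: Sequence[int] | None):
    """Align the two curves on common dates and slice them per calendar year."""
    common = reference.dates.intersection(predicted.dates)
    if len(common) == 0:
        raise ValidationError("curves share no dates")
    ref_vals = reference.value_on(common)
    pred_vals = predicted.value_on(common)
    yr = common.year.to_numpy()
    use_years = sorted(set(yr)) if years is None else list(years)
    for year in use_years:
        mask = yr == year
        if mask.sum() >= 2:
            yield year, ref_vals[mask], pred_vals[mask]


def evaluate_curves(reference: Mapping[str, AbundanceCurve],
                    predicted: Mapping[str, Mapping[str, AbundanceCurve]],
                    years: Sequence[int] | None = None,
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                    min_dwell: int = MIN_DWELL, max_gap: int = MAX_GAP) -> MetricReport:
    """Score predicted curves against references per model and location-year.

    ``predicted`` maps model name -> location -> smoothed curve; ``reference``
    maps location -> curve. Thresholds are percentages of the reference peak
    within each location-year; onset/offset deltas are scaled by the mean
    20%-threshold season length over the evaluated years at that location.
    """
    g_rows, s_rows, e_rows = [], [], []
    for model_name, curves in predicted.items():
        for loc, pred_curve in curves.items():
            ref_curve = reference[loc]
            pairs = list(_year_pairs(ref_curve, pred_curve, years))
            if not pairs:
                continue
            lengths = []
            for _, ref_vals, _ in pairs:
                t20 = 0.2 * ref_vals.max()
                lengths.append(season_length(
                    extract_intervals(ref_vals, t20, min_dwell, max_gap)))
            mean_ls = float(np.mean([l for l in lengths if l > 0])) \
                if any(l > 0 for l in lengths) else 0.0
            for year, ref_vals, pred_vals in pairs:
                fit = global_fit(ref_vals, pred_vals)
                g_rows.append({"model": model_name, "location": loc, "year": year,
                               "r2_plus": fit.r2_plus, "nrmse": fit.nrmse,
                               "rel_auc": fit.rel_auc, "r": fit.r,
                               "undefined": fit.undefined})
                peak = ref_vals.max()
                if peak <= 0 or mean_ls <= 0:
                    continue
                for t in thresholds:
                    thr = t / 100.0 * peak
                    ref_iv = extract_intervals(ref_vals, thr, min_dwell, max_gap)
                    pred_iv = extract_intervals(pred_vals, thr, min_dwell, max_gap)
                    if ref_iv.not_reached:
                        continue  # threshold not defined for this year
                    deltas = season_deltas(ref_iv, pred_iv, mean_ls)
                    for d_on, d_off in zip(deltas.d_on, deltas.d_off):
                        s_rows.append({"model": model_name, "location": loc,
                                       "year": year, "threshold": float(t),
                                       "d_on": d_on, "d_off": d_off})
                    e_rows.append({"model": model_name, "location": loc, "year": year,
                                   "threshold": float(t),
                                   "unmatched_reference": deltas.unmatched_reference,
                                   "unmatched_prediction": deltas.unmatched_prediction,
                                   "not_reached": pred_iv.not_reached})
    cols_s = ["model", "location", "year", "threshold", "d_on", "d_off"]
    cols_e = ["model", "location", "year", "threshold", "unmatched_reference",
              "unmatched_prediction", "not_reached"]
    return MetricReport(pd.DataFrame(g_rows),
                        pd.DataFrame(s_rows, columns=cols_s),
                        pd.DataFrame(e_rows, columns=cols_e))


def evaluate(models: Mapping[str, Model], benchmark, scaler: ScalerParams,
             delta: int = 90, years: Sequence[int] | None = None,
             thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> tuple[MetricReport, pd.DataFrame]:
    """Predict, smooth, and score all models on the benchmark's test locations.

    ``years`` defaults to all test-location years after the first (the first
    year lacks prior-year warm-up weather for a full curve). Returns the
    report and a ranking table ordered by composite score ascending.
    """
    split = benchmark.split
    if years is None:
        first = min(benchmark.weather[split.test_locations[0]].dates.year)
        last = max(benchmark.weather[split.test_locations[0]].dates.year)
        years = list(range(first + 1, last + 1))
    predicted: dict[str, dict[str, AbundanceCurve]] = {}
    for name, model in models.items():
        predicted[name] = {}
        for loc in split.test_locations:
            raw = predict_curve(model, benchmark.weather[loc], scaler, delta=delta)
            predicted[name][loc] = smooth_curve(raw)
    reference = {loc: benchmark.abundance[loc] for loc in split.test_locations}
    report = evaluate_curves(reference, predicted, years=years, thresholds=thresholds)
    rows = []
    for name in report.models():
        agg = report.aggregates(name)
        rows.append({"model": name, "S": composite_score(report, name, thresholds),
                     **{k: agg[k] for k in ("mean_r2_plus", "mean_nrmse",
                                            "mean_abs_rel_auc", "mean_r",
                                            "frac_not_reached")}})
    ranking = pd.DataFrame(rows).sort_values("S").reset_index(drop=True)
    ranking.index = ranking.index + 1
    ranking.index.name = "rank"
    return report, ranking
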