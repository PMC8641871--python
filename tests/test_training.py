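"""Subset assembly, augmentation flagging, and the optimization loop."""
import numpy as np
import pandas as pd
import pytest

from gravidnet import (
    AbundanceCurve,
    ArchitectureSpec,
    DivergenceError,
    PlanError,
    TrainingConfig,
    ValidationError,
    build_model,
    build_training_subset,
    early_stopping_schedule,
    flag_augmentation_locations,
    train,
)
from gravidnet.training import AugmentationPlan
from gravidnet.weather import WindowSet

from conftest import random_weather


def synthetic_curve(shape: str, years=(2015, 2016), location_id="syn") -> AbundanceCurve:
    """Hand-built annual curves: single peak, double peak, or tropical
    (never far below peak)."""
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(float)
    if shape == "single":
        vals = np.exp(-0.5 * ((doy - 200) / 40.0) ** 2)
    elif shape == "double":
        vals = (np.exp(-0.5 * ((doy - 140) / 25.0) ** 2)
                + np.exp(-0.5 * ((doy - 260) / 25.0) ** 2))
    elif shape == "tropical":
        vals = 0.7 + 0.3 * np.cos(2 * np.pi * (doy - 196) / 365)
    else:
        raise ValueError(shape)
    return AbundanceCurve(location_id, dates, vals)


class TestEarlyStoppingRule:
    def test_scripted_sequence_hand_trace(self):
        """Losses [5,4,3,3.1,3.2,3.05] with patience 2: the running minimum
        is at epoch 3, two non-improving epochs follow, stop at epoch 5."""
        assert early_stopping_schedule([5, 4, 3, 3.1, 3.2, 3.05], patience=2) == (5, 3)

    def test_patience_at_least_length_runs_everything(self):
        losses = [5, 4, 3, 3.1, 3.2, 3.05]
        stop, best = early_stopping_schedule(losses, patience=10)
        assert stop == 6 and best == 3

    def test_strictly_decreasing_never_stops(self):
        losses = [5, 4, 3, 2, 1]
        assert early_stopping_schedule(losses, patience=2) == (5, 5)

    def test_plateau_is_not_improvement(self):
        assert early_stopping_schedule([3, 3, 3, 3], patience=2) == (3, 1)


class TestTrainLoop:
    def _sets(self, rng, n=96, delta=6):
        x = rng.standard_normal((n, delta, 4))
        y = np.abs(x[:, -1, 0]) + 0.1
        dates = pd.date_range("2015-01-01", periods=n)
        ws = WindowSet(x, y, np.array(["a"] * n, dtype=object), dates)
        return ws[: n // 2], ws[n // 2:]

    def test_restored_weights_achieve_min_recorded_val_loss(self, rng):
        train_set, val_set = self._sets(rng)
        spec = ArchitectureSpec(variant="FF", delta=6, conv_filters=4, units=4)
        model = build_model(spec, seed=0)
        config = TrainingConfig(learning_rate=0.005, max_epochs=25, patience=5,
                                samples_per_location=10, seed=0)
        history = train(model, train_set, val_set, config)
        assert history.best_epoch == int(history.epochs["val_loss"].idxmin()) + 1
        refit = float(np.mean((model.predict(val_set.x) - val_set.y) ** 2))
        assert refit == pytest.approx(history.best_val_loss, rel=1e-9)

    def test_beats_mean_predictor_on_training_data(self, rng):
        train_set, val_set = self._sets(rng, n=160)
        spec = ArchitectureSpec(variant="FF", delta=6, conv_filters=8, units=16)
        model = build_model(spec, seed=1)
        config = TrainingConfig(learning_rate=0.01, max_epochs=100, patience=99,
                                samples_per_location=10, seed=0)
        train(model, train_set, val_set, config)
        mse = float(np.mean((model.predict(train_set.x) - train_set.y) ** 2))
        assert mse < np.var(train_set.y)

    def test_divergent_loss_raises_with_epoch(self, rng):
        train_set, val_set = self._sets(rng)
        from gravidnet import build_baseline

        model = build_baseline(6, seed=0)
        # corrupt the weights so the first forward pass yields a NaN loss
        weights = model.get_weights()
        weights[0][:] = np.nan
        model.set_weights(weights)
        config = TrainingConfig(max_epochs=5, patience=2,
                                samples_per_location=10, seed=0)
        with pytest.raises(DivergenceError) as err:
            train(model, train_set, val_set, config)
        assert err.value.epoch == 1

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            TrainingConfig(patience=100, max_epochs=100)
        with pytest.raises(ValidationError):
            TrainingConfig(learning_rate=0.0)


class TestAugmentationFlagging:
    def test_double_peak_flagged_hi(self):
        curves = {"dp": synthetic_curve("double", location_id="dp"),
                  "sp": synthetic_curve("single", location_id="sp")}
        plan = flag_augmentation_locations(curves, years=(2015, 2016))
        assert "dp" in plan.hi_locations
        assert "sp" not in plan.hi_locations

    def test_tropical_not_flagged_lo(self):
        curves = {"tr": synthetic_curve("tropical", location_id="tr"),
                  "sp": synthetic_curve("single", location_id="sp")}
        plan = flag_augmentation_locations(curves, years=(2015, 2016))
        assert "tr" not in plan.lo_locations
        assert "sp" in plan.lo_locations  # Gaussian summer peak: long low winter

    def test_override_always_wins(self):
        curves = {"tr": synthetic_curve("tropical", location_id="tr")}
        plan = flag_augmentation_locations(curves, years=(2015, 2016),
                                           lo_override=["tr"])
        assert plan.lo_locations == ("tr",)

    def test_no_curves_is_error(self):
        with pytest.raises(ValidationError):
            flag_augmentation_locations({}, years=(2015,))

    def test_benchmark_hot_dry_locations_flagged(self, small_benchmark):
        train_locs = small_benchmark.split.train_locations
        plan = flag_augmentation_locations(
            {l: small_benchmark.abundance[l] for l in train_locs},
            small_benchmark.split.train_years)
        hot_dry = {l for l in train_locs if small_benchmark.regimes[l] == "hot_dry"}
        assert hot_dry & set(plan.hi_locations)
        cold = {l for l in train_locs if small_benchmark.regimes[l] == "cold_winter"}
        assert cold & set(plan.lo_locations)


class TestSubsetAssembly:
    def _windows_per_location(self, rng, simple_scaler, locs, n_days=500):
        from gravidnet import make_windows

        return {loc: make_windows(random_weather(rng, n_days, loc, start="2015-06-01"),
                                  simple_scaler, delta=90) for loc in locs}

    def _plan(self, locs, hi=(), lo=()):
        mask = np.zeros(367, dtype=bool)
        mask[120:280] = True  # on-season: late April to early October
        return AugmentationPlan(mode="BASE", hi_locations=tuple(hi),
                                lo_locations=tuple(lo),
                                on_season={l: mask for l in locs}, extra_samples=50)

    @pytest.mark.parametrize("mode,hi,lo,expected", [
        ("BASE", ("a", "b"), (), 5 * 50),
        ("HI", ("a", "b"), (), 5 * 50 + 2 * 50),
        ("HILO", ("a", "b"), ("c", "d", "e"), 5 * 50 + 2 * 50 + 3 * 50),
    ])
    def test_subset_counts(self, rng, simple_scaler, mode, hi, lo, expected):
        locs = list("abcde")
        per_loc = self._windows_per_location(rng, simple_scaler, locs)
        plan = self._plan(locs, hi, lo).with_mode(mode)
        config = TrainingConfig(samples_per_location=50, seed=0)
        subset = build_training_subset(per_loc, plan, config)
        assert len(subset) == expected

    def test_extra_samples_respect_season_mask(self, rng, simple_scaler):
        locs = ["a", "b"]
        per_loc = self._windows_per_location(rng, simple_scaler, locs)
        plan = self._plan(locs, hi=("a",)).with_mode("HI")
        config = TrainingConfig(samples_per_location=30, seed=1)
        subset = build_training_subset(per_loc, plan, config)
        base = build_training_subset(per_loc, plan.with_mode("BASE"), config)
        # the 50 extra windows all end inside the on-season day mask
        extra = len(subset) - len(base)
        assert extra == 50
        counts = pd.Series(subset.location_ids).value_counts()
        assert counts["a"] == 30 + 50

    def test_trivial_mask_rejected_at_plan_construction(self):
        with pytest.raises(PlanError):
            AugmentationPlan(mode="HI", hi_locations=("a",),
                             on_season={"a": np.zeros(367, dtype=bool)})

    def test_subset_determinism(self, rng, simple_scaler):
        locs = ["a", "b"]
        per_loc = self._windows_per_location(rng, simple_scaler, locs)
        plan = self._plan(locs, hi=("a",)).with_mode("HI")
        config = TrainingConfig(samples_per_location=20, seed=3)
        s1 = build_training_subset(per_loc, plan, config)
        s2 = build_training_subset(per_loc, plan, config)
        assert (s1.t0 == s2.t0).all() and (s1.location_ids == s2.location_ids).all()
        np.testing.assert_array_equal(s1.x, s2.x)
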