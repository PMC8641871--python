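"""Training-subset assembly, augmentation, and the MSE/Adam optimization loop.

Training minimizes the mean squared error between network output and the
teacher abundance on the window's final day, using Adam at a fixed learning
rate of 1e-4 with batch size 64, up to 100 epochs with early stopping at
patience 15, restoring the weights of the best validation epoch.

Two oversampling schemes enrich the base subset (1000 windows per training
location): HI adds on-season windows from locations with a heat-suppressed
double-peak season, LO adds off-season windows from locations with a long
cold off-season. Combined with the three architectures this yields the
twelve-model variant matrix {FF, LSTM, GRU} x {BASE, HI, LO, HILO}.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DivergenceError, PlanError, ValidationError
from .networks import ArchitectureSpec, Model, build_baseline, build_model
from .synthetic import Benchmark
from .weather import (
    AbundanceCurve,
    WindowSet,
    fit_scaler,
    make_windows,
    sample_training_windows,
)

logger = logging.getLogger(__name__)

AUGMENT_MODES = ("BASE", "HI", "LO", "HILO")
VARIANTS = ("FF", "LSTM", "GRU")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 15
    samples_per_location: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValidationError("Adam decay rates must lie in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValidationError("patience must be smaller than max_epochs")


@dataclasses.dataclass(frozen=True)
class AugmentationPlan:
    """Which locations receive extra on-season (HI) / off-season (LO) samples.

    ``on_season`` maps a location to a boolean day-of-year mask (index 1..366)
    marking its season; off-season is the complement.
    """

    mode: str = "BASE"
    hi_locations: tuple[str, ...] = ()
    lo_locations: tuple[str, ...] = ()
    on_season: Mapping[str, np.ndarray] = dataclasses.field(default_factory=dict)
    extra_samples: int = 1000

    def __post_init__(self):
        if self.mode not in AUGMENT_MODES:
            raise ValidationError(f"unknown augmentation mode {self.mode!r}")
        flagged = set(self.hi_locations) | set(self.lo_locations)
        for loc in flagged:
            mask = self.on_season.get(loc)
            if mask is None or not np.asarray(mask).any() or np.asarray(mask).all():
                raise PlanError(f"location {loc} needs a non-trivial season mask")

    def with_mode(self, mode: str) -> "AugmentationPlan":
        return dataclasses.replace(self, mode=mode)


# ---------------------------------------------------------------------------
# Augmentation-location flagging
# ---------------------------------------------------------------------------

def _mean_annual_curve(curve: AbundanceCurve, years: Iterable[int]) -> np.ndarray:
    """Day-of-year mean over the given years (365 entries; leap day merged)."""
    years = set(years)
    mask = np.isin(curve.dates.year, list(years))
    if not mask.any():
        raise ValidationError(f"{curve.location_id}: no data in the requested years")
    doy = np.minimum(curve.dates.dayofyear[mask], 365)
    return pd.Series(curve.values[mask]).groupby(doy).mean().reindex(
        range(1, 366)).interpolate(limit_direction="both").to_numpy()


def _has_double_peak(annual: np.ndarray, peak_frac: float = 0.4,
                     trough_frac: float = 0.6) -> bool:
    """Two local maxima above ``peak_frac`` of peak separated by a trough
    below ``trough_frac`` of peak."""
    from scipy.signal import find_peaks

    peak = annual.max()
    if peak <= 0:
        return False
    idx, _ = find_peaks(annual, height=peak_frac * peak, distance=14)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if annual[idx[a]:idx[b] + 1].min() < trough_frac * peak:
                return True
    return False


def _has_cold_off_season(annual: np.ndarray, frac: float = 0.2,
                         min_days: int = 60) -> bool:
    """At least ``min_days`` consecutive days below ``frac`` of peak,
    allowing the run to wrap around the year boundary."""
    peak = annual.max()
    if peak <= 0:
        return False
    low = np.concatenate([annual, annual]) < frac * peak
    run = best = 0
    for flag in low:
        run = run + 1 if flag else 0
        best = max(best, run)
    return min(best, len(annual)) >= min_days


def _season_mask(annual: np.ndarray, frac: float = 0.2) -> np.ndarray:
    """Boolean day-of-year mask (length 367, 1-based) of the on-season,
    defined by the stable 20%-of-peak threshold intervals."""
    from .evaluation import extract_intervals

    intervals = extract_intervals(annual, frac * annual.max())
    mask = np.zeros(367, dtype=bool)
    for i, j in intervals.intervals:
        mask[i + 1:j + 2] = True  # interval indices are 0-based days of year
    mask[366] = mask[365]  # leap day follows day 365
    return mask


def flag_augmentation_locations(curves: Mapping[str, AbundanceCurve],
                                years: Iterable[int],
                                hi_override: Iterable[str] | None = None,
                                lo_override: Iterable[str] | None = None,
                                extra_samples: int = 1000) -> AugmentationPlan:
    """Automatically flag HI (double-peak) and LO (cold off-season) locations.

    Explicit override lists always win over the heuristic.
    """
    if not curves:
        raise ValidationError("no training curves given")
    years = tuple(years)
    hi, lo, masks = [], [], {}
    for loc in sorted(curves):
        annual = _mean_annual_curve(curves[loc], years)
        masks[loc] = _season_mask(annual)
        if _has_double_peak(annual):
            hi.append(loc)
        if _has_cold_off_season(annual):
            lo.append(loc)
    if hi_override is not None:
        hi = sorted(hi_override)
    if lo_override is not None:
        lo = sorted(lo_override)
    for loc in set(hi) | set(lo):
        if loc not in masks:
            raise PlanError(f"override location {loc} has no training curve")
    return AugmentationPlan(mode="BASE", hi_locations=tuple(hi), lo_locations=tuple(lo),
                            on_season=masks, extra_samples=extra_samples)


# ---------------------------------------------------------------------------
# Subset assembly
# ---------------------------------------------------------------------------

def _masked_sample(ws: WindowSet, mask: np.ndarray, n: int,
                   rng: np.random.Generator, loc: str, season: str) -> WindowSet:
    doy = ws.t0.dayofyear.to_numpy()
    keep = mask[doy] if season == "on" else ~mask[doy]
    idx = np.where(keep)[0]
    if idx.size == 0:
        raise PlanError(f"location {loc} has no {season}-season windows")
    if idx.size < n:
        logger.warning("location %s: only %d %s-season windows (< %d)",
                       loc, idx.size, season, n)
        chosen = rng.permutation(idx)
    else:
        chosen = rng.choice(idx, size=n, replace=False)
    return ws[chosen]


def build_training_subset(windows_per_location: Mapping[str, WindowSet],
                          plan: AugmentationPlan, config: TrainingConfig,
                          seed: int | None = None) -> WindowSet:
    """Assemble the BASE/HI/LO/HILO training subset and shuffle it globally."""
    seed = config.seed if seed is None else seed
    base = sample_training_windows(dict(windows_per_location),
                                   config.samples_per_location, rng_seed=seed)
    parts = [base]
    rng = np.random.default_rng(seed + 1)
    if plan.mode in ("HI", "HILO"):
        for loc in plan.hi_locations:
            if loc not in windows_per_location:
                raise PlanError(f"HI location {loc} not in training windows")
            parts.append(_masked_sample(windows_per_location[loc],
                                        np.asarray(plan.on_season[loc]),
                                        plan.extra_samples, rng, loc, "on"))
    if plan.mode in ("LO", "HILO"):
        for loc in plan.lo_locations:
            if loc not in windows_per_location:
                raise PlanError(f"LO location {loc} not in training windows")
            parts.append(_masked_sample(windows_per_location[loc],
                                        np.asarray(plan.on_season[loc]),
                                        plan.extra_samples, rng, loc, "off"))
    combined = WindowSet.concatenate(parts)
    order = np.random.default_rng(seed + 2).permutation(len(combined))
    return combined[order]


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float, beta2: float,
                 eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class EarlyStopping:
    """Stop after ``patience`` epochs without strict validation improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.wait = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch (1-based); returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def early_stopping_schedule(val_losses: Iterable[float], patience: int) -> tuple[int, int]:
    """Pure trace of the stopping rule over a scripted validation-loss
    sequence; returns (stop_epoch, best_epoch), both 1-based."""
    stopper = EarlyStopping(patience)
    epoch = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if stopper.update(epoch, loss):
            break
    return epoch, stopper.best_epoch


@dataclasses.dataclass
class TrainingHistory:
    epochs: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int
    stopped_epoch: int

    @property
    def best_val_loss(self) -> float:
        return float(self.epochs["val_loss"].min())


def _mse(model: Model, x: np.ndarray, y: np.ndarray, batch_size: int = 512) -> float:
    pred = model.predict(x, batch_size=batch_size)
    return float(np.mean((pred - y) ** 2))


def train(model: Model, train_set: WindowSet, val_set: WindowSet,
          config: TrainingConfig = TrainingConfig()) -> TrainingHistory:
    """Fit the model in place; returns the per-epoch loss history.

    The loss is the plain MSE; the l2 penalty on the output weights enters
    through the gradients. Early stopping restores the weights (and batch
    normalization statistics) of the best validation epoch.
    """
    if train_set.y is None or val_set.y is None:
        raise ValidationError("training and validation sets need targets")
    x, y = train_set.x, train_set.y
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params(), config.learning_rate, config.beta1, config.beta2)
    stopper = EarlyStopping(config.patience)
    best_weights = model.get_weights()
    best_state = model.get_state()
    rows = []
    stopped = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model.forward(x[idx], training=True)
            resid = pred - y[idx]
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            batch_losses.append(loss)
            model.backward(2.0 * resid / len(idx))
            optimizer.step(model.grads())
        val_loss = _mse(model, val_set.x, val_set.y)
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)
        train_loss = float(np.mean(batch_losses))
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("epoch %d: train MSE %.6g, val MSE %.6g", epoch, train_loss, val_loss)
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_weights = model.get_weights()
            best_state = model.get_state()
        stopped = epoch
        if stop:
            break
    model.set_weights(best_weights)
    model.set_state(best_state)
    return TrainingHistory(pd.DataFrame(rows), stopper.best_epoch, stopped)


# ---------------------------------------------------------------------------
# High-level assembly over a benchmark
# ---------------------------------------------------------------------------

def benchmark_windows(benchmark: Benchmark, delta: int = 90):
    """Fit the scaler on the training period and cut per-location windows.

    Returns (scaler, train_windows, val_windows): dicts of WindowSets keyed
    by training location, restricted to training / validation years by the
    window's final day.
    """
    split = benchmark.split
    train_series = [benchmark.weather[l] for l in split.train_locations]
    scaler = fit_scaler(train_series)
    train_w: dict[str, WindowSet] = {}
    val_w: dict[str, WindowSet] = {}
    for loc in split.train_locations:
        ws = make_windows(benchmark.weather[loc], scaler,
                          targets=benchmark.abundance[loc], delta=delta)
        years = ws.t0.year.to_numpy()
        train_w[loc] = ws[np.isin(years, split.train_years)]
        val_w[loc] = ws[np.isin(years, split.validation_years)]
    return scaler, train_w, val_w


def _flatten_validation(val_w: Mapping[str, WindowSet], max_per_location: int,
                        seed: int) -> WindowSet:
    return sample_training_windows(dict(val_w), max_per_location, rng_seed=seed)


@dataclasses.dataclass
class TrainedModel:
    name: str
    model: Model
    spec: ArchitectureSpec
    history: TrainingHistory
    augment: str


def train_variant_matrix(benchmark: Benchmark, config: TrainingConfig = TrainingConfig(),
                         delta: int = 90, l2: float = 0.01,
                         variants: Iterable[str] = VARIANTS,
                         modes: Iterable[str] = AUGMENT_MODES,
                         include_baseline: bool = True,
                         hi_override: Iterable[str] | None = None,
                         lo_override: Iterable[str] | None = None,
                         val_samples_per_location: int | None = None):
    """Train the {FF, LSTM, GRU} x {BASE, HI, LO, HILO} matrix (plus the LR
    baseline on the base subset). Returns (scaler, dict name -> TrainedModel)."""
    scaler, train_w, val_w = benchmark_windows(benchmark, delta=delta)
    plan = flag_augmentation_locations(
        {l: benchmark.abundance[l] for l in benchmark.split.train_locations},
        benchmark.split.train_years, hi_override=hi_override, lo_override=lo_override,
        extra_samples=config.samples_per_location)
    val_set = _flatten_validation(
        val_w, val_samples_per_location or config.samples_per_location,
        config.seed + 7)

    subsets = {mode: build_training_subset(train_w, plan.with_mode(mode), config)
               for mode in modes}
    trained: dict[str, TrainedModel] = {}
    for variant in variants:
        for mode in modes:
            name = variant if mode == "BASE" else f"{variant} {mode}"
            spec = ArchitectureSpec(variant=variant, delta=delta, l2=l2)
            model = build_model(spec, seed=config.seed)
            logger.info("training %s (%d samples)", name, len(subsets[mode]))
            history = train(model, subsets[mode], val_set, config)
            trained[name] = TrainedModel(name, model, spec, history, mode)
    if include_baseline:
        spec = ArchitectureSpec(variant="LR", delta=delta)
        model = build_baseline(delta, seed=config.seed)
        history = train(model, subsets.get("BASE", next(iter(subsets.values()))),
                        val_set, config)
        trained["Baseline"] = TrainedModel("Baseline", model, spec, history, "BASE")
    return scaler, trained
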