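"""Weather and abundance series, CSV I/O, min-max scaling, and sliding windows.

A model input sample is a block of ``delta`` consecutive days of four weather
variables ending on the prediction day ``t0``; its target is the abundance on
``t0``. Weather is scaled per variable with global training-set extrema that
are frozen with the model weights.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateScaleError,
    FormatError,
    InsufficientHistoryError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Fixed column order of the model input block. Frozen so that saved weights
#: remain portable across runs.
VARIABLES = ("precip", "tmax", "tmin", "rh")

WEATHER_COLUMNS = ("date", "tmax", "tmin", "precip", "rh")
ABUNDANCE_COLUMNS = ("date", "abundance")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class WeatherSeries:
    """Daily weather record for one location: tmax/tmin in degrees Celsius,
    precipitation in mm/day, relative humidity in percent."""

    location_id: str
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    tmin: np.ndarray
    precip: np.ndarray
    rh: np.ndarray

    def __post_init__(self):
        n = len(self.dates)
        for name in ("tmax", "tmin", "precip", "rh"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n,):
                raise ValidationError(f"{name} has length {arr.shape}, expected ({n},)")
            if np.isnan(arr).any():
                raise ValidationError(f"NaN values in {name} for {self.location_id}")
        if n == 0:
            raise ValidationError("empty series")
        if not isinstance(self.dates, pd.DatetimeIndex):
            object.__setattr__(self, "dates", pd.DatetimeIndex(self.dates))
        diffs = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if n > 1 and not (diffs == 1).all():
            raise ValidationError(f"dates of {self.location_id} are not consecutive days")
        if (self.precip < 0).any():
            raise ValidationError("negative precipitation")
        if ((self.rh < 0) | (self.rh > 100)).any():
            raise ValidationError("relative humidity outside [0, 100]")

    def __len__(self) -> int:
        return len(self.dates)

    def to_matrix(self) -> np.ndarray:
        """(n_days, 4) array in the fixed ``VARIABLES`` column order."""
        return np.column_stack([getattr(self, v) for v in VARIABLES])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "tmax": self.tmax,
                "tmin": self.tmin,
                "precip": self.precip,
                "rh": self.rh,
            }
        )


@dataclasses.dataclass(frozen=True)
class AbundanceCurve:
    """Daily abundance estimates (arbitrary scaled gravid-female units)."""

    location_id: str
    dates: pd.DatetimeIndex
    values: np.ndarray
    smoothed: bool = False

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not isinstance(self.dates, pd.DatetimeIndex):
            object.__setattr__(self, "dates", pd.DatetimeIndex(self.dates))
        if vals.shape != (len(self.dates),):
            raise ValidationError("values and dates have different lengths")
        if np.isnan(vals).any():
            raise ValidationError("NaN abundance values")
        if self.smoothed and (vals < -1e-12).any():
            raise ValidationError("smoothed curve must be nonnegative")

    def __len__(self) -> int:
        return len(self.dates)

    def value_on(self, dates: pd.DatetimeIndex) -> np.ndarray:
        """Values on the given dates; raises if any date is not covered."""
        idx = self.dates.get_indexer(pd.DatetimeIndex(dates))
        if (idx < 0).any():
            raise ValidationError(f"abundance for {self.location_id} does not cover all requested dates")
        return self.values[idx]

    def year_slice(self, year: int) -> "AbundanceCurve":
        mask = self.dates.year == year
        if not mask.any():
            raise ValidationError(f"no data for year {year}")
        return AbundanceCurve(self.location_id, self.dates[mask], self.values[mask], self.smoothed)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_weather_csv(path: str | Path, location_id: str | None = None) -> WeatherSeries:
    """Read a daily weather CSV with columns date,tmax,tmin,precip,rh."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="%Y-%m-%d"))
    return WeatherSeries(
        location_id=location_id or path.stem,
        dates=dates,
        tmax=df["tmax"].to_numpy(float),
        tmin=df["tmin"].to_numpy(float),
        precip=df["precip"].to_numpy(float),
        rh=df["rh"].to_numpy(float),
    )


def write_weather_csv(series: WeatherSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_abundance_csv(path: str | Path, location_id: str | None = None) -> AbundanceCurve:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(ABUNDANCE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="%Y-%m-%d"))
    curve = AbundanceCurve(
        location_id=location_id or path.stem,
        dates=dates,
        values=df["abundance"].to_numpy(float),
        smoothed=True,
    )
    return curve


def write_abundance_csv(curve: AbundanceCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"date": curve.dates.strftime("%Y-%m-%d"), "abundance": curve.values}
    ).to_csv(path, index=False, float_format="%.8f")


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ScalerParams:
    """Global per-variable min/max over the whole training subset.

    The extrema are model parameters: they are frozen after fitting and must
    be applied unchanged to validation, test and future data. Scaled values
    for unseen extremes may fall outside [0, 1]; no clipping is applied.
    """

    minimum: np.ndarray  # (4,) in VARIABLES order
    maximum: np.ndarray  # (4,)

    def __post_init__(self):
        mn = np.asarray(self.minimum, dtype=float)
        mx = np.asarray(self.maximum, dtype=float)
        object.__setattr__(self, "minimum", mn)
        object.__setattr__(self, "maximum", mx)
        if mn.shape != (4,) or mx.shape != (4,):
            raise ValidationError("scaler extrema must have shape (4,)")
        if not (mx > mn).all():
            bad = [VARIABLES[i] for i in np.where(mx <= mn)[0]]
            raise DegenerateScaleError(f"constant variable(s) over training subset: {bad}")

    def transform(self, block: np.ndarray) -> np.ndarray:
        """Map (..., 4) raw weather to (v - min) / (max - min), unclipped."""
        return (np.asarray(block, dtype=float) - self.minimum) / (self.maximum - self.minimum)

    def inverse_transform(self, block: np.ndarray) -> np.ndarray:
        return np.asarray(block, dtype=float) * (self.maximum - self.minimum) + self.minimum

    def to_dict(self) -> dict:
        return {
            "variables": list(VARIABLES),
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        if tuple(d.get("variables", ())) != VARIABLES:
            raise FormatError("scaler sidecar has unexpected variable order")
        return cls(np.asarray(d["minimum"]), np.asarray(d["maximum"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScalerParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_scaler(training_series: Iterable[WeatherSeries]) -> ScalerParams:
    """Per-variable global extrema over all days of all training locations."""
    series = list(training_series)
    if not series:
        raise ValidationError("fit_scaler needs at least one series")
    stacked = np.vstack([s.to_matrix() for s in series])
    return ScalerParams(stacked.min(axis=0), stacked.max(axis=0))


def scale(series: WeatherSeries, params: ScalerParams) -> np.ndarray:
    """Scaled (n_days, 4) block for one series, in VARIABLES order."""
    return params.transform(series.to_matrix())


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class WindowSample:
    """One training/prediction sample: scaled weather block and its target."""

    x: np.ndarray  # (delta, 4), rows are consecutive days ending at t0
    y: float | None
    location_id: str
    t0: pd.Timestamp


class WindowSet(Sequence):
    """Dense set of sliding-window samples for one or more locations.

    Stores the samples as contiguous arrays (``x`` of shape (n, delta, 4) and
    ``y`` of shape (n,)) while behaving as a sequence of ``WindowSample``.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray | None,
                 location_ids: np.ndarray, t0: pd.DatetimeIndex):
        self.x = np.asarray(x, dtype=float)
        self.y = None if y is None else np.asarray(y, dtype=float)
        self.location_ids = np.asarray(location_ids)
        self.t0 = pd.DatetimeIndex(t0)
        if self.x.ndim != 3:
            raise ValidationError("window block must be 3-D (n, delta, 4)")
        n = self.x.shape[0]
        if self.y is not None and self.y.shape != (n,):
            raise ValidationError("targets and windows have different lengths")
        if len(self.location_ids) != n or len(self.t0) != n:
            raise ValidationError("metadata and windows have different lengths")

    @property
    def delta(self) -> int:
        return self.x.shape[1]

    def __len__(self) -> int:
        return self.x.shape[0]

    def __getitem__(self, i):
        if isinstance(i, (slice, np.ndarray, list)):
            idx = np.arange(len(self))[i] if isinstance(i, slice) else np.asarray(i)
            return WindowSet(
                self.x[idx],
                None if self.y is None else self.y[idx],
                self.location_ids[idx],
                self.t0[idx],
            )
        return WindowSample(
            x=self.x[i],
            y=None if self.y is None else float(self.y[i]),
            location_id=str(self.location_ids[i]),
            t0=self.t0[i],
        )

    def __iter__(self) -> Iterator[WindowSample]:
        for i in range(len(self)):
            yield self[i]

    @staticmethod
    def concatenate(parts: Sequence["WindowSet"]) -> "WindowSet":
        if not parts:
            raise ValidationError("nothing to concatenate")
        ys = [p.y for p in parts]
        y = None if any(v is None for v in ys) else np.concatenate(ys)
        return WindowSet(
            np.concatenate([p.x for p in parts]),
            y,
            np.concatenate([p.location_ids for p in parts]),
            pd.DatetimeIndex(np.concatenate([p.t0.values for p in parts])),
        )


def make_windows(series: WeatherSeries, params: ScalerParams,
                 targets: AbundanceCurve | None = None, delta: int = 90) -> WindowSet:
    """Cut all sliding windows of length ``delta`` from a series.

    One sample per admissible final day t0 (count = len(series) - delta + 1);
    ``y`` is the abundance target on t0 when ``targets`` is given.
    """
    n = len(series)
    if n < delta:
        raise InsufficientHistoryError(
            f"{series.location_id}: series of length {n} is shorter than delta={delta}"
        )
    scaled = scale(series, params)
    # (n - delta + 1, delta, 4) view over consecutive days
    x = np.lib.stride_tricks.sliding_window_view(scaled, delta, axis=0)
    x = np.ascontiguousarray(np.moveaxis(x, 2, 1))
    t0 = series.dates[delta - 1:]
    y = None
    if targets is not None:
        y = targets.value_on(t0)
        if (y < 0).any():
            raise ValidationError("negative abundance target")
    loc = np.full(len(t0), series.location_id, dtype=object)
    return WindowSet(x, y, loc, t0)


def sample_training_windows(windows_per_location: dict[str, WindowSet],
                            n: int, rng_seed: int) -> WindowSet:
    """Draw ``n`` windows without replacement per location, then shuffle globally.

    Locations with fewer than ``n`` admissible windows contribute everything
    they have (with a logged warning).
    """
    if n <= 0:
        raise ValueError("sample count must be positive")
    rng = np.random.default_rng(rng_seed)
    parts = []
    # deterministic iteration order regardless of dict insertion order
    for loc in sorted(windows_per_location):
        ws = windows_per_location[loc]
        if len(ws) == 0:
            raise ValidationError(f"location {loc} has no admissible windows")
        if len(ws) < n:
            logger.warning("location %s has only %d < %d windows; using all", loc, len(ws), n)
            idx = rng.permutation(len(ws))
        else:
            idx = rng.choice(len(ws), size=n, replace=False)
        parts.append(ws[idx])
    combined = WindowSet.concatenate(parts)
    order = rng.permutation(len(combined))
    return combined[order]
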