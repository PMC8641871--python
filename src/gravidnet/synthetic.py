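"""Synthetic weather and a simplified mechanistic abundance surrogate.

The weather generator emulates the statistical structure of downscaled daily
climate products: seasonal sinusoids for temperature and relative humidity
with AR(1) noise (temperature autocorrelation time of about three weeks,
humidity about six days), and precipitation as a two-state wet/dry
persistence chain with gamma-distributed wet-day amounts and a seasonal
wet-day probability.

The abundance surrogate is deliberately *not* an agent-based life-cycle
simulation. It is a minimal delayed-recruitment model with logistic
saturation, chosen so that (a) abundance depends on weather over a
multi-week history, which is what the sliding-window premise of the
emulators requires, and (b) it is cheap, smooth, and deterministic:

    rho_t   = r_max * B(Tbar_t) * H_t / (H_t + H_half) * sigma(rh_t)
    H_{t+1} = (1 - habitat_decay) * H_t + habitat_gain * precip_t
    A_{t+1} = (1 - mortality) * A_t + max(0, rho_{t - delay} * (1 - A_t / K))

where B is a piecewise-quadratic thermal performance curve (zero outside the
critical limits, one at the optimum), sigma a relative-humidity survival
factor, and ``delay`` the immature maturation time. Under constant forcing
the recursion has the closed-form fixed point A* = rho K / (mortality K + rho).
The daily series is finished with two passes of a 15-day centered moving
average, matching the output convention of the mechanistic teacher model the
networks are meant to emulate. Abundance is expressed in units of the
carrying capacity, the natural normalization for output that is defined only
up to a location-specific multiplicative factor.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InsufficientHistoryError, ValidationError
from .weather import AbundanceCurve, WeatherSeries

_SUMMER_PEAK_DOY = 196  # mid-July, northern hemisphere


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ClimateParams:
    """Statistical description of one location's weather climate."""

    tmax_mean: float = 25.0          # annual-mean daily maximum temperature, degC
    tmax_amplitude: float = 10.0     # seasonal half-range of tmax, degC
    tmin_offset: float = 12.0        # mean diurnal gap tmax - tmin, degC
    tmin_amplitude: float = 9.0      # seasonal half-range of tmin, degC
    temp_autocorr_days: float = 21.0  # AR(1) autocorrelation time of temperature noise
    temp_noise_sd: float = 2.5       # stationary sd of temperature noise, degC
    rh_mean: float = 55.0            # annual-mean relative humidity, percent
    rh_amplitude: float = 10.0       # seasonal half-range of rh, percent
    rh_peak_doy: int = _SUMMER_PEAK_DOY  # day-of-year of the rh seasonal maximum
    rh_autocorr_days: float = 6.0    # AR(1) autocorrelation time of rh noise
    rh_noise_sd: float = 8.0         # stationary sd of rh noise, percent
    wet_prob_summer: float = 0.3     # wet-day probability at the summer peak
    wet_prob_winter: float = 0.2     # wet-day probability at mid-winter
    wet_persistence: float = 0.5     # lag-1 correlation of the wet/dry occurrence chain
    precip_shape: float = 0.7        # gamma shape of wet-day amounts
    precip_mean_mm: float = 6.0      # mean wet-day amount, mm
    seed: int = 0                    # bookkeeping seed used by benchmark generation

    def __post_init__(self):
        if min(self.tmax_amplitude, self.tmin_amplitude, self.rh_amplitude) < 0:
            raise ValidationError("seasonal amplitudes must be nonnegative")
        if min(self.temp_autocorr_days, self.rh_autocorr_days) <= 0:
            raise ValidationError("autocorrelation times must be positive")
        for p in (self.wet_prob_summer, self.wet_prob_winter):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("wet-day probabilities must lie in [0, 1]")
        if not 0.0 <= self.wet_persistence < 1.0:
            raise ValidationError("wet persistence must lie in [0, 1)")
        if self.precip_shape <= 0 or self.precip_mean_mm < 0:
            raise ValidationError("invalid wet-day amount distribution")


@dataclasses.dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the delayed-recruitment abundance surrogate."""

    t_opt: float = 29.0          # thermal optimum for recruitment, degC
    t_lo: float = 14.0           # lower critical temperature, degC
    t_hi: float = 36.0           # upper critical temperature, degC
    habitat_gain: float = 1.0    # habitat index gained per mm of rain
    habitat_decay: float = 0.05  # daily fractional decay of the habitat index
    habitat_half: float = 25.0   # habitat index at half saturation
    rh_slope: float = 0.6        # survival gain per 100 percentage points of rh
    maturation_delay: int = 12   # days from recruitment conditions to adults
    carrying_capacity: float = 1.0  # logistic saturation level (abundance unit)
    recruit_rate: float = 0.35   # maximum recruitment per day at the optimum
    mortality: float = 0.1       # daily adult mortality

    def __post_init__(self):
        if not self.t_lo < self.t_opt < self.t_hi:
            raise ValidationError("critical temperatures must satisfy t_lo < t_opt < t_hi")
        if not 0.0 < self.habitat_decay < 1.0:
            raise ValidationError("habitat decay must lie in (0, 1)")
        for name in ("habitat_gain", "habitat_half", "rh_slope", "carrying_capacity",
                     "recruit_rate", "mortality"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and nonnegative")
        if self.maturation_delay < 0:
            raise ValidationError("maturation delay must be nonnegative")

    def thermal_performance(self, temp: np.ndarray) -> np.ndarray:
        """Piecewise-quadratic performance: 1 at t_opt, 0 outside (t_lo, t_hi)."""
        temp = np.asarray(temp, dtype=float)
        below = 1.0 - ((temp - self.t_opt) / (self.t_opt - self.t_lo)) ** 2
        above = 1.0 - ((temp - self.t_opt) / (self.t_hi - self.t_opt)) ** 2
        out = np.where(temp <= self.t_opt, below, above)
        return np.clip(out, 0.0, None)

    def rh_survival(self, rh: np.ndarray) -> np.ndarray:
        """Relative-humidity survival factor, clipped to [0.1, 1]."""
        return np.clip(0.5 + self.rh_slope * (np.asarray(rh, float) - 50.0) / 100.0, 0.1, 1.0)

    def equilibrium(self, tmean: float, precip: float, rh: float) -> float:
        """Closed-form fixed point of the recursion under constant weather."""
        h_star = self.habitat_gain * precip / self.habitat_decay
        rho = (self.recruit_rate * float(self.thermal_performance(tmean))
               * h_star / (h_star + self.habitat_half) * float(self.rh_survival(rh)))
        k = self.carrying_capacity
        return rho * k / (self.mortality * k + rho) if rho > 0 else 0.0


# ---------------------------------------------------------------------------
# Weather generation
# ---------------------------------------------------------------------------

def _seasonal(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    """Unit-amplitude annual cycle, 1 at peak_doy; depends only on day-of-year."""
    return np.cos(2.0 * np.pi * (doy - peak_doy) / 365.0)


def _ar1(rng: np.random.Generator, n: int, autocorr_days: float, sd: float) -> np.ndarray:
    phi = np.exp(-1.0 / autocorr_days)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(n) * innov_sd
    out = np.empty(n)
    out[0] = rng.standard_normal() * sd
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def generate_weather(params: ClimateParams, n_days: int, seed: int,
                     location_id: str = "synthetic",
                     start: str = "2014-01-01") -> WeatherSeries:
    """Generate a daily weather series; deterministic under (params, seed)."""
    if n_days < 1:
        raise ValidationError("n_days must be at least 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    season = _seasonal(doy, _SUMMER_PEAK_DOY)

    temp_noise = _ar1(rng, n_days, params.temp_autocorr_days, params.temp_noise_sd)
    tmin_extra = 0.3 * _ar1(rng, n_days, params.temp_autocorr_days, params.temp_noise_sd)
    tmax = params.tmax_mean + params.tmax_amplitude * season + temp_noise
    tmin = (params.tmax_mean - params.tmin_offset
            + params.tmin_amplitude * season + temp_noise + tmin_extra)
    tmin = np.minimum(tmin, tmax - 0.5)  # physical ordering, strict

    rh_season = _seasonal(doy, params.rh_peak_doy)
    rh = params.rh_mean + params.rh_amplitude * rh_season
    rh = np.clip(rh + _ar1(rng, n_days, params.rh_autocorr_days, params.rh_noise_sd), 0.0, 100.0)

    # wet/dry occurrence chain with seasonal stationary probability
    weight = 0.5 * (1.0 + season)  # 1 at summer peak, 0 at mid-winter
    p_wet = np.clip(params.wet_prob_winter
                    + (params.wet_prob_summer - params.wet_prob_winter) * weight, 0.0, 1.0)
    rho_chain = params.wet_persistence
    wet = np.zeros(n_days, dtype=bool)
    u = rng.random(n_days)
    wet[0] = u[0] < p_wet[0]
    for t in range(1, n_days):
        p = p_wet[t] + rho_chain * ((1.0 - p_wet[t]) if wet[t - 1] else -p_wet[t])
        wet[t] = u[t] < p
    amounts = rng.gamma(params.precip_shape,
                        params.precip_mean_mm / params.precip_shape, size=n_days)
    precip = np.where(wet, amounts, 0.0)

    return WeatherSeries(location_id=location_id, dates=pd.DatetimeIndex(dates),
                         tmax=tmax, tmin=tmin, precip=precip, rh=rh)


# ---------------------------------------------------------------------------
# Abundance surrogate
# ---------------------------------------------------------------------------

def moving_average_smooth(values: np.ndarray, window: int = 15, passes: int = 2) -> np.ndarray:
    """Centered moving average with edge truncation, applied ``passes`` times."""
    out = pd.Series(np.asarray(values, dtype=float))
    for _ in range(passes):
        out = out.rolling(window, center=True, min_periods=1).mean()
    return out.to_numpy()


def simulate_abundance(weather: WeatherSeries,
                       params: SurrogateParams = SurrogateParams()) -> AbundanceCurve:
    """Run the delayed-recruitment surrogate over a weather series.

    Returns the daily abundance curve smoothed with two passes of a 15-day
    centered moving average (the teacher model's output convention).
    """
    n = len(weather)
    if n < params.maturation_delay + 30:
        raise InsufficientHistoryError(
            f"need at least {params.maturation_delay + 30} days of weather, got {n}")
    tmean = 0.5 * (weather.tmax + weather.tmin)
    thermal = params.thermal_performance(tmean)
    survival = params.rh_survival(weather.rh)

    # rainfall-fed habitat index
    habitat = np.empty(n)
    h = 0.0
    for t in range(n):
        h = (1.0 - params.habitat_decay) * h + params.habitat_gain * weather.precip[t]
        habitat[t] = h
    habitat_factor = habitat / (habitat + params.habitat_half)

    rho = params.recruit_rate * thermal * habitat_factor * survival

    k = params.carrying_capacity
    delay = params.maturation_delay
    a = np.empty(n)
    a_t = 0.05 * k  # small seed population; transient decays within weeks
    for t in range(n):
        recruit = rho[t - delay] if t >= delay else 0.0
        a_t = (1.0 - params.mortality) * a_t + max(0.0, recruit * (1.0 - a_t / k))
        a[t] = a_t
    smoothed = np.clip(moving_average_smooth(a), 0.0, None)
    return AbundanceCurve(weather.location_id, weather.dates, smoothed, smoothed=True)


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

#: Climate regimes spanning the qualitative abundance patterns of interest:
#: hot-dry (mid-summer heat suppression producing a double-peak season),
#: hot-humid (long single season), and cold-winter (long off-season).
REGIMES: dict[str, ClimateParams] = {
    "hot_dry": ClimateParams(
        tmax_mean=33.0, tmax_amplitude=12.0, tmin_offset=13.0, tmin_amplitude=11.0,
        rh_mean=35.0, rh_amplitude=10.0, rh_peak_doy=15, rh_noise_sd=6.0,
        wet_prob_summer=0.25, wet_prob_winter=0.15, precip_mean_mm=5.0,
    ),
    "hot_humid": ClimateParams(
        tmax_mean=28.0, tmax_amplitude=5.0, tmin_offset=9.0, tmin_amplitude=4.0,
        rh_mean=75.0, rh_amplitude=5.0, rh_noise_sd=6.0,
        wet_prob_summer=0.55, wet_prob_winter=0.3, precip_mean_mm=9.0,
    ),
    "cold_winter": ClimateParams(
        tmax_mean=15.0, tmax_amplitude=14.0, tmin_offset=10.0, tmin_amplitude=13.0,
        rh_mean=65.0, rh_amplitude=8.0, wet_prob_summer=0.4, wet_prob_winter=0.35,
        precip_mean_mm=7.0,
    ),
}


@dataclasses.dataclass(frozen=True)
class Split:
    """Location/year partition: held-out test locations; training locations
    with the later years reserved for validation."""

    train_locations: tuple[str, ...]
    test_locations: tuple[str, ...]
    train_years: tuple[int, ...]
    validation_years: tuple[int, ...]

    def __post_init__(self):
        if set(self.train_locations) & set(self.test_locations):
            raise ValidationError("train and test locations overlap")


@dataclasses.dataclass
class Benchmark:
    """A fully specified synthetic study: weather, abundance, and splits."""

    weather: dict[str, WeatherSeries]
    abundance: dict[str, AbundanceCurve]
    climates: dict[str, ClimateParams]
    regimes: dict[str, str]
    split: Split
    surrogate: SurrogateParams
    seed: int

    @property
    def locations(self) -> list[str]:
        return sorted(self.weather)


def _jitter(rng: np.random.Generator, base: ClimateParams, seed: int) -> ClimateParams:
    """Small location-to-location variation around a regime's climate."""
    return dataclasses.replace(
        base,
        tmax_mean=base.tmax_mean + rng.normal(0.0, 1.0),
        rh_mean=float(np.clip(base.rh_mean + rng.normal(0.0, 3.0), 5.0, 95.0)),
        precip_mean_mm=float(max(0.5, base.precip_mean_mm * rng.uniform(0.8, 1.25))),
        seed=seed,
    )


def make_benchmark(n_locations: int = 20, years: int = 6, seed: int = 0,
                   surrogate: SurrogateParams = SurrogateParams(),
                   start_year: int = 2014) -> Benchmark:
    """Generate a reproducible multi-location benchmark with regime diversity.

    Locations cycle through the three climate regimes; roughly a quarter are
    held out as test locations (at least one per regime). The last two years
    of the training locations form the validation period.
    """
    if n_locations < 3:
        raise ValidationError("need at least 3 locations to cover all regimes")
    if years < 2:
        raise ValidationError("need at least 2 years")
    rng = np.random.default_rng(seed)
    regime_names = list(REGIMES)
    n_days = (pd.Timestamp(f"{start_year + years - 1}-12-31")
              - pd.Timestamp(f"{start_year}-01-01")).days + 1

    weather: dict[str, WeatherSeries] = {}
    abundance: dict[str, AbundanceCurve] = {}
    climates: dict[str, ClimateParams] = {}
    regimes: dict[str, str] = {}
    for i in range(n_locations):
        loc = f"loc{i:02d}"
        regime = regime_names[i % len(regime_names)]
        loc_seed = int(rng.integers(0, 2**31 - 1))
        params = _jitter(rng, REGIMES[regime], loc_seed)
        w = generate_weather(params, n_days, seed=loc_seed, location_id=loc,
                             start=f"{start_year}-01-01")
        weather[loc] = w
        abundance[loc] = simulate_abundance(w, surrogate)
        climates[loc] = params
        regimes[loc] = regime

    locs = [f"loc{i:02d}" for i in range(n_locations)]
    n_test = max(1, n_locations // 4)
    # stride 4 over regime cycle of 3 => consecutive test picks rotate regimes
    test = locs[3::4][:n_test]
    if len(test) < n_test:
        test += [l for l in reversed(locs) if l not in test][: n_test - len(test)]
    train = [l for l in locs if l not in test]

    all_years = tuple(range(start_year, start_year + years))
    n_val = min(2, years - 1)
    split = Split(
        train_locations=tuple(train),
        test_locations=tuple(sorted(test)),
        train_years=all_years[: years - n_val],
        validation_years=all_years[years - n_val:],
    )
    return Benchmark(weather, abundance, climates, regimes, split, surrogate, seed)
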