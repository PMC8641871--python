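# Methods

## Problem and model

`gravidnet` treats daily mosquito-abundance estimation as sliding-window
regression. A sample is a matrix x ∈ ℝ^{Δ×4} of Δ consecutive days (default
90) of scaled weather — columns fixed as (precip, tmax, tmin, rh) — and the
target y ≥ 0 is the scaled gravid-female abundance on the window's final
day. Ninety days is roughly three average mosquito lifespans and matches
the ramp-up horizon of mechanistic life-cycle models, so the window carries
the population-dynamical memory the mapping needs. Δ is configurable;
windows shorter than 5 days are rejected because the convolutional stack
would be empty.

### Architectures

All three emulators share the front end: Conv1D(64 filters, kernel 3,
stride 1, no padding, no additive bias) → ReLU → batch normalization, twice.
Convolution biases are omitted because they are redundant under the
following normalization; batch normalization carries a learnable scale and
shift per channel (128 parameters per layer). The heads are:

- **FF** — flatten (86 × 64 = 5504 values at Δ = 90) → Dense(64, ReLU) →
  Dense(64, ReLU);
- **LSTM** — two LSTM layers (64 units, tanh activations, sigmoid gates,
  one bias vector per gate, forget bias initialized to 1), the first
  returning its full sequence, the second its final step;
- **GRU** — two GRU layers (64 units, "reset-after" formulation with
  separate input and recurrent bias vectors per gate), stacked the same
  way.

The output layer is a single ReLU unit whose weight vector w carries an ℓ2
penalty (coefficient 0.01 by default; the penalty strength is a free
choice, as only the presence of the ‖w‖₂ term is fixed by the design). The
resulting trainable totals are FF 369,857; LSTM 79,425; GRU 63,297;
LR baseline 90·4+1 = 361. The LSTM single-bias and GRU dual-bias
conventions are load-bearing: with conv biases every count would grow by
128, and a single-bias GRU would give 63,041 instead of 63,297.

The networks are implemented directly in numpy (float64) with hand-written
backpropagation, verified against central finite differences in the test
suite. Initialization is Glorot-uniform for input kernels and per-gate
orthogonal for recurrent kernels, all seeded. Batch normalization uses
momentum 0.99 and ε = 10⁻³ and switches to running statistics at inference,
which makes predictions independent of batch composition.

### Scaling

Min–max scaling per weather variable uses the global extrema over **all
days of all training locations**; the eight extrema are model parameters,
persisted in a JSON sidecar next to the weights, and applied unchanged to
all future data. Values outside the training range deliberately map outside
[0, 1] — clipping would silently distort extreme-weather inputs.

### Training protocol

MSE loss, Adam with α = 10⁻⁴, β₁ = 0.9, β₂ = 0.999, batch size 64, at most
100 epochs. 1000 windows per training location are drawn without
replacement (the draw is per location across all its training years) and
globally shuffled. Early stopping monitors validation MSE with patience 15;
"improvement" means strictly lower than the running best (no minimum
delta), and the weights and batch-norm statistics of the best epoch are
restored. The validation split follows the protocol's shape: the later
years of the training locations, not held-out locations. A non-finite loss
raises a divergence error naming the epoch. The reported loss history is
the plain MSE; the ℓ2 term enters through the gradients only.

### Augmentation

The HI/LO location lists are produced by a reproducible heuristic on the
mean annual training curve of each location (manual override lists in the
config always win):

- **HI** (heat-suppressed double peak): at least two local maxima above 40%
  of the annual peak separated by a trough below 60% of the peak;
- **LO** (cold off-season): at least 60 consecutive days (wrapping the year
  boundary) below 20% of the peak.

On-season day-of-year masks are the stable 20%-of-peak threshold intervals
of the same mean annual curve, reusing the season definition of the
evaluation metrics rather than inventing a second convention; off-season is
the complement. HI adds 1000 windows per flagged location whose final day
falls in the on-season mask, LO adds 1000 off-season windows, HILO adds
both.

## Evaluation

Raw daily predictions are smoothed with a Savitzky–Golay filter (window 11,
polynomial order 3 — the central point of each local cubic fit), then
negatives are set to exactly 0. The filter is linear up to that clamp.

Global fit per location-year: R₊² = max(0, 1 − SS_res/SS_tot);
NRMSE = RMSE / mean(reference) (mean-normalization was chosen because the
metric exists to compare locations of different abundance scales);
Rel. AUC Diff. = (AUC_ref − AUC_pred)/AUC_ref with trapezoidal AUC, so
over-prediction is negative; Pearson r. A constant reference leaves R₊² and
r undefined; such rows are flagged and excluded from aggregates.

Season timing: for thresholds T at 20/40/60/80% of the reference peak
(peak taken per location-year), "stably above T" is operationalized as
maximal runs of days ≥ T, merged across gaps shorter than `max_gap` = 7
days, with merged runs shorter than `min_dwell` = 7 days discarded (both
configurable). Predicted intervals are matched one-to-one to reference
intervals greedily by nearest onset, closest pairs first (so an early
predicted interval cannot claim a distant reference onset while a nearer
prediction goes unmatched), ties to the earlier reference interval;
unmatched intervals are counted, not differenced. For matched
pairs, D_on = (î − i)/ℓ̄_S and D_off = (ĵ − j)/ℓ̄_S, where ℓ̄_S is the mean
over evaluated years of ℓ_S = max(j_m) − min(i_m) at the 20% threshold.

Composite score (an explicit definition of this package; the qualitative
contract is that it penalizes mean errors and error variability and is zero
for perfect predictions):

S = (1 − mean R₊²) + mean NRMSE + mean |RelAUC| + (1 − mean r)
  + (1/8) Σ_T (|D̄_on,T| + σ(D_on,T) + |D̄_off,T| + σ(D_off,T))
  + λ · frac_not_reached,  λ = 1,

where the mean |RelAUC| is the mean of per-location-year absolute values,
σ is the population standard deviation over matched pairs, and
frac_not_reached is the fraction of (location-year, threshold) cases in
which the reference reached the threshold but the prediction never did.

## Synthetic testbed

### Weather generator

Per location: tmax/tmin are seasonal sinusoids (peak at day-of-year 196)
plus shared AR(1) noise with autocorrelation time ≈ 3 weeks for temperature
(configurable; the generated lag structure recovers the configured time
constant to a few percent) and an independent component for tmin, with
tmin < tmax enforced; relative humidity is a clipped AR(1) around its own
seasonal cycle with a ≈ 6-day time constant; precipitation is a two-state
wet/dry persistence chain with seasonal wet-day probability and
gamma-distributed wet-day amounts. Everything is deterministic under
(params, seed).

### Abundance surrogate

The teacher stand-in is a minimal delayed-recruitment model, not a
life-cycle simulation:

- thermal performance B(T̄): piecewise-quadratic in mean temperature, 1 at
  t_opt = 29 °C, 0 outside (t_lo, t_hi) = (14, 36) °C — the hard upper
  cut-off is what produces the hot-summer double peak;
- habitat index H integrates rainfall with 5%/day decay and saturates as
  H/(H + 25);
- humidity survival σ(rh) rises linearly with rh, clipped to [0.1, 1];
- recruitment ρ = r_max · B · H-factor · σ enters the adult pool after a
  12-day maturation delay with logistic saturation:
  A_{t+1} = (1 − μ)A_t + max(0, ρ_{t−delay}(1 − A_t/K)), μ = 0.1/day.

Under constant forcing the fixed point is A* = ρK/(μK + ρ), which the
simulation reaches and the tests verify against the closed form. The raw
series is finished with two passes of a 15-day centered moving average
(edge-truncated so the curve keeps its length), matching the teacher's
output convention. Abundance is expressed in units of the carrying capacity
K = 1 — abundance here is defined only up to a location-specific
multiplicative factor, and O(1) targets are the natural normalization.

Benchmarks cycle locations through three regimes — hot-dry (summer mean
temperature exceeds t_hi, splitting the season), hot-humid (long humid
single season) and cold-winter (winter recruitment zero for months) — with
small per-location parameter jitter. Roughly a quarter of locations are
held out for testing (the stride-4 pick rotates through the regimes); the
last two years of the training locations form the validation period.

**What the surrogate does not emulate:** observation noise, the egg-bank /
desiccation memory of real populations (extreme-rain events far outside the
input window), location-specific carrying capacities, or any spatial
correlation between locations. Passing the recovery tests therefore shows
that the pipeline can learn a smooth, weather-driven, multi-week-memory
abundance law — not that it reproduces real surveillance counts.

## Problem sizes used by the tests and the acceptance script

The end-to-end study runs on 20 locations (15 train / 5 test) × 6 years
with 200 samples per location, validation on 100 windows per location from
the last two years, and at most 20 epochs at the protocol's fixed learning
rate — sizes chosen so the whole study is a desk-scale computation while
leaving the protocol itself untouched. At this scale the GRU reaches pooled
held-out R₊² ≈ 0.95 and the linear baseline ≈ 0.4, reproducing the
qualitative ordering GRU ≥ FF > baseline of the full-scale setting.

## Known limitations

- No GPU or mixed-precision path; training beyond desk scale is slow.
- The HI/LO flagging heuristic is a reproducible stand-in for expert manual
  curation; borderline humid-climate locations can be flagged HI when
  rain-driven troughs in their mean annual curve dip below 60% of peak.
- The composite score S and the "stably above" interval rule are explicit
  package definitions with the documented qualitative properties; other
  reasonable operationalizations would rank very similar models
  differently.
- Batch-norm inference statistics come from the exponential running
  average (momentum 0.99), so very short trainings evaluate with partially
  converged statistics.
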