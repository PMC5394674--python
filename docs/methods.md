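# Methods

## Locomotor model

Swimming is modelled in one dimension as alternation between two motor
primitives:

- **Glide**: passive deceleration under viscous drag, `dv/dt = −α v`.
  The drag constant defaults to `α = 2.7 s⁻¹`, the value recovered by the
  shared-decay fit on zebrafish-like glide waveforms.  A quadratic-drag
  alternative `dv/dt = −α_q v²` is available for model comparison; its
  closed-form decay is the hyperbola `v(t) = A/(1 + A α_q t)`.
- **Burst**: active acceleration towards the aerobic speed ceiling,
  `a(v) = a_max (1 − v/v_max)`, with `a_max = 60 cm s⁻²` (the peak value,
  produced at stand-still) and `v_max = 30 cm s⁻¹`.  The equivalent
  parametrisation `α'(v_max − v)` is recovered by setting
  `a_max = α' v_max`; both forms are exposed through the same two numbers.
  `v_max` is chosen so that ~95% of observed speeds fall below it; speeds
  are clipped to `[0, v_max]` after every integration step.

## Drag fitting

Glide phases are segmented from the speed series by strict sign changes of
the first difference (plateaus are attributed to their first index, so
segmentation is deterministic); a decreasing run into the end of the series
counts as a segment, and segments shorter than 3 samples are treated as
noise.  Each segment's amplitude `A_i` is pinned to its observed peak; the
single free parameter `α`, shared across all segments and both fish, is
found by bounded scalar minimisation (`α ∈ (0.01, 50) s⁻¹`, golden-section
via `scipy.optimize.minimize_scalar`) of the total absolute deviation
between predicted and observed speeds.  The objective is unimodal in
practice over this biological bracket.  Fit quality is reported as the
fraction of explained linear variation (below) with per-segment median
speeds as the reference predictor.

Parameter recovery: on 200 synthetic segments (amplitudes uniform on
5–30 cm/s, 30 Hz sampling, 5% multiplicative observation noise) the fit
recovers the generating `α` within ±0.1; on noiseless segments it is exact
to the optimiser tolerance.  Applied to the full closed-loop pipeline
(smoothing → differencing → segmentation → fit), the recovered constant is
biased low by roughly 15% because the 170 ms moving-average filter flattens
the fastest part of each decay — a bias shared with any tracked recording
analysed the same way, and a reason the fit is validated on unsmoothed
synthetic segments.

## The decision surface

On the switching surface, a pure glide brings the focal fish to the
partner's position exactly when their speeds match.  Integrating the glide
dynamics from `v_F` down to `v_P` against a constant-speed partner gives
the closed relative distance

    d*(v_F, v_P) = (v_F − v_P)/α − (v_P/α) ln(v_F/v_P),   v_F ≥ v_P,

with limits `d* → v_F/α` as `v_P → 0` and `d* → 0` as `v_P → v_F`.  Because
this expression is a reconstruction from the glide-matching argument, the
test suite validates it against a brute-force RK4 integration of the glide
ODE on 1,000 random states to 1e-5 relative error before anything else
depends on it.  The policy is memoryless: per decision step, glide if the
perceived gap is negative (focal fish ahead; rear blind angle), otherwise
burst iff `T = d − d* > 0`, with the tie `T = 0` resolved to glide (the
passive default on a measure-zero set).

`T` is increasing in `d`, decreasing in `v_F` and increasing in `v_P` on
the glide-matching branch — the acceleration zone grows with partner speed
and shrinks with focal speed, which is the qualitative signature the
forcemaps test.  A time-optimality signature is checked empirically:
policies with the switching surface shifted ±20% or with half the burst
amplitude never reach cohesion (|d| < 0.5 cm and |Δv| < 0.5 cm/s) faster
on a grid of initial states.

## Sensory noise

The perceived gap is `d̃ = d + ε`.  Two error models are provided by the
same `SensoryNoise` object:

- **White** (`tau_s = 0`, the controller-level default): `ε` i.i.d.
  Gaussian per decision step.
- **Drifting bias** (`tau_s > 0`): `ε` follows an Ornstein–Uhlenbeck
  process with stationary s.d. `sigma_d` and correlation time `tau_s`.

The closed-loop simulator defaults to the drifting bias
(`sigma_d = 6 cm ≈ 1.5 body lengths`, `tau_s = 1 s`).  The reason is
dynamical: a memoryless 30 Hz controller filters white distance noise
through the plant's inertia, so the pair self-centres at a gap of well
under 1 cm no matter how large the white noise is — far tighter than real
pairs swim.  A slowly drifting estimation error instead makes the follower
stabilise a phantom offset of a few centimetres, loosening the median gap
to the observed ~4.5 cm, while remaining zero-mean so the sign structure
of the extracted forcemaps is preserved.  `sigma_d = 0` reproduces the
noiseless controller exactly and consumes no random draws.

## Closed-loop simulation

Geometry is a 1-D ring of circumference 140 cm — the perimeter of a
35 × 35 cm tank, standing in for wall-following motion — with signed
distance the shortest signed arc.  Integration is forward Euler at
`dt = 1/30 s` so simulated output is frame-for-frame comparable to 30 fps
recordings; positions advance with the pre-step speed and speeds are
clipped to `[0, v_max]`.

The **leader** swims non-socially: a hysteresis oscillator that glides
until speed falls below `v_low` and bursts until it exceeds `v_high`, with
thresholds redrawn multiplicatively at every phase switch.  Defaults:
`v_low = 4 cm/s` jittered ±40% (glide troughs are the variable part of
burst-and-glide swimming) and `v_high = 22 cm/s` jittered ±10% (the burst
ceiling is physiologically consistent; the jittered value is additionally
clamped below `v_max`).  The **follower** obeys the bang-bang rule except
during non-social episodes, governed by a two-state Markov chain with exit
rate `1/15 s⁻¹` from the non-social state and `(1/15)·(0.2/0.8) s⁻¹` from
the social state, giving stationary non-social occupancy 0.2 and 15 s mean
episodes.  During those episodes the follower runs the same oscillator as
the leader.  Leadership alternates at exponentially distributed intervals
(mean 60 s by default), matching the alternating leadership of real pairs
and justifying pooling both fish as focal when building forcemaps.  An
optional follower sensorimotor latency (`latency_s`, off by default) delays
the percept of the leader's state.

These leader/noise parameters are the stand-in part of the model, and they
are pinned by calibration against the summary statistics the loop must
reproduce — per-fish speed mean ± s.d. near 13.5 ± 5.8 and 12 ± 6.5 cm/s,
median inter-fish distance near 4.6 cm, and forcemap peak amplitude near
25 cm/s² — rather than chosen independently
(`scripts/calibrate_leader.py` re-derives the sweep).  At the frozen
defaults a 30-minute run gives mean speeds ≈ 12.6 cm/s (s.d. ≈ 6.5),
median gap 4.1–4.3 cm and pooled-map peak 23–33 cm/s², stable across
disjoint seed sets.  The two simulated fish are statistically exchangeable
(roles alternate), so unlike a real pair they do not show persistent
13.5-vs-12 asymmetry; both means sit between those two values.

Output is a `TrajectoryPair` with unwrapped arclength as x and constant y
(the quasi-1-D dialect); `unroll_to_perimeter` maps it onto the square
tank perimeter when genuinely 2-D wall-following coordinates are needed.

## Forcemaps

For each usable frame (focal speed > 0) the partner's relative position
and velocity are projected onto the focal heading, and the focal
acceleration component parallel to it is the "force" sample.  Samples are
restricted to quasi-1-D episodes — heading difference < 45°, perpendicular
separation < 7 cm, parallel separation < 20 cm — then accumulated into
half-open bins: parallel distance in 10 bins over [−20, 20] cm, projected
partner speed in 6 bins over [0, 32.5] cm/s, stratified by focal speed
into 0–10.5, 10.5–21 and 21–32.5 cm/s.  The bin counts are a design
choice; the axis ranges and speed strata follow the standard presentation
of such maps.  Negative projected partner speeds fall outside the binned
range and are excluded but counted.  Leader and follower samples are
pooled by summing occupancies and accelerations before dividing — the
occupancy-weighted merge is exact and tested.

**Shuffle correction.**  Chance-level co-occurrence is estimated by
circularly shifting one fish's series by a random offset uniform on
[60 s, duration − 60 s] (10 shuffles by default; frame permutation is
available behind a flag), re-running the pipeline, and taking
`k` = shuffled / observed total occupancy.  Mean forces are scaled by
`1/(1 − k)`; occupancies are never touched, so the correction is
idempotent on the map structure, and `k ≥ 1` — shuffling producing at
least as much co-occurrence as observed — is rejected as a filter failure.
For trajectories stored in unwrapped ring coordinates the shifted partner
is re-expressed as the shortest signed arc from fish 1 (`wrap_length`),
since otherwise the unwrapped offset would send it off the track entirely.
For an already-independent pair, shuffling changes nothing and `k ≈ 1`;
for the default simulated pair `k ≈ 0.3`.

**Summaries.**  The distance profile marginalises over partner speed and
focal-speed strata (occupancy-weighted, empty bins masked, per-bin
standard errors from pooled moments).  Quadrant analysis splits the map at
`d = 0` and at the midpoint of the partner-speed range (16.25 cm/s):
Q1 = behind & slow, Q2 = ahead & slow, Q3 = behind & fast, Q4 = ahead &
fast, reported per focal-speed stratum.  On the noiseless controller
evaluated at the bin centres the ordering is exactly
Q4 > Q2 > Q3 = Q1.  On simulated maps the partner-ahead quadrants exceed
the partner-behind ones in every stratum and every quadrant is negatively
modulated by focal speed; the strict Q4 > Q2 refinement is asserted in the
fastest stratum, the only one where the glide-matching rule actually
distinguishes partner speeds — in the pooled average the difference is
diluted to ≈ 0 because slow fish produce the largest burst amplitudes and
dominate Q2's occupancy.  Peak amplitude is the maximum |mean force| over
bins with ≥ 20 observations (an acceleration-side variant is exposed via
`side="positive"`); being a maximum over ~170 noisy bin means it carries a
few cm/s² of extreme-value inflation at the 5-run scale.

## Predictability

The common statistic is the fraction of explained linear variation
`f = (T − U)/T` with `U = Σ|pred − obs|` and `T = Σ|obs − median_i(obs)|`
over episodes `i`; `f = 1` for perfect predictions, `f = 0` for the
per-episode median predictor, undefined (error) for constant observations.
Regression analyses use a single episode (global median) unless episode
boundaries are supplied.

- **Autoregressive**: `a(t+1) ~ a(t)` by ordinary least squares per
  component, pooled into one f.  Constant components (e.g. the unused
  coordinate of quasi-1-D data) carry no linear variation and are skipped.
- **Social**: a one-hidden-layer (40-unit) `MLPRegressor` maps the eight
  standardized inputs at time t — x/y positions and velocity components of
  both fish — to the focal acceleration components at t+1.  Data are split
  70/15/15 into train/validation/test at random with a fixed seed;
  standardization uses training-split moments; the validation split
  selects the lbfgs iteration budget (100 vs 500) and f is reported on the
  held-out test split.  The optimiser is deliberately unconstrained — the
  contract is the architecture, split and standardization, not the fitting
  algorithm.
- **Leadership**: normalized velocity-vector cross-correlation over lags
  up to ±5 s (150 frames); the peak lag identifies who leads, and the
  statistic is exactly antisymmetric under swapping the fish.

On simulated pairs the autoregressive f (≈ 0.65) far exceeds the social f
(≈ 0.05): the locomotor cycle, not social information, dominates
short-horizon acceleration prediction.  These simulated values are
properties of the model, not re-measurements of real fish.

## Synthetic data and I/O

One file dialect everywhere: `time,x1,y1,x2,y2` (seconds, centimetres,
one row per frame), written to 12 significant digits so round trips are
lossless to 1e-9.  The reader rejects non-numeric rows, wrong columns,
non-monotone times and gaps, reporting line numbers; no gap interpolation
or identity-swap repair is attempted (tracking is out of scope).  Fixture
factories are pure functions of their parameters and seed, and every
emitted fixture carries a JSON sidecar with its ground truth so recovery
tests never hard-code it.  Observation noise is i.i.d. Gaussian position
jitter (default 0.1 cm, sub-body-length); the 170 ms smoothing filter
reduces the induced per-frame velocity noise variance by the squared
window length (adjacent window means telescope), which is tested.

## What the synthetic conditions do and do not show

The generator emulates saw-tooth burst–glide speed profiles, quasi-1-D
wall-following, alternating leadership, non-social episodes and tracking
noise.  It does not emulate 2-D turning, wall avoidance, homebase
behaviour, aggression, fear-state switching, body-size exclusion, or
persistent individual asymmetries.  Passing tests therefore demonstrate
that the pipeline recovers the rules and statistics of the model that
generated the data — the loop-closure claim — not that real fish obey
those rules; the experimentally printed values tied to real recordings
(62% drag fit, 45%/6.5% predictability) are not reproduction targets here.

## Numerical choices

Euler at `dt = 1/30 s` for all production simulation (format parity with
recordings); reference oracles integrate at `dt = 1e-4` (RK4 for the glide
closure).  The drag optimiser tolerance is 1e-8 on α.  Decision ties go to
glide.  Degenerate inputs raise: empty segment lists, all-zero amplitudes,
constant observations in f, `k ≥ 1`, non-finite simulation states (with
the frame index).  Random streams are `numpy.random.Generator`s seeded
explicitly; acceptance sub-seeds derive from one master seed via
`SeedSequence` and stay below 2³¹.
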