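# Methods

## The model

`boutseg` segments a nest-temperature time series into incubation
**on-bouts** (parent on the nest) and **off-bouts** (parent away) with a
first-order, two-state hidden Markov model. The observation at sample
*t* is the temperature change from the previous sample,
`x_t = T_t − T_{t−1}` (with `x_1 = 0` by convention, since the first
sample has no predecessor), computed on either the raw egg temperature
or the air-adjusted egg temperature (egg − air). The model carries
exactly ten free values: initial probabilities `π_on, π_off`, the 2×2
transition matrix `a_ij`, and per-state observation means and standard
deviations `μ_s, σ_s` (degC per sample).

### Emission semantics

Decoding uses monotone **CDF weights** rather than densities: the
on-state weight of a change `x` is `Φ((x − μ_on)/σ_on)` and the
off-state weight is `1 − Φ((x − μ_off)/σ_off)`. These encode the
asymmetry of the problem directly — the more positive the change, the
more on-bout-like, at any magnitude — so a strong warming spike is never
penalized for being "too far above" the on mean, as a Gaussian density
would do. Weights are clamped to `[1e−12, 1]` so log-space recursions
stay finite.

Unsupervised learning, by contrast, runs Baum–Welch with ordinary
**Gaussian density** emissions: with densities the M-step has the
standard closed form and the expectation–maximization monotonicity
guarantee holds, neither of which is true for the CDF weights. The ten
estimated parameters are then handed to the CDF decoder. A
`emission="density"` flag on `viterbi`/`label_states` enables density
decoding for comparison. On well-separated data the two decoders agree
almost everywhere; they differ mainly at extreme observations, where the
CDF weights saturate at 1 instead of falling off.

### Decoding and learning

* `viterbi` maximizes the path product of initial/transition
  probabilities and emission weights in log space. Ties are broken by
  preferring to remain in the previous state, and by preferring *on* at
  the first point — stated explicitly so brute-force enumeration can
  replicate the decoder bit-exactly on small instances (and does, in the
  test suite, over 100 random instances of up to 12 points).
* `forward_backward` uses per-step scaling; its log-likelihood matches
  exhaustive summation over all `2^T` paths to 1e−9 on small instances,
  and hmmlearn's `GaussianHMM.score` on identical parameters for the
  density case.
* `baum_welch` starts from a deterministic median split of the deltas
  (lower half seeds the off state, upper half the on state; transitions
  0.9 self / 0.1 cross; uniform initial distribution), so no random
  initialization is needed; an optional seed enables jittered
  multi-start, best final likelihood wins. Convergence: relative
  log-likelihood improvement below `tol = 1e−6`, capped at 250
  iterations. Standard deviations are floored at `1e−3` degC/sample and
  a degenerate-fit warning is logged if a state's expected occupancy
  falls below one effective point.
* `supervised_fit` is exact maximum-likelihood counting on a contiguous
  block of hand labels: transition probabilities are normalized pair
  counts, state moments are sample mean and SD (n−1), the initial
  distribution is the indicator of the first labeled point's state.
  Zero transition probabilities are legitimate (e.g. a bird that never
  leaves at night); no pseudocounts are added by default.

### Segmentation, filtering, statistics

Decoded states are run-length encoded into bouts. A bout's duration
includes one trailing sampling interval, so a one-point bout lasts one
interval and bout durations tile the trace exactly: `Σ durations = span
+ one interval`. This conservation law is asserted at every statistics
tier.

The off-bout filter reclassifies decoded off-bouts whose egg-temperature
drop or duration falls below user thresholds, then merges neighbors.
The drop is measured as *starting temperature minus the bout's minimum*,
not the net start-to-end change, because a parent may return before the
logger catches the rebound — net change would understate real drops.
The filter runs after decoding in every workflow, is idempotent, and is
off by default (both thresholds 0).

Statistics come in three tiers — individual bout, individual day/file,
and pooled multi-file. Bouts are assigned to the calendar date (and the
day or night window, default 07:00–19:00) containing their start time;
temperature statistics are computed point-wise, each sample in its own
date and window, so nothing is double counted at boundaries. "Time
above/below critical egg temperature" uses strict inequalities, each
qualifying sample contributing one full interval. Pooled statistics
weight every bout and every point equally (pooling, not mean-of-means).
Standard deviations use the n−1 denominator and are left blank when
n < 2. Durations are reported in minutes and temperatures in degC, both
with 2 decimals; internal precision is full double.

## The synthetic-trace generator

`simulate_trace` emulates an egg-shaped thermal probe in an attended
nest: a two-state Markov chain with geometric (memoryless) bout
durations drives Newtonian relaxation of egg temperature,

    egg[t] = egg[t−1] + k · (target − egg[t−1]) + ε_t ,

with `target = setpoint, k = k_on` during on-bouts and
`target = air(t), k = k_off` during off-bouts; air follows a diurnal
sinusoid bottoming out at a configurable clock time (05:00 default) and
`ε_t` is Gaussian sensor noise. Geometric durations are chosen
deliberately: they match the first-order Markov assumption of the
decoder, so recovery tests have an exactly correct target — the
generating self-transition probability is `1 − interval/mean_duration`.

Default conditions (also the `clear` preset): 30-s sampling, 24 h,
setpoint 37.5 degC, air 18 ± 6 degC, mean on-bout 60 min, mean off-bout
8 min, `k_on = 0.2`, `k_off = 0.018` per sample, noise SD 0.02 degC.
These give warming/cooling deltas well separated from sensor noise — the
regime the method is designed for, comparable to a songbird nest logged
at 30 s. The `hard` preset (weak contrast, noise SD 0.15 degC, short
off-bouts) exercises smoothing and the bout filter; `quail-2min` and
`swallow-30s` mirror common logger programs (2-min sampling with
overnight sitting; 30-s sampling with short bouts).

### What the generator does and does not emulate

It reproduces the features the model consumes: regular sampling,
state-dependent temperature trends, diurnal ambient drift, sensor noise.
It does **not** emulate partial-incubation postures, weather fronts,
probe displacement, clutch-size effects, or non-geometric bout-length
distributions (real birds have refractory periods). Passing tests on
simulated data therefore demonstrate correctness of the algorithms under
the model's own assumptions, not field accuracy; on real data,
predictions should be spot-checked against direct observation.

One limitation is intrinsic and worth knowing: an off-bout that begins
before the egg has rewarmed (after a return of only a sample or two)
produces near-zero temperature changes throughout and is undetectable in
principle by *any* method based on temperature change — in 250 simulated
clear-mode off-bouts we observed one such case. The recommended
clear-mode decode (smoothing window 3) achieves ≥ 95% pointwise accuracy
on every 24-h fixture we generate in the tests, typically ~98%.

## Numerical and design choices

* **Smoothing** is a centered rolling mean whose window is clipped at
  the series edges (`[1,2,3,4,5]`, window 3 → `[1.5, 2, 3, 4, 4.5]`); a
  centered window keeps bout boundaries unshifted in time, where a
  trailing window would bias transitions late. Default off; window 3
  when requested without a value.
* **First point:** its delta is defined as 0 and its state comes from
  the full decode; 0 lies between typical on/off means, so its influence
  is negligible.
* **Gaps:** sampling gaps up to 2× the modal interval are tolerated with
  a warning; larger gaps split the trace into segments decoded
  independently (the model assumes regular observations), with bout and
  summary outputs concatenated.
* **Timestamps** are timezone-naive local time; no daylight-saving
  handling. Accepted layouts are `M/D/YYYY H:MM[:SS]` and ISO-8601;
  anything else is an explicit parse error naming the row — silent
  guessing is worse than failure.
* **Multi-file runs:** supervised parameters are fit once, from the
  labels applied to the first input file, then reused for every file;
  unsupervised learning runs per file by default (nests differ), with
  `--pool-learning` to fit one model on all files concatenated.
* **Problem sizes in tests:** brute-force oracles run at T ≤ 12 (path
  enumeration) and T ≤ 10 (likelihood summation); recovery tests use
  T = 10,000; end-to-end fixtures are 24-h traces at 30-s sampling
  (2,881 points). These sizes make every oracle exact or statistically
  decisive while keeping the whole suite under half a minute.

## Known limitations

* Two states only; no partial-incubation or multi-parent structure.
* Emissions are conditionally independent given states; real cooling
  within an off-bout is autocorrelated and decays toward ambient, which
  the fixed per-state Gaussian only approximates — the main source of
  decode error in long off-bouts.
* The CDF/density split means the unsupervised objective is not exactly
  the decoding objective; in practice the estimated parameters transfer
  cleanly, but a likelihood printed by Baum–Welch is a density
  likelihood, not a CDF-weight score.
* Posterior (per-point) decoding is available via `forward_backward`
  but Viterbi is the default and the only path used by the CLI.
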