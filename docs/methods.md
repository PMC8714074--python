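# Methods

## Scope and model

`mseqrc` implements system identification of spiking, optic-flow-sensitive
neurons by m-sequence reverse correlation. The underlying model is the
standard linear–nonlinear (LN) cascade: the spike response y(t) is assumed
to arise from the stimulus x(t) — here, the ±1 polarity of successive roll
impulses — by convolution with a causal linear kernel h(t), optionally
followed by a static nonlinearity. Because a maximal-length shift-register
sequence has delta-like circular autocorrelation (N at lag 0, −1
elsewhere, N = 2ⁿ−1), the kernel can be read out by cross-correlating the
impulse-polarity sequence with the binned spike train: on a noiseless
linear response over a circularly extended sequence the estimator equals

    ĥ(τ) = h(τ)·(1 + 1/N) − Σh/N

exactly, which is the closed-form oracle used in the test suite.

## Stimulus

The stimulus model is a starfield: `round(density · side³)` spheres
(defaults 100 /m³ in a 4 m cube, 2 cm diameter) placed uniformly around
the animal and projected gnomonically onto a screen 6.5 cm away subtending
155° × 138° (2560 × 1440 px, 165 Hz). Spheres are drawn only when in
front of the animal at straight-line distances within [6 cm, 2 m] —
brightness interpolates linearly from black at 6 cm to white at 2 m, so a
sphere at 2 m is white on the white background and invisible; cutting the
render at 2 m is what reproduces the ~1200 visible spheres of the default
geometry (without the far cutoff the count roughly doubles). Roll rotates
the cloud about the body axis (positive = counter-clockwise on screen);
lift translates it vertically (positive = downward on screen, the
excitatory direction), with positions wrapped modulo the cube so density
is stationary over a trial.

Each trial presents an 8th-order m-sequence (255 impulses) circularly
extended to 400 frames; the leading 145 frames are warm-up and only the
final full period is analysed. Per frame the roll increment is
`sign · base_impulse + constant_roll / frame_rate` and the lift increment
is `constant_lift / frame_rate`; exact values are used internally
(descriptions that print 0.3/0.63/0.303 are 2-decimal roundings). The
nine standard conditions are impulse sizes 0.18°/0.33°/0.48° ("Roll
18/33/48"), Roll 33 plus constant roll at ±25/±50 °/s, and Roll 33 plus
constant lift at ±50 cm/s.

One convention choice deserves note: with the display mapping bit 1 → +1
(chosen so the majority value is +1, matching the balance property
2ⁿ⁻¹ of +1), the elementwise product of the sequence with a shifted copy
equals the *negation* of a circular shift; the classic product-closure
property holds verbatim under the opposite mapping (−1)^bit. The verifier
therefore checks closure over GF(2) — XOR of the bit sequence with any
nonzero shift is another shift — which is equivalent and
convention-independent.

## Synthetic generator

The generator exists so that every downstream stage is testable without
recordings. Each ground-truth neuron is an LN cascade with Bernoulli
spiking:

* **Kernel** — a causal log-normal lag profile
  `h(t) = A·exp(−ln²(t/ttp)/2σ²)` with σ set in closed form so the full
  width at half maximum is exact. Defaults: peak time 18 ms, half-width
  12 ms (the study-median kernel timing), length 300 ms.
* **Drive** — the kernel filters the per-frame roll input expressed in
  units of the base impulse (±1 for a pure m-sequence; a constant-roll
  condition adds `constant_roll/(frame_rate·base)` per frame), scaled by
  `roll_gain`, plus the per-frame lift increment (cm) scaled by
  `lift_gain`. Impulse-size conditions scale `roll_gain` proportionally,
  so impulse size acts multiplicatively on drive, not through the
  correlation input. Right-side neurons receive sign-flipped roll drive.
* **Nonlinearity** — `rate = clip(r0 + drive, 0, 300 Hz)` with baseline
  r0 ~ U(20, 40) Hz.
* **Spiking** — at most one spike per 1 ms bin with probability
  `rate·1 ms` (implicit 1 ms refractoriness); adequate below ~300 Hz.

Gains were calibrated once to the firing-rate scale of the recordings the
protocol emulates: `roll_gain = 80` puts the constant-excitatory-roll
condition near the ~199 spikes/s preferred-direction reference while
Roll 33 m-sequence rates sit near 60 Hz; `lift_gain = 200` makes
excitatory lift raise the spike rate by roughly +178%. A lognormal ±10%
gain jitter across neurons provides realistic heterogeneity.

The default experiment is 12 neurons × 9 conditions × 8 trials, every
trial a fresh random m-sequence (random primitive polynomial, register
state and circular phase) except the second Roll 33 trial, which shares
one m-sequence across all neurons for cross-neuron validation. All
randomness derives from one master seed through a `SeedSequence` tree, so
datasets are bit-reproducible.

What the generator does **not** emulate: adaptation and persistent
firing (so the synthetic return-to-baseline is short, ~40 ms, versus
~100 ms in recordings — passing recovery tests says nothing about slow
response components in real neurons); direction-asymmetric lift input
(the model's lift term is linear, so "neutral" lift is inhibitory to the
model rather than merely non-excitatory); correlated trial-to-trial
variability; and spike-sorting artefacts. Default neurons are all
left-sided so that one shared physical m-sequence is identical for every
neuron in preferred-direction coordinates; the mirror machinery is used
whenever right-side neurons are simulated or loaded.

## Analysis

* **QC** — a trial with any dropped stimulus frame is discarded whole.
* **Inclusion** — a neuron whose preferred-direction roll rate is below
  `round(0.8 × 199) = 159` spikes/s is removed (strictly below: exactly
  159 is kept); a neuron-condition with mean rate below 5 spikes/s over
  trials is removed. In the synthetic pipeline the preferred-direction
  rate is taken from the constant-excitatory-roll condition.
* **Kernel estimation** — spikes binned at 1 ms; for each of the final
  255 impulses the ±1 sign is placed at the frame-onset millisecond; the
  raw correlation `(1/M)·Σ s_m·y(t_m+τ)` is computed on the lag grid
  [−200, 600] ms, averaged over trials, and smoothed with a Gaussian of
  SD 5 ms (truncated ±3 SD; a config switch interprets the window as
  FWHM instead). The constant-flow component is never part of x.
* **Parameters** — amplitude = max over lags ≥ 0; TTP = its lag
  (earliest on ties); half-width from the two 50%-of-peak crossings with
  linear interpolation; decay = interpolated first crossing of
  amplitude/e after the peak, minus TTP. Return to baseline uses a
  separate 25 ms-Gaussian smoothing of the raw mean correlation: the
  first lag after the TTP inside mean ± 2 SD of the baseline region
  (lags −200…−10 ms; SD floored at 10⁻⁶ of the amplitude so noiseless
  inputs behave), minus TTP. Spike rate = spikes during the 255 analysed
  impulses over their duration. A kernel with no positive peak yields
  NaN parameters flagged undefined, never silent zeros.
* **Validation** — per neuron, a kernel and a binned static nonlinearity
  (20 equal-occupancy bins of the generator signal; out-of-range inputs
  clamp to edge bins) are fitted on the shared-condition trials with the
  shared trial held out. The shared-trial prediction
  `NL(x_shared ⊛ ĥ)` is compared (Pearson, over the final-period span)
  with the reference: the summed spike trains of all other neurons,
  smoothed with a 200 ms centred sliding mean (window shrinking at the
  edges). The prediction receives the same smoothing by default so the
  comparison is like-with-like (config switch).
  One DC subtlety: because the m-sequence signs sum to +1 rather than 0,
  a stimulus-independent spike train of mean rate ȳ produces a flat
  correlation offset ȳ/M at every lag. In the prediction path this
  offset is removed analytically per trial before averaging — it carries
  no kernel information, but left in place it couples every prediction
  (including the shuffled controls, which would then sit at r ≈ +0.1–0.2
  rather than 0) to the sliding average of the stimulus. Kernels used
  for parameter extraction are left as plain cross-correlations.
* **Shuffle control** — per neuron, 20 repetitions: every training spike
  train replaced by the same number of uniformly random times, kernel
  and nonlinearity refitted, the shared trial predicted and correlated
  with the unshuffled reference; per-neuron means, then the median
  across neurons. The statistic's own sampling noise is substantial by
  construction (20 shuffles, ~8 independent 200 ms windows in the
  correlated span): its across-replicate SD is ≈ 0.03 around 0.
* **Statistics** — per parameter, an omnibus Kruskal–Wallis test across
  all conditions (tie-corrected H, χ² p; H = 0, p = 1 when all values
  are identical), then pairwise two-sided Mann–Whitney U tests (exact
  null when both groups ≤ 12 and tie-free, normal approximation with tie
  correction otherwise) corrected by Benjamini–Hochberg within one
  parameter's family; significance at adjusted p < 0.05. Percent change
  = 100·(median_condition − median_reference)/median_reference. The
  compact-letter display for figure panels is presentation plumbing
  computed greedily from the significance matrix.

## Numerical choices and problem sizes

1 ms analysis grid throughout (TTP is reported below frame resolution,
so sub-frame lags are kept). Frame onsets are floored to milliseconds.
Correlation products falling outside the spike vector are dropped via
zero padding with M constant. Kernel normalisation is 1/M (amplitudes
are in arbitrary units; the normalisation is fixed and documented).
Quantile bin edges are nudged by ±10⁻⁹ so extreme values fall inside the
outer bins; duplicate edges are merged with a warning. Simulations in
tests and the acceptance script use the protocol sizes themselves
(12 neurons, 8 trials, 255 analysed impulses, 100–120 Monte-Carlo
starfield placements), which run in seconds.

## Known limitations

Exact reproduction of the recorded trials is impossible without the
study's stimulus logs (the generating polynomials are not published);
the loader targets this package's own CSV schema, with the manifest as
the documented adapter point for deposited data. Kernel-parameter
medians of the recordings (e.g. the ~100 ms return to baseline) are not
reproduced by the synthetic generator by design — it contains no
slow/persistent component; an optional slow-tail flag was considered and
left out of the default model. The screen projection is planar
(gnomonic) with the pixel scale fixed by the stated angular extents at
screen centre; no gamma or edge-distortion modelling.
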