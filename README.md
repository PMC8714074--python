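# mseqrc

M-sequence reverse correlation for optic-flow-sensitive spiking neurons:
stimulus construction, impulse-response (kernel) extraction, LN-model
validation and nonparametric group statistics, exercised end to end on a
built-in synthetic spiking-neuron generator.

## The problem

Wide-field motion-sensitive descending neurons relay optic-flow
information (roll, lift) from the visual lobes toward motor centres. A
fast way to characterise their temporal response is white-noise system
identification with maximal-length shift-register sequences
(m-sequences): a sequence of ±1 values sets the direction of successive
small roll impulses of a starfield stimulus shown at the display frame
rate, and the neuron's impulse response falls out of a cross-correlation.

Writing the spike response as a convolution y(t) = (x ⊛ h)(t) of the
impulse-polarity sequence x with a causal kernel h, the delta-like
circular autocorrelation of an m-sequence (N at lag 0, −1 elsewhere,
N = 2ⁿ − 1) gives the estimator

    ĥ(τ) = (1/M) Σₘ sₘ · y(tₘ + τ)  =  h(τ)·(1 + 1/N) − Σh/N   (noiseless case)

over the M = 255 analysed impulses of an order-8 sequence. From each
kernel six parameters are extracted (amplitude, time to peak, half-width,
1/e decay, return to baseline of a broadly smoothed correlation, spike
rate), an LN model (kernel + binned static nonlinearity) predicts the
response to a shared held-out m-sequence trial with leave-one-neuron-out
correlation, and parameters are compared across stimulus conditions with
Kruskal–Wallis and BH-corrected Mann–Whitney tests.

The package is aimed at sensory-systems electrophysiologists who want a
tested, reproducible implementation of this analysis chain — and a
ground-truth generator to verify it recovers what it should.

## Worked example

```python
from mseqrc.pipeline import RunConfig, run_pipeline

results = run_pipeline(RunConfig(seed=5))
cols = ["amplitude", "ttp_ms", "half_width_ms", "spike_rate_hz"]
print(results["params"].groupby("condition")[cols].median().round(3))
v = results["validation"]
print(f"loo median r = {v.median:.3f}, shuffle median = "
      f"{results['shuffle']['median']:.3f}")
```

prints (12 synthetic neurons, 9 conditions, 8 trials each):

```
                 amplitude  ttp_ms  half_width_ms  spike_rate_hz
condition
er25                 0.050    19.0         16.685        114.125
er50                 0.050    19.0         17.133        181.864
ir25                 0.017    19.0         17.212         21.272
ir50                 0.005    21.0         21.541          5.257
lift_excitatory      0.052    19.0         16.820        154.930
lift_neutral         0.007    20.0         20.411          8.007
roll18               0.022    19.0         16.999         39.309
roll33               0.035    19.0         17.200         56.820
roll48               0.048    19.0         17.297         75.625

loo median r = 0.947, shuffle median = 0.025
```

Reading this: kernel amplitude grows with impulse size (roll18 → roll48)
and with added excitatory roll (er25/er50), and collapses under constant
inhibitory roll (ir25/ir50) or the non-excitatory lift direction — the
qualitative fingerprint of these neurons. Time to peak sits at ~19 ms for
a ground-truth kernel peaking at 18 ms (the +1 ms is the expected shift
from smoothing a skewed kernel with a 5 ms Gaussian). The LN prediction
of the shared held-out trial correlates ~0.95 with the other neurons'
pooled response, while predictions rebuilt from temporally shuffled
spikes sit at ~0 — the estimated kernels are not an artefact of the
analysis.

The same pipeline is scriptable from the shell:

```
mseqrc all --seed 5 --out runs/demo          # full pipeline, CSV/JSON outputs
mseqrc simulate --seed 5 --out data/demo     # export a synthetic dataset
mseqrc validate --seed 5                     # LOO validation + shuffle control
```

`RunConfig` (YAML-serialisable) controls neuron/trial counts, smoothing
windows, bin counts, inclusion thresholds and input mode (`synthetic` or
`csv` for datasets exported by `simulate` / external recordings in the
same schema).

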