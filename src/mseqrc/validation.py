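"""LN-model validation against a shared held-out m-sequence trial.

Each neuron's kernel (estimated from its own trials, excluding the shared
trial) is convolved with the stimulus to form a linear "generator
signal"; a static nonlinearity — the mean firing rate per generator-value
bin — maps it to a predicted rate.  The prediction for the shared trial
is then correlated (Pearson) with the reference response: the summed
spike trains of all OTHER neurons to that same shared m-sequence,
smoothed with a 200 ms sliding mean.  Repeating this for every neuron
gives a leave-one-neuron-out distribution of prediction correlations.

A negative control repeats the whole procedure with temporally shuffled
spike trains; the resulting correlations scatter around zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mseqrc.kernels import (
    DEFAULT_LAG_RANGE,
    ImpulseResponse,
    cross_correlate,
    mean_smooth,
)
from mseqrc.spikes import SpikeTrain, bin_spikes, mirror_normalize
from mseqrc.starfield import StimulusTrace
from mseqrc.synthetic import SyntheticDataset, Trial

__all__ = [
    "Nonlinearity",
    "ValidationResult",
    "generator_signal",
    "fit_nonlinearity",
    "predict_response",
    "reference_response",
    "loo_correlations",
    "shuffle_control",
]

#: Width (ms) of the sliding-mean window applied to the reference response
#: (and, by default, to the prediction before correlating).
REFERENCE_SMOOTH_MS = 200


@dataclass
class Nonlinearity:
    """Binned static nonlinearity: mean firing rate per generator-value bin."""

    bin_edges: np.ndarray            # len n_bins + 1, strictly increasing
    mean_rate: np.ndarray            # Hz, per bin
    counts: np.ndarray               # samples per bin

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 1):
            raise ValueError("every retained bin must be occupied")

    @property
    def n_bins(self) -> int:
        return len(self.mean_rate)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate by bin lookup; out-of-range inputs clamp to edge bins."""
        idx = np.clip(
            np.searchsorted(self.bin_edges[1:-1], x), 0, self.n_bins - 1
        )
        return self.mean_rate[idx]


@dataclass
class ValidationResult:
    """Leave-one-neuron-out prediction correlations."""

    per_neuron: dict[str, float]
    median: float
    range: tuple[float, float]
    shuffle_per_neuron: dict[str, float] = field(default_factory=dict)
    shuffle_median: float = float("nan")

    def __post_init__(self) -> None:
        for r in self.per_neuron.values():
            if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError(f"correlation {r} outside [-1, 1]")


def generator_signal(
    trace: StimulusTrace, kernel: ImpulseResponse | np.ndarray
) -> np.ndarray:
    """Convolve the ±1 impulse train with the (causal part of the) kernel.

    Impulses are placed at frame-onset milliseconds; the signal is
    returned on the 1 ms grid over the trace duration.
    """
    if isinstance(kernel, ImpulseResponse):
        h = kernel.values[kernel.lags >= 0]
    else:
        h = np.asarray(kernel, dtype=float)
    n_ms = int(np.ceil(trace.duration * 1000.0))
    onsets = np.floor(trace.frame_times * 1000.0).astype(int)
    imp = np.zeros(n_ms)
    np.add.at(imp, onsets,
              trace.sign_sequence * trace.frame_log.astype(float))
    return np.convolve(imp, h)[:n_ms]


def fit_nonlinearity(
    generator: np.ndarray, spike_vector: np.ndarray, n_bins: int = 20
) -> Nonlinearity:
    """Bin the generator signal and average the observed rate per bin.

    Bins are equal-occupancy (quantiles of the generator values).  If
    there are fewer distinct values than requested bins, duplicate edges
    are merged with a warning.
    """
    g = np.asarray(generator, dtype=float)
    y = np.asarray(spike_vector, dtype=float)
    if len(g) != len(y):
        raise ValueError("generator and spike vector lengths differ")
    edges = np.quantile(g, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        warnings.warn(
            f"fewer distinct generator values than bins; merged to "
            f"{len(uniq) - 1} bins",
            stacklevel=2,
        )
        edges = uniq
    if len(edges) < 2:
        edges = np.array([edges[0], edges[0] + 1e-9])
    idx = np.clip(np.searchsorted(edges[1:-1], g), 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=y, minlength=len(edges) - 1)
    keep = counts > 0
    with np.errstate(invalid="ignore"):
        rates = np.where(keep, sums / np.maximum(counts, 1), 0.0) * 1000.0
    if not np.all(keep):
        # drop empty interior bins by merging their edges away
        edges = np.concatenate([edges[:-1][keep], edges[-1:]])
        rates = rates[keep]
        counts = counts[keep]
    return Nonlinearity(bin_edges=edges, mean_rate=rates, counts=counts)


def _sliding_mean(x: np.ndarray, window_ms: int) -> np.ndarray:
    """Centred sliding mean; the window shrinks at the edges."""
    if window_ms <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(window_ms)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(len(x)), kernel, mode="same")
    return num / den


def predict_response(
    shared_trace: StimulusTrace,
    kernel: ImpulseResponse | np.ndarray,
    nonlinearity: Nonlinearity,
    smooth_ms: int = REFERENCE_SMOOTH_MS,
) -> np.ndarray:
    """Predicted rate for the shared trial: NL(generator), then smoothing.

    By default the prediction receives the same 200 ms sliding mean as the
    reference response, so the correlation compares like with like; pass
    ``smooth_ms=0`` to skip it.
    """
    rate = nonlinearity(generator_signal(shared_trace, kernel))
    if smooth_ms:
        rate = _sliding_mean(rate, smooth_ms)
    return rate


def reference_response(
    spike_trains: list[SpikeTrain], smooth_ms: int = REFERENCE_SMOOTH_MS
) -> np.ndarray:
    """Sum the binned spike trains and apply a centred sliding mean."""
    if not spike_trains:
        raise ValueError("need at least one spike train")
    binned = [bin_spikes(t) for t in spike_trains]
    n = min(len(b) for b in binned)
    total = np.sum([b[:n] for b in binned], axis=0).astype(float)
    return _sliding_mean(total, smooth_ms)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _analysis_span(trace: StimulusTrace) -> tuple[int, int]:
    """Millisecond span of the final analysed m-sequence period."""
    start = int(np.floor(trace.frame_times[trace.analysis_start] * 1000.0))
    end = int(np.ceil(trace.duration * 1000.0))
    return start, end


def _neuron_trace(dataset: SyntheticDataset, nid: str,
                  trace: StimulusTrace) -> StimulusTrace:
    """The trace in the neuron's preferred-direction frame."""
    side = getattr(dataset.neurons[nid], "side", "left")
    return mirror_normalize(trace, side)


def _shared_trial(dataset: SyntheticDataset, nid: str) -> Trial:
    trials = dataset.trials[(nid, dataset.shared_condition)]
    for t in trials:
        if t.shared:
            return t
    raise ValueError(f"neuron {nid} has no shared trial")


def _training_trials(dataset: SyntheticDataset, nid: str) -> list[Trial]:
    """The neuron's shared-condition trials with the shared one held out."""
    return [
        t for t in dataset.trials[(nid, dataset.shared_condition)]
        if not t.shared
    ]


def _fit_neuron(
    dataset: SyntheticDataset,
    nid: str,
    n_bins: int,
    window_ms: float,
    shuffle_rng: np.random.Generator | None = None,
) -> tuple[ImpulseResponse, Nonlinearity]:
    """Kernel + nonlinearity from the neuron's non-shared trials.

    With ``shuffle_rng`` set, every training spike train is replaced by a
    uniformly redrawn one of the same count (the negative control).

    Each per-trial correlation has its analytic DC offset removed before
    averaging: because the m-sequence signs sum to +1 rather than 0, a
    stimulus-independent spike train of mean rate ȳ produces a flat
    correlation of ȳ·Σs/M at every lag.  That offset carries no impulse-
    response information, but left in place it couples the prediction to
    the sliding average of the stimulus; it is subtracted exactly (from
    the known spike count), adding no estimation noise.
    """
    training = _training_trials(dataset, nid)
    if not training:
        raise ValueError(f"neuron {nid} has no training trials")
    corrs, gens, vecs = [], [], []
    for trial in training:
        train = trial.train
        if shuffle_rng is not None:
            train = SpikeTrain(
                times=np.sort(
                    shuffle_rng.uniform(0, train.duration, train.n_spikes)
                ),
                duration=train.duration,
                neuron_id=train.neuron_id,
                condition=train.condition,
                trial=train.trial,
            )
        vec = bin_spikes(train)
        trace_n = _neuron_trace(dataset, nid, trial.trace)
        corr = cross_correlate(trace_n, vec)
        start = trace_n.analysis_start
        signs = trace_n.sign_sequence[start:].astype(float)
        dc = float(vec.mean()) * signs.sum() / len(signs)
        corrs.append(corr - dc)
        vecs.append(vec)
    kernel = mean_smooth(corrs, window_ms=window_ms)
    clipped = []
    for trial, vec in zip(training, vecs):
        g = generator_signal(_neuron_trace(dataset, nid, trial.trace), kernel)
        s, e = _analysis_span(trial.trace)
        gens.append(g[s:e])
        clipped.append(vec[s:e])
    nl = fit_nonlinearity(
        np.concatenate(gens), np.concatenate(clipped), n_bins=n_bins
    )
    return kernel, nl


def _predict_and_correlate(
    dataset: SyntheticDataset,
    nid: str,
    kernel: ImpulseResponse,
    nl: Nonlinearity,
    references: dict[str, np.ndarray],
    smooth_ms: int,
) -> float:
    shared = _shared_trial(dataset, nid)
    pred = predict_response(
        _neuron_trace(dataset, nid, shared.trace), kernel, nl,
        smooth_ms=smooth_ms,
    )
    s, e = _analysis_span(shared.trace)
    return _pearson(pred[s:e], references[nid][s:e])


def _references(
    dataset: SyntheticDataset, smooth_ms: int
) -> dict[str, np.ndarray]:
    """Per held-out neuron: smoothed summed response of all OTHER neurons."""
    shared_trains = {
        nid: _shared_trial(dataset, nid).train for nid in dataset.neuron_ids
    }
    refs = {}
    for nid in dataset.neuron_ids:
        others = [t for n, t in shared_trains.items() if n != nid]
        refs[nid] = reference_response(others, smooth_ms=smooth_ms)
    return refs


def loo_correlations(
    dataset: SyntheticDataset,
    n_bins: int = 20,
    window_ms: float = 5.0,
    smooth_ms: int = REFERENCE_SMOOTH_MS,
) -> ValidationResult:
    """Leave-one-neuron-out prediction correlations for the shared trial."""
    if len(dataset.neuron_ids) < 2:
        raise ValueError("need at least 2 neurons for leave-one-out")
    refs = _references(dataset, smooth_ms)
    per_neuron = {}
    for nid in dataset.neuron_ids:
        kernel, nl = _fit_neuron(dataset, nid, n_bins, window_ms)
        per_neuron[nid] = _predict_and_correlate(
            dataset, nid, kernel, nl, refs, smooth_ms
        )
    vals = np.array(list(per_neuron.values()))
    return ValidationResult(
        per_neuron=per_neuron,
        median=float(np.median(vals)),
        range=(float(vals.min()), float(vals.max())),
    )


def shuffle_control(
    dataset: SyntheticDataset,
    rng: np.random.Generator,
    n_shuffles: int = 20,
    n_bins: int = 20,
    window_ms: float = 5.0,
    smooth_ms: int = REFERENCE_SMOOTH_MS,
) -> tuple[dict[str, float], float]:
    """Shuffled-spike control for the leave-one-out validation.

    For each neuron the kernel and nonlinearity are re-estimated
    ``n_shuffles`` times from uniformly shuffled spike trains, each time
    predicting the shared trial and correlating with the (unshuffled)
    reference of the other neurons.  Returns the per-neuron mean
    correlations and their median across neurons.
    """
    if len(dataset.neuron_ids) < 2:
        raise ValueError("need at least 2 neurons for leave-one-out")
    refs = _references(dataset, smooth_ms)
    per_neuron = {}
    for nid in dataset.neuron_ids:
        rs = []
        for _ in range(n_shuffles):
            kernel, nl = _fit_neuron(
                dataset, nid, n_bins, window_ms, shuffle_rng=rng
            )
            rs.append(
                _predict_and_correlate(
                    dataset, nid, kernel, nl, refs, smooth_ms
                )
            )
        per_neuron[nid] = float(np.mean(rs))
    median = float(np.median(list(per_neuron.values())))
    return per_neuron, median
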