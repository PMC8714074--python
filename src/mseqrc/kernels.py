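"""Impulse-response estimation by cross-correlation and parameterisation.

Assuming the spike response y(t) arises from the stimulus x(t) by
convolution with a linear kernel h(t), the kernel is estimated as the
cross-correlation of the ±1 m-sequence (impulses placed at frame-onset
milliseconds) with the binned spike train.  Because the circular
autocorrelation of an m-sequence is N at lag 0 and −1 elsewhere, on a
noiseless linear response this estimator returns
``h * (1 + 1/N) - sum(h)/N`` exactly.

Only the final full m-sequence period (255 impulses at order 8) of each
trial enters the estimate; the earlier impulses are warm-up.  Per-trial
correlations are averaged across trials and smoothed with a 5 ms Gaussian
to give the kernel, and re-smoothed with a broad 25 ms Gaussian for the
return-to-baseline measurement.

Six scalar parameters summarise each kernel: amplitude (peak value), time
to peak (TTP), half-width (width at 50% of the peak), decay (time past
the peak to fall to 1/e of it), return to baseline (time past the peak
for the broadly smoothed correlation to re-enter ±2 SD of its baseline),
and the mean spike rate during the analysed impulses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from mseqrc.spikes import SpikeTrain, bin_spikes
from mseqrc.starfield import StimulusTrace

__all__ = [
    "ImpulseResponse",
    "KernelParams",
    "DEFAULT_LAG_RANGE",
    "cross_correlate",
    "mean_smooth",
    "extract_params",
    "shuffled_kernel",
]

#: Lag grid (ms) of the estimated kernels: [-200, +600] at 1 ms.
DEFAULT_LAG_RANGE = (-200, 600)
#: Baseline region (ms) of the broadly smoothed series used for the
#: return-to-baseline band; the kernel is causal, so lags well before 0
#: reflect correlation noise only.
BASELINE_LAGS = (-200, -10)
#: SD floor of the baseline band, as a fraction of the amplitude; guards
#: noiseless inputs whose baseline has zero variance.
BASELINE_SD_FLOOR = 1e-6


@dataclass
class ImpulseResponse:
    """A lag-indexed kernel estimate on a uniform 1 ms grid."""

    lags: np.ndarray                 # ms
    values: np.ndarray               # a.u.
    smoothing_ms: float = 0.0
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.lags) != len(self.values):
            raise ValueError("lags and values must have equal length")
        steps = np.diff(self.lags)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("lag grid must be uniform")

    def value_at(self, lag: float) -> float:
        return float(np.interp(lag, self.lags, self.values))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"lag_ms": self.lags, "value": self.values}).to_csv(
            path, index=False
        )


@dataclass
class KernelParams:
    """The six scalar parameters extracted from one kernel.

    Parameters that cannot be measured (e.g. no positive peak) are NaN
    and ``defined`` is False.
    """

    amplitude: float
    ttp: float
    half_width: float
    decay: float
    return_to_baseline: float
    spike_rate: float
    defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "amplitude": self.amplitude,
            "ttp_ms": self.ttp,
            "half_width_ms": self.half_width,
            "decay_ms": self.decay,
            "return_to_baseline_ms": self.return_to_baseline,
            "spike_rate_hz": self.spike_rate,
        }


def _analysis_onsets(trace: StimulusTrace) -> tuple[np.ndarray, np.ndarray]:
    """Frame-onset milliseconds and signs of the final analysed period."""
    start = trace.analysis_start
    onsets = np.floor(trace.frame_times[start:] * 1000.0).astype(int)
    signs = trace.sign_sequence[start:].astype(float)
    return onsets, signs


def cross_correlate(
    trace: StimulusTrace,
    spike_vector: np.ndarray,
    lag_range: tuple[int, int] = DEFAULT_LAG_RANGE,
) -> np.ndarray:
    """Raw stimulus–response cross-correlation over a lag grid.

    For each lag τ the estimate is ``(1/M) Σ_m s_m y(t_m + τ)`` over the
    M impulses of the final m-sequence period, with s_m the ±1 impulse
    sign, t_m its onset millisecond and y the 1 ms-binned spike train.
    The cross-correlation uses the m-sequence polarity only — any
    constant-flow component of the stimulus is excluded from x.  Products
    that fall outside the spike vector are dropped.
    """
    y = np.asarray(spike_vector, dtype=float)
    onsets, signs = _analysis_onsets(trace)
    if len(y) <= onsets[-1]:
        raise ValueError(
            f"spike vector of length {len(y)} does not cover the analysed "
            f"impulses (last onset at {onsets[-1]} ms)"
        )
    lags = np.arange(lag_range[0], lag_range[1] + 1)
    pad_lo = max(0, -(onsets[0] + lags[0]))
    pad_hi = max(0, onsets[-1] + lags[-1] - (len(y) - 1))
    y_pad = np.pad(y, (pad_lo, pad_hi))
    idx = onsets[:, None] + lags[None, :] + pad_lo
    return signs @ y_pad[idx] / len(onsets)


def mean_smooth(
    correlations: np.ndarray | list[np.ndarray],
    window_ms: float = 5.0,
    lag_range: tuple[int, int] = DEFAULT_LAG_RANGE,
    window_is_sd: bool = True,
) -> ImpulseResponse:
    """Average per-trial correlations and Gaussian-smooth the mean.

    The ``window_ms`` Gaussian window is interpreted as the filter SD
    (truncated at ±3 SD); set ``window_is_sd=False`` to interpret it as
    the full width at half maximum instead.  ``window_ms = 0`` skips
    smoothing.
    """
    arr = np.atleast_2d(np.asarray(correlations, dtype=float))
    if arr.size == 0:
        raise ValueError("no correlation series given")
    mean = arr.mean(axis=0)
    if window_ms > 0:
        sigma = window_ms if window_is_sd else window_ms / 2.3548
        mean = gaussian_filter1d(mean, sigma, truncate=3.0, mode="nearest")
    lags = np.arange(lag_range[0], lag_range[1] + 1)
    if len(lags) != len(mean):
        raise ValueError("correlation length does not match lag range")
    return ImpulseResponse(
        lags=lags, values=mean, smoothing_ms=window_ms, n_trials=len(arr)
    )


def _cross_down(lags: np.ndarray, values: np.ndarray, start_idx: int,
                level: float) -> float:
    """First lag at/after start_idx where values fall to <= level
    (linear interpolation); NaN if never."""
    for i in range(start_idx, len(values)):
        if values[i] <= level:
            if i == start_idx or values[i - 1] <= level:
                return float(lags[i])
            frac = (values[i - 1] - level) / (values[i - 1] - values[i])
            return float(lags[i - 1] + frac * (lags[i] - lags[i - 1]))
    return float("nan")


def _cross_up(lags: np.ndarray, values: np.ndarray, end_idx: int,
              level: float) -> float:
    """Last lag at/before end_idx where values rise through level, scanning
    backwards (linear interpolation); NaN if never below level."""
    for i in range(end_idx, -1, -1):
        if values[i] <= level:
            if i == end_idx:
                return float(lags[i])
            frac = (level - values[i]) / (values[i + 1] - values[i])
            return float(lags[i] + frac * (lags[i + 1] - lags[i]))
    return float(lags[0])


def extract_params(
    impulse_response: ImpulseResponse,
    raw_correlations: np.ndarray | list[np.ndarray] | None = None,
    broad_window_ms: float = 25.0,
    spike_rate: float = float("nan"),
    baseline_lags: tuple[int, int] = BASELINE_LAGS,
) -> KernelParams:
    """Extract the six kernel parameters.

    Amplitude and TTP come from the maximum of the smoothed kernel over
    nonnegative lags (ties broken by the earliest lag).  Half-width and
    decay are measured on the same series with linear interpolation of the
    level crossings.  Return to baseline is measured on a separately
    ``broad_window_ms``-smoothed version of the raw mean correlation: the
    first lag after the TTP at which it re-enters mean ± 2 SD of the
    baseline region (negative lags).  ``spike_rate`` (Hz, measured over
    the analysed impulses) is carried through; compute it with
    :func:`mseqrc.spikes.mean_rate`.
    """
    ir = impulse_response
    lags, values = ir.lags, ir.values
    pos = lags >= 0
    if not np.any(values[pos] > 0):
        return KernelParams(*([float("nan")] * 5), spike_rate, defined=False)
    pos_idx = np.nonzero(pos)[0]
    peak_rel = int(np.argmax(values[pos]))       # argmax → earliest tie
    peak_idx = int(pos_idx[peak_rel])
    amplitude = float(values[peak_idx])
    ttp = float(lags[peak_idx])

    half = amplitude / 2.0
    left = _cross_up(lags, values, peak_idx, half)
    right = _cross_down(lags, values, peak_idx, half)
    half_width = (
        right - left if np.isfinite(left) and np.isfinite(right)
        else float("nan")
    )

    decay_lag = _cross_down(lags, values, peak_idx, amplitude / np.e)
    decay = decay_lag - ttp if np.isfinite(decay_lag) else float("nan")

    rtb = float("nan")
    if raw_correlations is not None:
        broad = mean_smooth(
            raw_correlations, window_ms=broad_window_ms,
            lag_range=(int(lags[0]), int(lags[-1])),
        )
        b = broad.values
        base = (lags >= baseline_lags[0]) & (lags <= baseline_lags[1])
        mu = float(b[base].mean())
        sd = max(float(b[base].std()), BASELINE_SD_FLOOR * amplitude)
        lo, hi = mu - 2 * sd, mu + 2 * sd
        for i in range(peak_idx + 1, len(b)):
            if lo <= b[i] <= hi:
                if b[i - 1] > hi:
                    frac = (b[i - 1] - hi) / (b[i - 1] - b[i])
                    rtb = float(lags[i - 1] + frac) - ttp
                elif b[i - 1] < lo:
                    frac = (lo - b[i - 1]) / (b[i] - b[i - 1])
                    rtb = float(lags[i - 1] + frac) - ttp
                else:
                    rtb = float(lags[i]) - ttp
                break

    return KernelParams(
        amplitude=amplitude,
        ttp=ttp,
        half_width=half_width,
        decay=decay,
        return_to_baseline=rtb,
        spike_rate=spike_rate,
    )


def shuffled_kernel(
    trace: StimulusTrace,
    train: SpikeTrain,
    rng: np.random.Generator,
    window_ms: float = 5.0,
    lag_range: tuple[int, int] = DEFAULT_LAG_RANGE,
) -> ImpulseResponse:
    """Kernel from a spike train with uniformly redrawn spike times.

    The K spikes of the trial are replaced by K random time points within
    the trial duration (count preserved), then the kernel is estimated as
    usual.  Shuffling destroys the stimulus locking, so the resulting
    kernel is flat up to estimation noise — the negative control.
    """
    k = train.n_spikes
    times = np.sort(rng.uniform(0.0, train.duration, size=k))
    shuffled = SpikeTrain(
        times=times, duration=train.duration,
        neuron_id=train.neuron_id, condition=train.condition,
        trial=train.trial,
    )
    corr = cross_correlate(trace, bin_spikes(shuffled), lag_range)
    return mean_smooth([corr], window_ms=window_ms, lag_range=lag_range)
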