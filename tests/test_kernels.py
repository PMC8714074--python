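"""Cross-correlation kernel estimator and parameter extraction.

The estimator oracle: for a noiseless linear response driven by a
circularly extended m-sequence, the delta-like autocorrelation gives the
closed form  estimate(τ) = h(τ)·(1 + 1/N) − Σh/N  exactly.
"""

import numpy as np
import pytest

from mseqrc.kernels import (
    ImpulseResponse,
    cross_correlate,
    extract_params,
    mean_smooth,
    shuffled_kernel,
)
from mseqrc.msequence import extend_circular, random_msequence
from mseqrc.spikes import SpikeTrain, bin_spikes
from mseqrc.starfield import FlowCondition, ScreenGeometry, compose_trace

# 1 frame per ms: the frame grid coincides with the analysis grid, so the
# closed form holds sample-exactly.
MS_SCREEN = ScreenGeometry(frame_rate=1000.0)


def _oracle_setup(order, h, rng, warm=50):
    """Trace + noiseless periodic linear response for one m-sequence."""
    seq = random_msequence(order, rng)
    v = seq.values.astype(float)
    n = len(v)
    total = n + warm
    trace = compose_trace(
        extend_circular(seq, total),
        FlowCondition(0.33, 0, 0, "roll33"),
        screen=MS_SCREEN,
        period=n,
    )
    # circular convolution of one period
    y_period = np.array([
        sum(h[k] * v[(t - k) % n] for k in range(len(h)))
        for t in range(n)
    ])
    # y aligned so the analysis window (final period) sees phase 0, and
    # extended N-1 ms past the last impulse for the full lag range
    t_grid = np.arange(total + n)
    y = y_period[(t_grid - (total - n)) % n]
    return trace, y


class TestOracleEquivalence:
    @pytest.mark.parametrize("order", range(3, 9))
    def test_closed_form_on_noiseless_linear_response(self, order, rng):
        h = np.array([2.0, 1.0, 0.5, 0.25])
        n = 2**order - 1
        trace, y = _oracle_setup(order, h, rng)
        est = cross_correlate(trace, y, (0, n - 1))
        expected = np.full(n, -h.sum() / n)
        expected[: len(h)] += h * (1 + 1 / n)
        assert np.max(np.abs(est - expected)) <= 1e-9

    def test_printed_values_for_short_kernel(self, rng):
        h = np.array([2.0, 1.0, 0.5])
        trace, y = _oracle_setup(8, h, rng)
        est = cross_correlate(trace, y, (0, 254))
        assert est[0] == pytest.approx((2 * 256 - 3.5) / 255, abs=1e-9)
        assert est[100] == pytest.approx(-3.5 / 255, abs=1e-9)

    def test_pure_delay_peaks_at_delay_lag(self, rng):
        delay = 13
        trace, y = _oracle_setup(8, np.eye(1, delay + 1, delay)[0], rng)
        est = cross_correlate(trace, y, (0, 254))
        assert np.argmax(est) == delay
        assert est[delay] == pytest.approx(1.0, abs=1e-9)

    def test_constant_response_gives_flat_series(self, rng):
        trace, _ = _oracle_setup(8, np.array([1.0]), rng)
        y = np.full(700, 3.0)
        est = cross_correlate(trace, y, (0, 200))
        assert np.allclose(est, 3.0 / 255, atol=1e-12)

    def test_linear_in_response(self, rng):
        h1 = np.array([1.0, 0.3])
        h2 = np.array([0.2, 0.9, 0.4])
        trace, y1 = _oracle_setup(8, h1, np.random.default_rng(0))
        _, y2 = _oracle_setup(8, h2, np.random.default_rng(0))
        lhs = cross_correlate(trace, 2.0 * y1 - 0.5 * y2, (0, 100))
        rhs = 2.0 * cross_correlate(trace, y1, (0, 100)) - 0.5 * \
            cross_correlate(trace, y2, (0, 100))
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_short_spike_vector_rejected(self, rng):
        trace, y = _oracle_setup(8, np.array([1.0]), rng)
        with pytest.raises(ValueError, match="cover"):
            cross_correlate(trace, y[:100], (0, 10))


class TestMeanSmooth:
    def test_zero_window_is_identity(self):
        x = np.random.default_rng(0).normal(size=801)
        ir = mean_smooth([x], window_ms=0)
        assert np.array_equal(ir.values, x)

    def test_two_identical_trials_equal_one(self):
        x = np.random.default_rng(1).normal(size=801)
        one = mean_smooth([x], window_ms=5)
        two = mean_smooth([x, x], window_ms=5)
        assert np.allclose(one.values, two.values)
        assert two.n_trials == 2

    def test_gaussian_filter_preserves_area(self):
        x = np.zeros(801)
        x[400] = 1.0
        ir = mean_smooth([x], window_ms=5)
        assert ir.values.sum() == pytest.approx(1.0, abs=1e-6)
        assert ir.values.max() < 0.1  # spread out

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_smooth([], window_ms=5)


def _piecewise_kernel():
    """0 at 0 ms, 1 at 20 ms, back to 0 at 60 ms, flat after (closed-form
    parameters: amplitude 1, TTP 20, half-width 30, decay 40(1-1/e))."""
    lags = np.arange(-200, 601)
    values = np.zeros(lags.shape, dtype=float)
    up = (lags >= 0) & (lags <= 20)
    down = (lags > 20) & (lags <= 60)
    values[up] = lags[up] / 20.0
    values[down] = 1.0 - (lags[down] - 20) / 40.0
    return ImpulseResponse(lags=lags, values=values)


class TestExtractParams:
    def test_closed_form_piecewise_kernel(self):
        ir = _piecewise_kernel()
        p = extract_params(ir, raw_correlations=[ir.values],
                           broad_window_ms=0.0, spike_rate=42.0)
        assert p.amplitude == pytest.approx(1.0)
        assert p.ttp == pytest.approx(20.0)
        assert p.half_width == pytest.approx(30.0, abs=0.01)
        assert p.decay == pytest.approx(40 * (1 - 1 / np.e), abs=0.01)
        assert p.spike_rate == 42.0

    def test_return_to_baseline_touches_band_at_60ms(self):
        ir = _piecewise_kernel()
        p = extract_params(ir, raw_correlations=[ir.values],
                           broad_window_ms=0.0)
        assert p.return_to_baseline == pytest.approx(40.0, abs=0.01)

    def test_no_positive_peak_flagged_undefined(self):
        lags = np.arange(-200, 601)
        p = extract_params(ImpulseResponse(lags=lags,
                                           values=np.full(801, -0.5)))
        assert not p.defined
        assert np.isnan(p.amplitude) and np.isnan(p.ttp)

    def test_tie_at_maximum_takes_earliest_lag(self):
        lags = np.arange(-200, 601)
        values = np.zeros(801)
        values[lags == 10] = 1.0
        values[lags == 30] = 1.0
        p = extract_params(ImpulseResponse(lags=lags, values=values))
        assert p.ttp == 10.0

    def test_negative_lag_peak_ignored(self):
        lags = np.arange(-200, 601)
        values = np.zeros(801)
        values[lags == -50] = 5.0
        values[lags == 15] = 1.0
        p = extract_params(ImpulseResponse(lags=lags, values=values))
        assert p.ttp == 15.0 and p.amplitude == 1.0


class TestShuffledKernel:
    def test_deterministic_under_fixed_seed(self, roll33_dataset):
        trial = roll33_dataset.trials[("n00", "roll33")][0]
        a = shuffled_kernel(trial.trace, trial.train,
                            np.random.default_rng(5))
        b = shuffled_kernel(trial.trace, trial.train,
                            np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)

    def test_shuffled_kernels_are_flat(self, roll33_dataset):
        """Shuffling spike times destroys the kernel (the Fig-style
        negative control): shuffled estimates stay far below the real
        kernel amplitude, and their average is within the baseline noise
        band."""
        trial = roll33_dataset.trials[("n01", "roll33")][0]
        real = mean_smooth(
            [cross_correlate(trial.trace, bin_spikes(trial.train))]
        )
        neg = real.lags < -10
        amp = real.values[real.lags >= 0].max() - real.values[neg].mean()
        rng = np.random.default_rng(11)
        devs, all_values = [], []
        for _ in range(20):
            ir = shuffled_kernel(trial.trace, trial.train, rng)
            centered = ir.values - ir.values[neg].mean()
            devs.append(np.abs(centered).max())
            all_values.append(ir.values)
        assert max(devs) < 0.5 * amp
        mean_ir = np.mean(all_values, axis=0)
        mean_centered = mean_ir - mean_ir[neg].mean()
        base_sd = mean_ir[neg].std()
        assert np.abs(mean_centered).max() <= 4 * base_sd

    def test_zero_spikes_give_zero_kernel(self, roll33_dataset):
        trial = roll33_dataset.trials[("n00", "roll33")][0]
        empty = SpikeTrain(times=np.array([]),
                           duration=trial.train.duration)
        ir = shuffled_kernel(trial.trace, empty, np.random.default_rng(0))
        assert np.allclose(ir.values, 0.0)
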