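"""Generator signal, static nonlinearity, prediction and LOO validation."""

import numpy as np
import pytest

from mseqrc.kernels import ImpulseResponse
from mseqrc.spikes import SpikeTrain
from mseqrc.starfield import FlowCondition, StimulusTrace
from mseqrc.synthetic import GroundTruthLN, ln_rate, make_kernel
from mseqrc.validation import (
    _pearson,
    _training_trials,
    fit_nonlinearity,
    generator_signal,
    loo_correlations,
    predict_response,
    reference_response,
    shuffle_control,
)


def _single_impulse_trace(duration_s=0.5):
    """One +1 impulse at t = 0; the generator signal is a kernel copy."""
    return StimulusTrace(
        sign_sequence=np.array([1], dtype=np.int8),
        roll_increment=np.array([0.33]),
        lift_increment=np.array([0.0]),
        frame_times=np.array([0.0]),
        condition=FlowCondition(0.33, 0, 0, "roll33"),
        frame_log=np.array([True]),
        frame_rate=1.0 / duration_s,
        period=1,
    )


class TestGeneratorSignal:
    def test_zero_kernel_gives_zero_signal(self, roll33_dataset):
        trace = roll33_dataset.trials[("n00", "roll33")][0].trace
        g = generator_signal(trace, np.zeros(300))
        assert np.allclose(g, 0.0)

    def test_unit_impulse_kernel_reproduces_impulse_train(self, roll33_dataset):
        trace = roll33_dataset.trials[("n00", "roll33")][0].trace
        g = generator_signal(trace, np.array([1.0]))
        onsets = np.floor(trace.frame_times * 1000).astype(int)
        expected = np.zeros(len(g))
        np.add.at(expected, onsets, trace.sign_sequence.astype(float))
        assert np.array_equal(g, expected)

    def test_single_impulse_copies_kernel(self):
        h = make_kernel(1.0, 18.0, 12.0, 300.0)
        g = generator_signal(_single_impulse_trace(), h)
        assert np.allclose(g[:300], h)
        assert np.allclose(g[300:], 0.0)

    def test_impulse_response_input_uses_causal_lags_only(self):
        lags = np.arange(-200, 601)
        values = np.zeros(801)
        values[lags == -50] = 7.0            # acausal content is ignored
        values[lags == 10] = 1.0
        ir = ImpulseResponse(lags=lags, values=values)
        g = generator_signal(_single_impulse_trace(), ir)
        assert g[10] == 1.0
        assert np.sum(g != 0) == 1


def test_fitted_kernels_have_no_dc_bias(roll33_dataset):
    """Stimulus-independent (shuffled) spikes yield kernels whose causal
    sum is centred on zero: the analytic m-sequence DC offset (mean rate
    times the +1 sign excess) is removed at fitting time."""
    from mseqrc.validation import _fit_neuron

    rng = np.random.default_rng(17)
    sums = []
    for _ in range(15):
        kernel, _ = _fit_neuron(roll33_dataset, "n03", 20, 5.0,
                                shuffle_rng=rng)
        sums.append(kernel.values[kernel.lags >= 0].sum())
    sums = np.asarray(sums)
    sem = sums.std(ddof=1) / np.sqrt(len(sums))
    assert abs(sums.mean()) < 4 * sem + 1e-3


class TestNonlinearity:
    def test_constant_generator_collapses_to_one_bin(self):
        g = np.zeros(5000)
        y = np.zeros(5000)
        y[::10] = 1  # 100 Hz
        with pytest.warns(UserWarning, match="merged"):
            nl = fit_nonlinearity(g, y, n_bins=20)
        assert nl.n_bins == 1
        assert nl.mean_rate[0] == pytest.approx(100.0)

    def test_two_level_generator_recovers_both_rates(self, rng):
        g = np.tile([-1.0, 1.0], 20_000)
        p = np.where(g > 0, 0.1, 0.0)
        y = (rng.random(len(g)) < p).astype(float)
        nl = fit_nonlinearity(g, y, n_bins=2)
        assert nl(np.array([-1.0]))[0] == pytest.approx(0.0, abs=1.0)
        assert nl(np.array([1.0]))[0] == pytest.approx(100.0, rel=0.1)

    def test_monotone_ground_truth_gives_monotone_bins(self, rng):
        g = rng.normal(size=50_000)
        rate = 200.0 / (1 + np.exp(-2 * g))       # Hz, sigmoidal
        y = (rng.random(len(g)) < rate * 1e-3).astype(float)
        nl = fit_nonlinearity(g, y, n_bins=10)
        assert np.all(np.diff(nl.mean_rate) > -10.0)  # monotone within noise
        assert nl.mean_rate[-1] > nl.mean_rate[0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_nonlinearity(np.zeros(10), np.zeros(11))

    def test_out_of_range_inputs_clamp_to_edge_bins(self, rng):
        g = rng.normal(size=10_000)
        y = (rng.random(len(g)) < 0.05).astype(float)
        nl = fit_nonlinearity(g, y, n_bins=5)
        assert nl(np.array([100.0]))[0] == nl.mean_rate[-1]
        assert nl(np.array([-100.0]))[0] == nl.mean_rate[0]


class TestPrediction:
    def test_true_ln_model_predicts_its_own_rate(self, roll33_dataset):
        """Self-consistency: with the true kernel and a nonlinearity fitted
        on the noiseless rate, the prediction matches that rate."""
        ds = roll33_dataset
        model = ds.neurons["n00"]
        trial = ds.trials[("n00", "roll33")][0]
        rate = ln_rate(trial.trace, model)
        g = generator_signal(trial.trace, model.kernel * model.roll_gain)
        nl = fit_nonlinearity(g, rate[: len(g)] * 1e-3, n_bins=50)
        pred = predict_response(trial.trace,
                                model.kernel * model.roll_gain,
                                nl, smooth_ms=0)
        r = np.corrcoef(pred, rate[: len(pred)])[0, 1]
        assert r > 0.99

    def test_flat_nonlinearity_gives_constant_prediction(self, roll33_dataset):
        trace = roll33_dataset.trials[("n00", "roll33")][0].trace
        g = np.linspace(-1, 1, 1000)
        nl = fit_nonlinearity(g, np.full(1000, 0.05), n_bins=4)
        pred = predict_response(trace, make_kernel(1, 18, 12, 300), nl,
                                smooth_ms=0)
        assert np.allclose(pred, 50.0)


class TestReferenceResponse:
    def test_single_empty_train_gives_zeros(self):
        ref = reference_response(
            [SpikeTrain(times=np.array([]), duration=1.0)]
        )
        assert np.allclose(ref, 0.0)

    def test_additive_in_trains(self, roll33_dataset):
        trains = [
            roll33_dataset.trials[(nid, "roll33")][0].train
            for nid in ["n00", "n01", "n02", "n03"]
        ]
        combined = reference_response(trains)
        split = reference_response(trains[:2]) + reference_response(trains[2:])
        assert np.allclose(combined, split)

    def test_constant_rate_trains_give_nearly_constant_output(self, rng):
        trains = [
            SpikeTrain(
                times=np.sort(rng.uniform(0, 10, 1000)), duration=10.0
            )
            for _ in range(5)
        ]
        ref = reference_response(trains)
        inner = ref[200:-200]
        assert inner.std() / inner.mean() < 0.2


def test_pearson_affine_invariance(rng):
    for _ in range(20):
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        r = _pearson(a, b)
        r2 = _pearson(3.2 * a + 7.0, 0.5 * b - 2.0)
        assert r2 == pytest.approx(r, abs=1e-12)
        assert -1.0 <= r <= 1.0


class TestLeaveOneOut:
    def test_median_correlation_on_synthetic_dataset(self, roll33_dataset):
        res = loo_correlations(roll33_dataset)
        assert res.median > 0.5
        assert all(-1 <= r <= 1 for r in res.per_neuron.values())
        assert res.range[0] <= res.median <= res.range[1]

    def test_requires_two_neurons(self, roll33_dataset):
        solo = roll33_dataset.subset(neuron_ids=["n00"])
        with pytest.raises(ValueError, match="2 neurons"):
            loo_correlations(solo)

    def test_shared_trial_held_out_of_training(self, roll33_dataset):
        for nid in roll33_dataset.neuron_ids:
            training = _training_trials(roll33_dataset, nid)
            assert len(training) == 7           # 8 trials minus shared
            assert not any(t.shared for t in training)


class TestShuffleControl:
    def test_deterministic_under_fixed_seed(self, tiny_dataset):
        a = shuffle_control(tiny_dataset, np.random.default_rng(3),
                            n_shuffles=2)
        b = shuffle_control(tiny_dataset, np.random.default_rng(3),
                            n_shuffles=2)
        assert a == b

    def test_single_shuffle_stays_bounded(self, tiny_dataset):
        per, med = shuffle_control(tiny_dataset, np.random.default_rng(0),
                                   n_shuffles=1)
        assert all(-1 <= r <= 1 for r in per.values())
        assert -1 <= med <= 1
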