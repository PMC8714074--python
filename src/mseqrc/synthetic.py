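"""Ground-truth linear–nonlinear (LN) spiking neurons under the protocol.

Every downstream stage of the pipeline (QC, kernel estimation, LN
validation, statistics) is exercised against data from this generator, so
there is no dependency on external recordings.

The generative model is an LN cascade with Bernoulli spiking: a causal
roll kernel (log-normal-shaped lag profile with specified peak time and
full width at half maximum) filters the ±1 impulse polarity sequence; a
rectifying-saturating static nonlinearity maps the resulting drive to a
firing rate; spikes are drawn independently per 1 ms bin (at most one
spike per bin, an implicit 1 ms refractoriness).

The default protocol mirrors the recording sessions it emulates: 8th-order
m-sequences shown at 165 Hz, extended to 400 impulses of which the final
255 are analysed, 8 trials per condition, 12 neurons, nine conditions
(three impulse sizes; constant roll at ±25/±50 deg/s; constant lift at
±50 cm/s), and one shared m-sequence (the second Roll 33 trial) common to
every neuron for cross-neuron validation.

Drive bookkeeping: the kernel filters the ±1 impulse signs scaled by
``roll_gain`` (drive per impulse at the reference 0.33 deg size), not
physical degrees; impulse-size conditions scale ``roll_gain``
proportionally, and a constant-roll condition contributes its per-frame
increment expressed in units of the base impulse.  Constant lift enters
through ``lift_gain`` (drive per cm of per-frame translation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from mseqrc.msequence import MSequence, extend_circular, random_msequence
from mseqrc.spikes import SpikeTrain
from mseqrc.starfield import (
    FlowCondition,
    ScreenGeometry,
    StimulusTrace,
    compose_trace,
    default_conditions,
)

__all__ = [
    "GroundTruthLN",
    "Trial",
    "SyntheticDataset",
    "SimConfig",
    "make_kernel",
    "ln_rate",
    "draw_spikes",
    "simulate_experiment",
]

#: Reference impulse size (deg): roll_gain is the drive per ±1 impulse at
#: this size, and other impulse sizes scale the drive proportionally.
REFERENCE_IMPULSE = 0.33


@dataclass
class GroundTruthLN:
    """Parameters of one ground-truth LN neuron.

    ``kernel`` is the causal roll impulse response on a 1 ms lag grid
    (lag 0 = impulse onset).  ``r0``/``slope``/``max_rate`` define the
    rectifying-saturating nonlinearity
    ``rate = clip(r0 + slope * drive, 0, max_rate)``.
    """

    kernel: np.ndarray
    ttp: float                       # ms, peak lag of the kernel
    roll_gain: float                 # drive per ±1 impulse (reference size)
    lift_gain: float                 # drive per cm of lift increment
    r0: float                        # baseline rate, Hz
    slope: float = 1.0               # Hz per drive unit
    max_rate: float = 300.0          # saturation, Hz
    side: str = "left"

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if not 0 <= self.r0 < self.max_rate:
            raise ValueError("need 0 <= r0 < max_rate")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class Trial:
    """One presented m-sequence trial with its simulated response."""

    trace: StimulusTrace
    train: SpikeTrain
    shared: bool = False


@dataclass
class SyntheticDataset:
    """All trials of one simulated experiment, keyed by neuron and condition."""

    neurons: dict[str, GroundTruthLN]
    conditions: list[FlowCondition]
    trials: dict[tuple[str, str], list[Trial]]
    shared_condition: str = "roll33"
    shared_trial_index: int = 1
    master_seed: int = 0

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.neurons)

    @property
    def condition_labels(self) -> list[str]:
        return [c.label for c in self.conditions]

    def condition(self, label: str) -> FlowCondition:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)

    def subset(
        self,
        neuron_ids: list[str] | None = None,
        drop_conditions: set[tuple[str, str]] | None = None,
    ) -> "SyntheticDataset":
        """A filtered copy keeping only the given neurons/conditions."""
        if neuron_ids is None:
            neuron_ids = self.neuron_ids
        drop_conditions = drop_conditions or set()
        keep = {
            key: trials
            for key, trials in self.trials.items()
            if key[0] in neuron_ids and key not in drop_conditions
        }
        return replace(
            self,
            neurons={n: self.neurons[n] for n in neuron_ids},
            trials=keep,
        )


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment."""

    n_neurons: int = 12
    n_trials: int = 8
    conditions: list[FlowCondition] = field(default_factory=default_conditions)
    order: int = 8
    total_length: int = 400
    shared_condition: str = "roll33"
    shared_trial_index: int = 1
    drop_prob: float = 0.0
    # ground-truth kernel shape (study-median timing)
    kernel_ttp: float = 18.0         # ms
    kernel_half_width: float = 12.0  # ms
    kernel_length_ms: float = 300.0
    # nonlinearity / gains (paper-scale firing rates)
    r0_range: tuple[float, float] = (20.0, 40.0)
    max_rate: float = 300.0
    roll_gain: float = 80.0
    lift_gain: float = 200.0
    gain_jitter_sd: float = 0.1      # lognormal sigma across neurons
    fraction_right: float = 0.0
    post_window_s: float = 0.7       # simulated time past the last frame
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be nonempty")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("conditions must have unique labels")
        if self.shared_condition not in labels:
            raise ValueError(
                f"shared_condition {self.shared_condition!r} not in conditions"
            )
        if not 0 <= self.shared_trial_index < self.n_trials:
            raise ValueError("shared_trial_index outside trial range")
        if not 0 <= self.drop_prob < 1:
            raise ValueError("drop_prob must lie in [0, 1)")


def make_kernel(
    amplitude: float, ttp: float, half_width: float, length_ms: float
) -> np.ndarray:
    """Causal log-normal lag profile with exact peak and half-maximum width.

    ``h(t) = amplitude * exp(-ln(t/ttp)^2 / (2 sigma^2))`` peaks at
    ``t = ttp`` with value ``amplitude``; the width at half maximum is
    ``ttp * 2 sinh(c)`` with ``c = sigma * sqrt(2 ln 2)``, so sigma is set
    in closed form from the requested half-width.  Returned on a 1 ms lag
    grid starting at lag 0 (where it is exactly 0: causal).
    """
    if not 0 < ttp < length_ms:
        raise ValueError("need 0 < ttp < length_ms")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    c = np.arcsinh(half_width / (2.0 * ttp))
    sigma = c / np.sqrt(2.0 * np.log(2.0))
    t = np.arange(int(round(length_ms)), dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    h[pos] = amplitude * np.exp(
        -np.log(t[pos] / ttp) ** 2 / (2.0 * sigma**2)
    )
    return h


def _frame_onset_ms(trace: StimulusTrace) -> np.ndarray:
    return np.floor(trace.frame_times * 1000.0).astype(int)


def ln_rate(
    trace: StimulusTrace, model: GroundTruthLN,
    post_window_s: float = 0.7,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of the LN model on a 1 ms grid.

    Impulses are placed at frame-onset milliseconds.  The roll input per
    frame is the ±1 sign plus the constant-roll increment in units of the
    base impulse; the lift input is the per-frame translation in cm.  For
    right-side neurons the roll input is sign-flipped (their preferred
    roll is the mirror direction).  Frames flagged dropped contribute no
    drive.  The grid extends ``post_window_s`` past the last frame so the
    response tail of the final impulses is simulated.
    """
    n_ms = int(np.ceil((trace.duration + post_window_s) * 1000.0))
    onsets = _frame_onset_ms(trace)
    cond = trace.condition
    if cond.base_impulse > 0:
        x_roll = trace.roll_increment / cond.base_impulse
    else:
        x_roll = np.zeros(trace.n_frames)
    if model.side == "right":
        x_roll = -x_roll
    presented = trace.frame_log.astype(float)
    roll_imp = np.zeros(n_ms)
    np.add.at(roll_imp, onsets, x_roll * presented)
    lift_imp = np.zeros(n_ms)
    np.add.at(lift_imp, onsets, trace.lift_increment * presented)
    u = model.roll_gain * np.convolve(roll_imp, model.kernel)[:n_ms]
    u += model.lift_gain * np.convolve(lift_imp, model.kernel)[:n_ms]
    return np.clip(model.r0 + model.slope * u, 0.0, model.max_rate)


def draw_spikes(
    rate: np.ndarray, rng: np.random.Generator, **train_kwargs
) -> SpikeTrain:
    """Bernoulli spiking: at most one spike per 1 ms bin.

    The per-bin spike probability is ``min(rate * 1 ms, 1)``; spike times
    are placed at bin centres.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be nonnegative")
    p = np.minimum(rate * 1e-3, 1.0)
    hits = rng.random(len(rate)) < p
    times = (np.nonzero(hits)[0] + 0.5) / 1000.0
    return SpikeTrain(times=times, duration=len(rate) / 1000.0, **train_kwargs)


def _make_neuron(
    config: SimConfig, rng: np.random.Generator, side: str
) -> GroundTruthLN:
    kernel = make_kernel(
        1.0, config.kernel_ttp, config.kernel_half_width,
        config.kernel_length_ms,
    )
    gain_scale = float(
        np.exp(rng.normal(0.0, config.gain_jitter_sd))
    )
    return GroundTruthLN(
        kernel=kernel,
        ttp=config.kernel_ttp,
        roll_gain=config.roll_gain * gain_scale,
        lift_gain=config.lift_gain * gain_scale,
        r0=float(rng.uniform(*config.r0_range)),
        slope=1.0,
        max_rate=config.max_rate,
        side=side,
    )


def simulate_experiment(
    config: SimConfig, rng: np.random.Generator | int
) -> SyntheticDataset:
    """Simulate the full experiment defined by ``config``.

    Every trial uses a unique random m-sequence except the shared trial
    (by default the second Roll 33 trial), which uses one common
    m-sequence across all neurons.  Reproducible: the same seed yields an
    identical dataset.
    """
    config.validate()
    if isinstance(rng, (int, np.integer)):
        master_seed = int(rng)
    else:
        master_seed = int(rng.integers(2**31))
    ss = np.random.SeedSequence(master_seed)
    shared_ss, neurons_ss = ss.spawn(2)
    shared_mseq = random_msequence(
        config.order, np.random.default_rng(shared_ss), label="shared"
    )
    neuron_seeds = neurons_ss.spawn(config.n_neurons)
    n_right = int(round(config.fraction_right * config.n_neurons))
    neurons: dict[str, GroundTruthLN] = {}
    trials: dict[tuple[str, str], list[Trial]] = {}
    for i, nss in enumerate(neuron_seeds):
        nid = f"n{i:02d}"
        param_ss, trial_ss = nss.spawn(2)
        side = "right" if i < n_right else "left"
        model = _make_neuron(
            config, np.random.default_rng(param_ss), side
        )
        neurons[nid] = model
        cond_seeds = trial_ss.spawn(len(config.conditions))
        for cond, css in zip(config.conditions, cond_seeds):
            # impulse-size conditions scale the roll drive proportionally
            cond_model = replace(
                model,
                roll_gain=model.roll_gain
                * cond.base_impulse / REFERENCE_IMPULSE,
            )
            trial_list: list[Trial] = []
            for t, tss in enumerate(css.spawn(config.n_trials)):
                trng = np.random.default_rng(tss)
                shared = (
                    cond.label == config.shared_condition
                    and t == config.shared_trial_index
                )
                mseq = (
                    shared_mseq
                    if shared
                    else random_msequence(
                        config.order, trng, label=f"{nid}/{cond.label}/{t}"
                    )
                )
                seq = extend_circular(mseq, config.total_length)
                trace = compose_trace(seq, cond, config.screen,
                                      period=mseq.period)
                if config.drop_prob > 0:
                    dropped = trng.random(trace.n_frames) < config.drop_prob
                    trace.frame_log = ~dropped
                rate = ln_rate(trace, cond_model, config.post_window_s)
                train = draw_spikes(
                    rate, trng, neuron_id=nid, condition=cond.label, trial=t
                )
                trial_list.append(Trial(trace=trace, train=train,
                                        shared=shared))
            trials[(nid, cond.label)] = trial_list
    return SyntheticDataset(
        neurons=neurons,
        conditions=list(config.conditions),
        trials=trials,
        shared_condition=config.shared_condition,
        shared_trial_index=config.shared_trial_index,
        master_seed=master_seed,
    )


def export_dataset(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Write one spike CSV and one trace CSV per trial plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "master_seed": dataset.master_seed,
        "shared_condition": dataset.shared_condition,
        "shared_trial_index": dataset.shared_trial_index,
        "neurons": {
            nid: {"side": m.side} for nid, m in dataset.neurons.items()
        },
        "conditions": [
            {
                "label": c.label,
                "base_impulse": c.base_impulse,
                "constant_roll": c.constant_roll,
                "constant_lift": c.constant_lift,
            }
            for c in dataset.conditions
        ],
        "trials": [],
    }
    for (nid, cond), trial_list in dataset.trials.items():
        for t, trial in enumerate(trial_list):
            stem = f"{nid}_{cond}_{t:02d}"
            trial.trace.to_csv(directory / f"{stem}_trace.csv")
            np.savetxt(
                directory / f"{stem}_spikes.csv",
                trial.train.times,
                fmt="%.6f",
                header="spike_time_s",
                comments="",
            )
            manifest["trials"].append(
                {
                    "neuron_id": nid,
                    "condition": cond,
                    "trial": t,
                    "shared": trial.shared,
                    "duration_s": trial.train.duration,
                    "period": trial.trace.period,
                }
            )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
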