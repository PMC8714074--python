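"""Spike trains, windowed rates, trial QC and neuron/condition inclusion.

Inputs are spike-time tables (spike sorting is upstream).  Two inclusion
rules gate the analysis:

* a neuron whose mean firing rate to preferred-direction roll falls below
  80% of the reference population mean (199 spikes/s, i.e. below
  159 spikes/s) is removed entirely — without a vigorous response the
  kernel estimate is unreliable;
* a neuron-condition whose mean rate over trials is below 5 spikes/s is
  removed — spikes are needed to compute a cross-correlation at all.

Receptive-field side is normalised by mirroring: for right-side neurons
the roll polarity of the stimulus is negated so that positive always
means excitatory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from mseqrc.starfield import StimulusTrace

__all__ = [
    "SpikeTrain",
    "TrialRecord",
    "PREFERRED_RATE_REFERENCE",
    "PREFERRED_RATE_FACTOR",
    "preferred_rate_threshold",
    "MIN_CONDITION_RATE",
    "bin_spikes",
    "mean_rate",
    "qc_trial",
    "apply_inclusion",
    "mirror_normalize",
]

# Reference preferred-direction roll response (spikes/s, population mean)
# and the fraction of it below which a neuron is excluded.
PREFERRED_RATE_REFERENCE = 199.0
PREFERRED_RATE_FACTOR = 0.8
# Minimum mean rate (spikes/s) over the trials of one condition.
MIN_CONDITION_RATE = 5.0


def preferred_rate_threshold(
    reference: float = PREFERRED_RATE_REFERENCE,
    factor: float = PREFERRED_RATE_FACTOR,
) -> float:
    """Neuron-level exclusion threshold: round(factor * reference) = 159."""
    return float(round(factor * reference))


@dataclass
class SpikeTrain:
    """Sorted spike times (s) for one trial."""

    times: np.ndarray
    duration: float
    neuron_id: str = ""
    condition: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))
        if len(self.times) and (
            self.times[0] < 0 or self.times[-1] >= self.duration
        ):
            raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return len(self.times)


@dataclass
class TrialRecord:
    """A (spike train, stimulus trace) pair with its QC verdict."""

    train: SpikeTrain
    trace: StimulusTrace
    keep: bool = True
    reason: str = ""


def bin_spikes(train: SpikeTrain, resolution_ms: float = 1.0) -> np.ndarray:
    """Spike counts per bin (floor convention); sums to the spike count."""
    if resolution_ms <= 0:
        raise ValueError("resolution_ms must be positive")
    n_bins = int(np.ceil(train.duration * 1000.0 / resolution_ms))
    idx = np.floor(train.times * 1000.0 / resolution_ms).astype(int)
    return np.bincount(idx, minlength=n_bins)[:n_bins]


def mean_rate(train: SpikeTrain, t0: float, t1: float) -> float:
    """Mean firing rate (Hz) over [t0, t1)."""
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if t0 < 0 or t1 > train.duration + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}) outside trial [0, {train.duration})"
        )
    n = int(np.sum((train.times >= t0) & (train.times < t1)))
    return n / (t1 - t0)


def qc_trial(record: TrialRecord) -> TrialRecord:
    """Discard the whole trial if any stimulus frame was dropped."""
    log = record.trace.frame_log
    if log is None or len(log) == 0:
        return replace(record, keep=False, reason="no_frame_log")
    if not np.all(log):
        return replace(record, keep=False, reason="dropped_frames")
    return replace(record, keep=True, reason="")


def apply_inclusion(
    dataset,
    preferred_roll_rates: dict[str, float],
    condition_rates: dict[tuple[str, str], float],
    threshold: float | None = None,
    min_condition_rate: float = MIN_CONDITION_RATE,
):
    """Apply the neuron- and condition-level inclusion rules.

    Parameters
    ----------
    dataset
        Object with ``neuron_ids``, ``condition_labels`` and a
        ``trials[(neuron_id, condition)]`` mapping (see
        :class:`mseqrc.synthetic.SyntheticDataset`); it is filtered by
        dropping excluded keys, the input is not mutated.
    preferred_roll_rates
        Mean preferred-direction roll rate (Hz) per neuron.
    condition_rates
        Mean rate (Hz) over trials per (neuron, condition).

    Returns
    -------
    (filtered_dataset, report)
        ``report`` is a DataFrame with columns neuron_id, condition,
        reason; condition is empty for whole-neuron exclusions.
    """
    if threshold is None:
        threshold = preferred_rate_threshold()
    rows = []
    excluded_neurons = set()
    for nid in dataset.neuron_ids:
        rate = preferred_roll_rates.get(nid)
        if rate is None or rate < threshold:
            excluded_neurons.add(nid)
            rows.append(
                {"neuron_id": nid, "condition": "",
                 "reason": f"preferred_roll_rate_below_{threshold:g}"}
            )
    excluded_conditions = set()
    for (nid, cond), rate in sorted(condition_rates.items()):
        if nid in excluded_neurons or (nid, cond) not in dataset.trials:
            continue
        if rate < min_condition_rate:
            excluded_conditions.add((nid, cond))
            rows.append(
                {"neuron_id": nid, "condition": cond,
                 "reason": f"condition_rate_below_{min_condition_rate:g}"}
            )
    filtered = dataset.subset(
        neuron_ids=[n for n in dataset.neuron_ids
                    if n not in excluded_neurons],
        drop_conditions=excluded_conditions,
    )
    report = pd.DataFrame(rows, columns=["neuron_id", "condition", "reason"])
    return filtered, report


def mirror_normalize(trace: StimulusTrace, side: str) -> StimulusTrace:
    """Express roll polarity in the neuron's preferred-direction frame.

    Left-side neurons are the reference (identity).  For right-side
    neurons the sign sequence and roll increments are negated so that
    positive roll is excitatory for every neuron; lift is unchanged.
    """
    if side == "left":
        return trace
    if side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return replace(
        trace,
        sign_sequence=(-trace.sign_sequence).astype(np.int8),
        roll_increment=-trace.roll_increment,
    )
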