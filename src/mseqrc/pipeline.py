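"""End-to-end orchestration: simulate/load → QC → kernels → validate → stats.

A run is fully described by a :class:`RunConfig` (serialisable to YAML)
and a seed; identical configurations and seeds produce identical output
tables.  Results are written as diffable CSV/JSON files plus a manifest
recording the seed and settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mseqrc._version import __version__
from mseqrc.kernels import cross_correlate, extract_params, mean_smooth
from mseqrc.spikes import (
    SpikeTrain,
    TrialRecord,
    apply_inclusion,
    bin_spikes,
    mean_rate,
    mirror_normalize,
    qc_trial,
)
from mseqrc.starfield import FlowCondition, StimulusTrace
from mseqrc.stats import kruskal_wallis, pairwise_mwu_bh, percent_change
from mseqrc.synthetic import (
    SimConfig,
    SyntheticDataset,
    Trial,
    simulate_experiment,
)
from mseqrc.validation import loo_correlations, shuffle_control

__all__ = ["RunConfig", "run_pipeline", "load_recordings"]

log = logging.getLogger("mseqrc")

#: Kernel parameters analysed by the statistics stage.
PARAM_COLUMNS = [
    "amplitude",
    "ttp_ms",
    "half_width_ms",
    "decay_ms",
    "return_to_baseline_ms",
    "spike_rate_hz",
]


@dataclass
class RecordedNeuron:
    """Minimal neuron record for datasets loaded from disk."""

    side: str = "left"


@dataclass
class RunConfig:
    """Settings of one pipeline run."""

    seed: int = 0
    input_mode: str = "synthetic"          # "synthetic" | "csv"
    input_dir: str | None = None
    out_dir: str | None = None
    # simulation
    n_neurons: int = 12
    n_trials: int = 8
    drop_prob: float = 0.0
    # analysis
    window_ms: float = 5.0
    broad_window_ms: float = 25.0
    n_bins: int = 20
    n_shuffles: int = 20
    reference_smooth_ms: int = 200
    reference_condition: str = "roll33"
    preferred_rate_condition: str = "er50"
    run_validation: bool = True
    run_shuffle_control: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_neurons=self.n_neurons,
            n_trials=self.n_trials,
            drop_prob=self.drop_prob,
        )


def _analysis_window(trace: StimulusTrace) -> tuple[float, float]:
    """Time span (s) of the final analysed m-sequence period."""
    t0 = float(trace.frame_times[trace.analysis_start])
    t1 = float(trace.duration)
    return t0, t1


def _qc_dataset(dataset: SyntheticDataset) -> tuple[SyntheticDataset, pd.DataFrame]:
    """Drop trials with dropped frames; report every exclusion."""
    rows = []
    kept: dict[tuple[str, str], list[Trial]] = {}
    for key, trials in dataset.trials.items():
        keep_list = []
        for t, trial in enumerate(trials):
            rec = qc_trial(TrialRecord(train=trial.train, trace=trial.trace))
            if rec.keep:
                keep_list.append(trial)
            else:
                rows.append(
                    {"neuron_id": key[0], "condition": key[1], "trial": t,
                     "reason": rec.reason}
                )
        if keep_list:
            kept[key] = keep_list
    out = SyntheticDataset(
        neurons=dataset.neurons,
        conditions=dataset.conditions,
        trials=kept,
        shared_condition=dataset.shared_condition,
        shared_trial_index=dataset.shared_trial_index,
        master_seed=dataset.master_seed,
    )
    return out, pd.DataFrame(rows, columns=["neuron_id", "condition",
                                            "trial", "reason"])


def _condition_rates(dataset: SyntheticDataset) -> dict[tuple[str, str], float]:
    rates = {}
    for key, trials in dataset.trials.items():
        per_trial = []
        for trial in trials:
            t0, t1 = _analysis_window(trial.trace)
            per_trial.append(mean_rate(trial.train, t0, t1))
        rates[key] = float(np.mean(per_trial))
    return rates


def _preferred_rates(
    dataset: SyntheticDataset,
    condition_rates: dict[tuple[str, str], float],
    preferred_condition: str,
) -> dict[str, float]:
    rates = {}
    for nid in dataset.neuron_ids:
        key = (nid, preferred_condition)
        if key not in condition_rates:
            key = (nid, dataset.shared_condition)
        rates[nid] = condition_rates.get(key, 0.0)
    return rates


def _estimate_all_kernels(
    dataset: SyntheticDataset, config: RunConfig
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Per neuron-condition: kernel estimate + the six parameters."""
    rows = []
    kernel_tables = {}
    for (nid, cond), trials in sorted(dataset.trials.items()):
        side = getattr(dataset.neurons[nid], "side", "left")
        corrs, rates = [], []
        for trial in trials:
            trace = mirror_normalize(trial.trace, side)
            corrs.append(cross_correlate(trace, bin_spikes(trial.train)))
            t0, t1 = _analysis_window(trial.trace)
            rates.append(mean_rate(trial.train, t0, t1))
        ir = mean_smooth(corrs, window_ms=config.window_ms)
        params = extract_params(
            ir,
            raw_correlations=corrs,
            broad_window_ms=config.broad_window_ms,
            spike_rate=float(np.mean(rates)),
        )
        row = {"neuron_id": nid, "condition": cond,
               "n_trials": len(trials), "defined": params.defined}
        row.update(params.as_dict())
        rows.append(row)
        kernel_tables[(nid, cond)] = pd.DataFrame(
            {"lag_ms": ir.lags, "value": ir.values}
        )
    table = pd.DataFrame(rows)
    return table, kernel_tables


def _group_statistics(
    params: pd.DataFrame, reference_condition: str
) -> dict:
    """Omnibus + pairwise statistics and percent changes per parameter."""
    omnibus_rows, pairwise_tables, pct_rows = [], [], []
    defined = params[params["defined"]]
    for col in PARAM_COLUMNS:
        groups = {
            cond: sub[col].dropna().to_numpy()
            for cond, sub in defined.groupby("condition")
        }
        groups = {c: v for c, v in groups.items() if len(v)}
        if len(groups) < 2:
            continue
        h, df_, p = kruskal_wallis(groups)
        omnibus_rows.append(
            {"parameter": col, "H": h, "df": df_, "p": p}
        )
        pw = pairwise_mwu_bh(groups)
        pw.insert(0, "parameter", col)
        pairwise_tables.append(pw)
        if reference_condition in groups:
            ref_median = float(np.median(groups[reference_condition]))
            for cond, vals in groups.items():
                if cond == reference_condition or ref_median == 0:
                    continue
                pct_rows.append(
                    {
                        "parameter": col,
                        "condition": cond,
                        "percent_change": percent_change(
                            float(np.median(vals)), ref_median
                        ),
                    }
                )
    return {
        "omnibus": pd.DataFrame(omnibus_rows),
        "pairwise": (
            pd.concat(pairwise_tables, ignore_index=True)
            if pairwise_tables else pd.DataFrame()
        ),
        "percent_change": pd.DataFrame(pct_rows),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load → QC → inclusion → kernels → validation → stats.

    Returns a results bundle (dict of DataFrames and plain values) and,
    if ``config.out_dir`` is set, writes CSV/JSON outputs plus a manifest.
    """
    if config.input_mode == "synthetic":
        if config.n_neurons < 1:
            raise ValueError("config.n_neurons must be >= 1")
        dataset = simulate_experiment(config.sim_config(), config.seed)
    elif config.input_mode == "csv":
        if not config.input_dir:
            raise ValueError("input_mode 'csv' requires input_dir")
        dataset = load_recordings(config.input_dir)
    else:
        raise ValueError(f"unknown input_mode {config.input_mode!r}")

    dataset, qc_report = _qc_dataset(dataset)
    log.info("QC discarded %d trials", len(qc_report))

    condition_rates = _condition_rates(dataset)
    preferred = _preferred_rates(
        dataset, condition_rates, config.preferred_rate_condition
    )
    dataset, inclusion_report = apply_inclusion(
        dataset, preferred, condition_rates
    )
    log.info("inclusion excluded %d entries", len(inclusion_report))

    params, kernel_tables = _estimate_all_kernels(dataset, config)

    validation = None
    shuffle = None
    rng_val = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0]
    )
    has_shared = [
        nid for nid in dataset.neuron_ids
        if any(
            t.shared
            for t in dataset.trials.get((nid, dataset.shared_condition), [])
        )
    ]
    if config.run_validation and len(has_shared) >= 2:
        val_dataset = dataset.subset(neuron_ids=has_shared)
        validation = loo_correlations(
            val_dataset, n_bins=config.n_bins,
            window_ms=config.window_ms,
            smooth_ms=config.reference_smooth_ms,
        )
        if config.run_shuffle_control:
            shuffle_per_neuron, shuffle_median = shuffle_control(
                val_dataset, rng_val, n_shuffles=config.n_shuffles,
                n_bins=config.n_bins, window_ms=config.window_ms,
                smooth_ms=config.reference_smooth_ms,
            )
            shuffle = {"per_neuron": shuffle_per_neuron,
                       "median": shuffle_median}

    statistics = _group_statistics(params, config.reference_condition)

    results = {
        "dataset": dataset,
        "qc_report": qc_report,
        "inclusion_report": inclusion_report,
        "params": params,
        "kernels": kernel_tables,
        "validation": validation,
        "shuffle": shuffle,
        "stats": statistics,
        "seed": config.seed,
    }
    if config.out_dir:
        _write_outputs(results, config)
    return results


def _write_outputs(results: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["params"].to_csv(out / "kernel_params.csv", index=False)
    results["qc_report"].to_csv(out / "qc_report.csv", index=False)
    results["inclusion_report"].to_csv(
        out / "inclusion_report.csv", index=False
    )
    kdir = out / "kernels"
    kdir.mkdir(exist_ok=True)
    for (nid, cond), table in results["kernels"].items():
        table.to_csv(kdir / f"{nid}_{cond}.csv", index=False)
    results["stats"]["omnibus"].to_csv(out / "stats_omnibus.csv", index=False)
    results["stats"]["pairwise"].to_csv(
        out / "stats_pairwise.csv", index=False
    )
    results["stats"]["percent_change"].to_csv(
        out / "stats_percent_change.csv", index=False
    )
    report = {}
    if results["validation"] is not None:
        v = results["validation"]
        report = {
            "per_neuron": v.per_neuron,
            "median": v.median,
            "range": list(v.range),
        }
    if results["shuffle"] is not None:
        report["shuffle"] = results["shuffle"]
    (out / "validation.json").write_text(json.dumps(report, indent=1))
    manifest = {
        "seed": config.seed,
        "version": __version__,
        "settings": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_recordings(directory: str | Path) -> SyntheticDataset:
    """Load an exported dataset (trace/spike CSVs plus manifest.json).

    Trials with a missing or malformed file are dropped with a logged
    reason; an empty or manifest-less directory is an error.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"no trials found: {manifest_path} does not exist"
        )
    manifest = json.loads(manifest_path.read_text())
    if not manifest.get("trials"):
        raise ValueError(f"no trials found in {manifest_path}")
    conditions = [
        FlowCondition(
            base_impulse=c["base_impulse"],
            constant_roll=c.get("constant_roll", 0.0),
            constant_lift=c.get("constant_lift", 0.0),
            label=c["label"],
        )
        for c in manifest["conditions"]
    ]
    cond_map = {c.label: c for c in conditions}
    neurons = {
        nid: RecordedNeuron(side=info.get("side", "left"))
        for nid, info in manifest.get("neurons", {}).items()
    }
    trials: dict[tuple[str, str], list[Trial]] = {}
    for entry in manifest["trials"]:
        nid, cond, t = entry["neuron_id"], entry["condition"], entry["trial"]
        stem = f"{nid}_{cond}_{t:02d}"
        trace_path = directory / f"{stem}_trace.csv"
        spike_path = directory / f"{stem}_spikes.csv"
        try:
            if not trace_path.exists():
                raise FileNotFoundError(f"missing trace {trace_path.name}")
            trace = StimulusTrace.from_csv(
                trace_path, cond_map[cond],
                period=entry.get("period", 255),
            )
            spikes = pd.read_csv(spike_path)
            times = spikes["spike_time_s"].to_numpy(float)
            if np.any(~np.isfinite(times)):
                raise ValueError(f"non-finite spike time in {spike_path.name}")
            train = SpikeTrain(
                times=times,
                duration=float(entry["duration_s"]),
                neuron_id=nid, condition=cond, trial=t,
            )
        except (FileNotFoundError, ValueError, KeyError) as exc:
            log.warning("dropping trial %s: %s", stem, exc)
            continue
        neurons.setdefault(nid, RecordedNeuron())
        trials.setdefault((nid, cond), []).append(
            Trial(trace=trace, train=train, shared=entry.get("shared", False))
        )
    if not trials:
        raise ValueError(f"no loadable trials found in {directory}")
    return SyntheticDataset(
        neurons=neurons,
        conditions=conditions,
        trials=trials,
        shared_condition=manifest.get("shared_condition", "roll33"),
        shared_trial_index=manifest.get("shared_trial_index", 1),
        master_seed=manifest.get("master_seed", 0),
    )
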