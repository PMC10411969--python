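"""Reading and writing trial tables, ground truth and configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import NeuronRecording, Trial
from .synthetic import GroundTruth, SimConfig
from .timebase import EVENT_NAMES, TrialEvents

__all__ = [
    "write_population_csv",
    "read_population_csv",
    "write_ground_truth_csv",
    "sim_config_from_dict",
    "load_yaml",
]


def write_population_csv(recordings: list[NeuronRecording], path: str | Path) -> None:
    """Trials table: one row per trial, spike times as a JSON array (ms)."""
    rows = []
    for rec in recordings:
        for trial_id, tr in enumerate(rec.trials):
            row = {
                "neuron_id": rec.neuron_id,
                "trial_id": trial_id,
                "task": tr.task,
                "action": tr.action,
            }
            ev = tr.events.as_array()
            for name, t in zip(EVENT_NAMES, ev):
                row[f"{name}_ms"] = t
            row["spikes_ms"] = json.dumps([round(float(s), 4) for s in tr.spikes])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_population_csv(path: str | Path) -> list[NeuronRecording]:
    df = pd.read_csv(path)
    recordings: dict[int, NeuronRecording] = {}
    for _, row in df.iterrows():
        nid = int(row["neuron_id"])
        rec = recordings.setdefault(nid, NeuronRecording(neuron_id=nid))
        events = TrialEvents(*[float(row[f"{name}_ms"]) for name in EVENT_NAMES])
        spikes = np.asarray(json.loads(row["spikes_ms"]), dtype=float)
        rec.trials.append(
            Trial(task=row["task"], action=row["action"], events=events, spikes=spikes)
        )
    return [recordings[k] for k in sorted(recordings)]


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for i, profile in enumerate(truth.profiles):
        row = {
            "neuron_id": i,
            "profile": profile,
            "window_start": int(truth.windows[i, 0]) + 1,
            "window_stop": int(truth.windows[i, 1]),
            "preferred_execution": int(truth.preferred["execution"][i]),
            "preferred_observation": int(truth.preferred["observation"][i]),
        }
        for j in range(truth.bin_code.shape[1]):
            row[f"bin_{j + 1}"] = truth.bin_code[i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-derived) plain dict.

    Duration-model keys may be given as "task/action" strings mapping
    interval names to [low, high] pairs.
    """
    d = dict(d)
    if "duration_model" in d:
        model = {}
        for key, spec in d["duration_model"].items():
            task, action = key.split("/")
            model[(task, action)] = {k: tuple(v) for k, v in spec.items()}
        d["duration_model"] = model
    if "coding_window" in d:
        d["coding_window"] = tuple(d["coding_window"])
    return SimConfig(**d)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
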