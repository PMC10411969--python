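"""Trial-based recording containers and their binned-rate views."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timebase import (
    ACTION_PERIOD_BINS,
    N_BINS,
    TrialEvents,
    bin_rates,
    epoch_windows,
    quartile_edges,
    window_rate,
)

__all__ = [
    "TASKS",
    "ACTIONS",
    "CONDITIONS",
    "Trial",
    "NeuronRecording",
    "BinnedNeuron",
    "bin_population",
]

TASKS = ("execution", "observation")
ACTIONS = ("lift", "twist", "shift")
#: the six task × action conditions, in canonical order
CONDITIONS = tuple((t, a) for t in TASKS for a in ACTIONS)


@dataclass(frozen=True)
class Trial:
    task: str
    action: str
    events: TrialEvents
    spikes: np.ndarray

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")


@dataclass
class NeuronRecording:
    """All trials of one neuron across the six task × action conditions."""

    neuron_id: int
    trials: list[Trial] = field(default_factory=list)

    def trials_of(self, task: str, action: str) -> list[Trial]:
        return [t for t in self.trials if t.task == task and t.action == action]

    def condition_counts(self) -> dict[tuple[str, str], int]:
        counts = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            counts[(t.task, t.action)] += 1
        return counts

    def min_trials_per_condition(self) -> int:
        return min(self.condition_counts().values())


@dataclass
class BinnedNeuron:
    """Precomputed per-trial rates of one neuron.

    ``rates[(task, action)]`` is a (n_trials, 24) array of per-bin discharge
    rates in Hz; ``epoch_rates[(task, action)]`` is (n_trials, 5) over the
    mirror-neuron screening windows (baseline, approach, manipulation-I,
    manipulation-II, hold).
    """

    neuron_id: int
    rates: dict[tuple[str, str], np.ndarray]
    epoch_rates: dict[tuple[str, str], np.ndarray]

    @classmethod
    def from_recording(cls, rec: NeuronRecording) -> "BinnedNeuron":
        rates: dict[tuple[str, str], np.ndarray] = {}
        epoch_rates: dict[tuple[str, str], np.ndarray] = {}
        for cond in CONDITIONS:
            trials = rec.trials_of(*cond)
            r = np.empty((len(trials), N_BINS))
            er = np.empty((len(trials), 5))
            for i, tr in enumerate(trials):
                grid = quartile_edges(tr.events)
                r[i] = bin_rates(tr.spikes, grid)
                wins = epoch_windows(tr.events).as_array()
                er[i] = [window_rate(tr.spikes, tuple(w)) for w in wins]
            rates[cond] = r
            epoch_rates[cond] = er
        return cls(neuron_id=rec.neuron_id, rates=rates, epoch_rates=epoch_rates)

    def n_trials(self, task: str, action: str) -> int:
        return self.rates[(task, action)].shape[0]

    def min_trials_per_condition(self) -> int:
        return min(self.rates[c].shape[0] for c in CONDITIONS)

    def task_rates(self, task: str, bin_index: int) -> list[np.ndarray]:
        """Per-action rate samples of one task in one bin (list of 3 arrays)."""
        return [self.rates[(task, a)][:, bin_index] for a in ACTIONS]

    def sorted_bin_rates(self, bin_index: int) -> dict[tuple[str, str], np.ndarray]:
        """Per-condition rate values in one bin, sorted ascending.

        Bootstrap stages resample these canonically sorted values by index,
        which makes every bootstrap p-value exactly invariant to the order in
        which trials were recorded or listed.
        """
        return {c: np.sort(self.rates[c][:, bin_index]) for c in CONDITIONS}


def bin_population(recordings: list[NeuronRecording]) -> list[BinnedNeuron]:
    return [BinnedNeuron.from_recording(r) for r in recordings]


def action_period_slice() -> slice:
    """0-based slice selecting the 12 action-period bins out of 24."""
    lo = int(ACTION_PERIOD_BINS[0])
    return slice(lo, lo + len(ACTION_PERIOD_BINS))
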