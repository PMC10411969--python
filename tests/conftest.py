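"""Shared fixtures and builders for synthetic neurons with known rate maps."""

from __future__ import annotations

import numpy as np
import pytest

from mirrorcode.records import ACTIONS, CONDITIONS, BinnedNeuron, NeuronRecording, Trial
from mirrorcode.synthetic import DEFAULT_DURATIONS, _poisson_spikes, draw_trial_events
from mirrorcode.timebase import N_BINS, quartile_edges

def flat_durations(ms: float) -> dict:
    """Degenerate duration model: every one of the 7 intervals exactly ``ms``."""
    return {
        cond: {k: (ms, ms) for k in
               ("bpr_led", "led_rls", "rls_tch", "tch_mov", "mov_hld", "hld_rew", "rew_wdr")}
        for cond in CONDITIONS
    }


#: every interval exactly 400 ms (100 ms quartile bins)
FLAT_400 = flat_durations(400.0)
#: every interval exactly 1600 ms (400 ms quartile bins)
FLAT_1600 = flat_durations(1600.0)


def make_neuron(
    rate_fn,
    trials_per_condition: int = 16,
    rng: np.random.Generator | None = None,
    neuron_id: int = 0,
    duration_model=None,
) -> NeuronRecording:
    """Build a Poisson neuron from an arbitrary rate map.

    ``rate_fn(task, action)`` returns a 24-vector of per-bin rates in Hz (or
    a scalar applied to all bins).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if duration_model is None:
        duration_model = DEFAULT_DURATIONS
    trials = []
    for task, action in CONDITIONS:
        rates = np.broadcast_to(np.asarray(rate_fn(task, action), dtype=float), (N_BINS,))
        for _ in range(trials_per_condition):
            events = draw_trial_events(task, action, duration_model, rng)
            grid = quartile_edges(events)
            spikes = _poisson_spikes(grid.edges, rates, rng)
            trials.append(Trial(task=task, action=action, events=events, spikes=spikes))
    return NeuronRecording(neuron_id=neuron_id, trials=trials)


def action_rate_map(base, preferred, effect, bins, tasks=("execution", "observation"),
                    obs_preferred=None):
    """Rate function: ``preferred`` action elevated by ``effect`` in ``bins``."""
    bins = np.asarray(bins)

    def fn(task, action):
        rates = np.full(24, float(base))
        pref = preferred if (obs_preferred is None or task == "execution") else obs_preferred
        if task in tasks and action == ACTIONS[pref]:
            rates[bins] += effect
        return rates

    return fn


@pytest.fixture(scope="session")
def flat_neuron() -> BinnedNeuron:
    """Action-independent neuron, 10 Hz everywhere, 16 trials per condition."""
    rec = make_neuron(lambda t, a: 10.0, rng=np.random.default_rng(5))
    return BinnedNeuron.from_recording(rec)


@pytest.fixture(scope="session")
def separable_neuron() -> BinnedNeuron:
    """Strongly separable shared-code neuron: rates 30/10/0 Hz in both tasks,
    all bins, 400 ms quartile bins."""

    def fn(task, action):
        return {"lift": 30.0, "twist": 10.0, "shift": 0.0}[action]

    rec = make_neuron(fn, trials_per_condition=32, rng=np.random.default_rng(6),
                      duration_model=FLAT_1600)
    return BinnedNeuron.from_recording(rec)
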