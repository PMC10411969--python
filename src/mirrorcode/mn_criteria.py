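"""Mirror-neuron screening.

A neuron qualifies as a mirror neuron when its discharge is modulated across
the five task epochs (baseline, approach, manipulation-I, manipulation-II,
hold) during execution (motor response) *and* during observation (visual
response).  Modulation is assessed per action with a Friedman test over the
per-trial epoch rates, Bonferroni-corrected over the three actions; any
direction of modulation counts, and the modulated epoch need not agree
between tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ACTIONS, TASKS, BinnedNeuron
from .stats import friedman

__all__ = ["NeuronScreen", "classify_neuron", "screen_population", "MIN_TRIALS"]

MIN_TRIALS = 8


@dataclass(frozen=True)
class NeuronScreen:
    neuron_id: int
    motor: bool
    visual: bool
    mirror: bool
    pvalues: dict[tuple[str, str], float]
    excluded: str | None = None


def classify_neuron(neuron: BinnedNeuron, alpha: float = 0.05) -> NeuronScreen:
    """Screen one neuron; requires >=8 trials in each of the 6 conditions."""
    n_min = neuron.min_trials_per_condition()
    if n_min < MIN_TRIALS:
        return NeuronScreen(
            neuron_id=neuron.neuron_id,
            motor=False,
            visual=False,
            mirror=False,
            pvalues={},
            excluded=f"only {n_min} valid trials in some condition (need {MIN_TRIALS})",
        )
    pvalues: dict[tuple[str, str], float] = {}
    significant = {t: False for t in TASKS}
    for task in TASKS:
        for action in ACTIONS:
            _, p = friedman(neuron.epoch_rates[(task, action)])
            pvalues[(task, action)] = p
            if p < alpha / len(ACTIONS):
                significant[task] = True
    motor = significant["execution"]
    visual = significant["observation"]
    return NeuronScreen(
        neuron_id=neuron.neuron_id,
        motor=motor,
        visual=visual,
        mirror=motor and visual,
        pvalues=pvalues,
    )


def screen_population(
    population: list[BinnedNeuron], alpha: float = 0.05
) -> tuple[list[BinnedNeuron], list[NeuronScreen]]:
    """Screen a population; returns (mirror neurons, all screen records)."""
    screens = [classify_neuron(n, alpha=alpha) for n in population]
    kept = [n for n, s in zip(population, screens) if s.mirror]
    return kept, screens
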