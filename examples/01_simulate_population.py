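"""Simulate a small mirror-neuron population and inspect its structure.

Builds 12 neurons with planted coding profiles (shared / non-shared /
observation-only / non-coding), prints the trial skeleton of one trial and
the planted ground truth, and writes the population to CSV.
"""

import numpy as np

from mirrorcode import SimConfig, simulate_population
from mirrorcode.io import write_ground_truth_csv, write_population_csv
from mirrorcode.timebase import EVENT_NAMES

cfg = SimConfig(n_neurons=12, trials_per_condition=16, seed=1)
recordings, truth = simulate_population(cfg)

trial = recordings[0].trials[0]
print(f"neuron 0, first trial: task={trial.task}, action={trial.action}")
for name, t in zip(EVENT_NAMES, trial.events.as_array()):
    print(f"  {name.upper():>4}: {t:8.1f} ms")
print(f"  {trial.spikes.size} spikes between start-button press and withdrawal")

print("\nplanted ground truth (profile, coding window in action-period bins):")
for i, profile in enumerate(truth.profiles):
    lo, hi = truth.windows[i]
    window = f"bins {lo + 1}-{hi}" if profile != "non_coding" else "-"
    print(f"  neuron {i:2d}: {profile:<11} {window}")

write_population_csv(recordings, "population.csv")
write_ground_truth_csv(truth, "ground_truth.csv")
print("\nwrote population.csv and ground_truth.csv")
print("Each neuron fires Poisson spikes whose rate depends on the action only")
print("inside its coding window; 'shared' neurons prefer the same action in")
print("both tasks, 'non_shared' neurons prefer different actions per task.")
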