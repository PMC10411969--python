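"""Decode actions from pseudo-population activity, within and across tasks.

Builds a mixed population (mostly non-shared coders), assembles
pseudo-trials with one feature per neuron, and compares within-task (e2e,
o2o) and cross-task (e2o, o2e) decoding accuracy in one action-period bin.
"""

import numpy as np

from mirrorcode import SimConfig, bin_population, population_accuracy, screen_population, simulate_population

cfg = SimConfig(n_neurons=40, trials_per_condition=16, seed=5)
recordings, _ = simulate_population(cfg)
kept, _ = screen_population(bin_population(recordings))
rng = np.random.default_rng(1)

bin_index = 16  # first quartile bin after the object is held (HLD->REW epoch)
print(f"population decoding, {len(kept)} neurons as features, grid bin {bin_index + 1}:")
for mode, meaning in (
    ("e2e", "trained and tested on execution"),
    ("o2o", "trained and tested on observation"),
    ("e2o", "execution-trained, tested on observation"),
    ("o2e", "observation-trained, tested on execution"),
):
    pa = population_accuracy(kept, bin_index, mode, n_boot=300, rng=rng)
    print(f"  {mode}: {100 * pa.mean:5.1f}%  (90% CI {100 * pa.ci[0]:.1f}-"
          f"{100 * pa.ci[1]:.1f}%)  - {meaning}")
print("\nChance is 33.3%. Within-task decoders recover the actions well; the")
print("cross-task decoders stay near (or below) chance because most planted")
print("neurons encode actions with task-specific (non-shared) codes.")
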