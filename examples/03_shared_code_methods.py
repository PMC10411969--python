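"""Decide per bin whether the action code is shared between tasks.

Runs the three shared-code criteria (same discharge, same preference,
cross-task LDA classification) on a planted population and compares the
recovered shared neurons against the planted ground truth and against the
independence permutation null.
"""

import numpy as np

from mirrorcode import (
    SHARED,
    SimConfig,
    bin_population,
    coding_flags,
    cross_task_shared,
    null_distribution,
    same_discharge,
    same_preference,
    screen_population,
    simulate_population,
)

cfg = SimConfig(n_neurons=40, trials_per_condition=64, seed=3)
recordings, truth = simulate_population(cfg)
binned = bin_population(recordings)
kept, _ = screen_population(binned)
coding = coding_flags(kept)
rng = np.random.default_rng(0)

labels = {
    "same discharge  ": same_discharge(kept, coding),
    "same preference ": same_preference(kept, coding, n_boot=500, rng=rng),
    "cross-task LDA  ": cross_task_shared(kept, coding, n_boot=500, rng=rng),
}

planted = sum(p == "shared" for p in truth.profiles)
print(f"planted shared neurons: {planted} of {cfg.n_neurons}\n")
for name, lab in labels.items():
    n_bins = int((lab == SHARED).sum())
    n_neurons = int((lab == SHARED).any(axis=1).sum())
    print(f"{name}: {n_bins:3d} shared bins, {n_neurons:2d} neurons with >=1 shared bin")

nd = null_distribution(kept, "preference", n_perm=100, rng=rng, coding=coding,
                       n_boot=200)
observed = int((labels["same preference "] == SHARED).any(axis=1).sum())
lo, hi = nd.interval("neurons")
print(f"\nindependence null (preference method, 100 re-pairings): "
      f"{nd.mean('neurons'):.1f} shared neurons expected, 95% band [{lo:.0f}, {hi:.0f}]")
print(f"observed {observed} -> {'above' if observed > hi else 'inside'} the null band")
print("\nA shared bin means the action->discharge mapping is statistically the")
print("same in execution and observation under that method's criterion.")
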