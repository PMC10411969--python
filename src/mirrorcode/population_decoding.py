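"""Population decoding with the neuron-per-feature pseudo-population design.

Neurons were not recorded simultaneously, so population trials are
assembled by index: per bootstrap resample, every neuron independently
contributes eight sampled trials per condition, and the i-th sampled trials
are concatenated into one pseudo-trial.  Eight-fold cross-validation then
holds out one pseudo-trial per condition per fold; cross-task modes test on
the held-out fold of the other task.  Accuracy is summarised by the
bootstrap mean and a central 90% interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ACTIONS, BinnedNeuron
from .shared_code import MODES, NON_SHARED, SHARED
from .stats import VAR_FLOOR

__all__ = ["PopulationAccuracy", "population_accuracy", "binwise_subpopulations"]

_N_TRIALS = 8  # per condition: the minimum guaranteed by the screening floor


@dataclass
class PopulationAccuracy:
    mode: str
    bin_index: int
    subset: str
    neuron_ids: list[int]
    mean: float
    ci: tuple[float, float]    # central 90% bootstrap interval
    accuracies: np.ndarray

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)


def population_accuracy(
    population: list[BinnedNeuron],
    bin_index: int,
    mode: str,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    subset: str = "all",
    ci_level: float = 90.0,
    chunk: int = 250,
) -> PopulationAccuracy:
    """Bootstrap 8-fold CV accuracy of the population classifier in one bin.

    Every neuron is one feature; all neurons must have >=8 trials per
    condition.  Returns mean accuracy and the central ``ci_level`` interval
    over ``n_boot`` resamples.
    """
    if not population:
        raise ValueError("empty neuron subset: population accuracy undefined")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    train_task, test_task = MODES[mode]
    d = len(population)
    # sorted per-condition values (d, task, 3, n); ragged n -> store per neuron
    vals: dict[str, list[list[np.ndarray]]] = {t: [] for t in ("execution", "observation")}
    for neuron in population:
        if neuron.min_trials_per_condition() < _N_TRIALS:
            raise ValueError(
                f"neuron {neuron.neuron_id} has fewer than {_N_TRIALS} trials per condition"
            )
        for t in vals:
            vals[t].append([np.sort(neuron.rates[(t, a)][:, bin_index]) for a in ACTIONS])

    accs = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        x = {}
        for t in ("execution", "observation"):
            if t not in (train_task, test_task):
                continue
            xt = np.empty((b, 3, _N_TRIALS, d))
            for j in range(d):
                for ai in range(3):
                    v = vals[t][j][ai]
                    idx = rng.integers(0, v.size, size=(b, _N_TRIALS))
                    xt[:, ai, :, j] = v[idx]
            x[t] = xt
        xtr, xte = x[train_task], x[test_task]
        # per fold f: train on the other 7 pseudo-trials per condition
        tot = xtr.sum(axis=2)                                   # (b, 3, d)
        means = (tot[:, :, None, :] - xtr) / (_N_TRIALS - 1)    # (b, 3, f, d)
        sq_tot = (xtr**2).sum(axis=2)
        ss = (sq_tot[:, :, None, :] - xtr**2) - (_N_TRIALS - 1) * means**2
        pooled = ss.sum(axis=1) / (3 * (_N_TRIALS - 1) - 3)     # (b, f, d)
        pooled = np.maximum(pooled, VAR_FLOOR)
        # test rows: fold f of the test task, (b, 3true, f, d)
        diff = xte[:, :, None, :, :] - means[:, None, :, :, :]  # (b, 3t, 3c, f, d)
        dist = (diff**2 / pooled[:, None, None, :, :]).sum(axis=-1)  # (b, 3t, 3c, f)
        pred = np.argmin(dist, axis=2)                          # (b, 3t, f)
        truth = np.arange(3)[None, :, None]
        accs[done : done + b] = (pred == truth).mean(axis=(1, 2))
        done += b
    lo = (100.0 - ci_level) / 2.0
    ci = tuple(np.percentile(accs, [lo, 100.0 - lo]))
    return PopulationAccuracy(
        mode=mode,
        bin_index=bin_index,
        subset=subset,
        neuron_ids=[n.neuron_id for n in population],
        mean=float(accs.mean()),
        ci=ci,
        accuracies=accs,
    )


def binwise_subpopulations(
    bin_labels: np.ndarray,
    rule: str,
    threshold_method_labels: np.ndarray | None = None,
) -> dict:
    """Neuron subsets for population decoding from per-bin shared-code labels.

    * ``any_shared``: indices of neurons with >=1 shared bin (global set).
    * ``only_shared_threshold``: neurons whose labeled bins under the
      threshold method are all shared (and nonempty); uses
      ``threshold_method_labels`` if given, else ``bin_labels``.
    * ``per_bin_shared``: bin -> indices of neurons shared in that bin.
    """
    labels = np.asarray(bin_labels)
    if rule == "any_shared":
        return {"neurons": np.nonzero((labels == SHARED).any(axis=1))[0]}
    if rule == "only_shared_threshold":
        src = labels if threshold_method_labels is None else np.asarray(threshold_method_labels)
        labeled = (src == SHARED) | (src == NON_SHARED)
        all_shared = (src == SHARED).any(axis=1) & ~((src == NON_SHARED).any(axis=1))
        has_label = labeled.any(axis=1)
        return {"neurons": np.nonzero(all_shared & has_label)[0]}
    if rule == "per_bin_shared":
        return {
            "per_bin": {
                b: np.nonzero(labels[:, b] == SHARED)[0] for b in range(labels.shape[1])
            }
        }
    raise ValueError(f"unknown rule {rule!r}")
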