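"""Per-bin action coding: does the discharge rate depend on the action?

For every neuron, relative-time bin and task, a Kruskal–Wallis test compares
the per-trial discharge rates of the three actions.  Rejections are
Benjamini–Hochberg corrected within one family per task (all neurons × all
24 bins).  The action-period summaries (coding on execution, on observation,
on both, on observation only) are computed on the 12 action-period bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import BinnedNeuron, action_period_slice
from .stats import bh_reject, kruskal_wallis
from .timebase import N_BINS

__all__ = ["CodingTable", "coding_flags"]


@dataclass
class CodingTable:
    """Bin-wise action-coding decisions for a population.

    ``p_exe``/``p_obs`` are (n_neurons, 24) raw Kruskal–Wallis p-values (NaN
    where a bin had an empty trial group and was excluded from the family);
    ``rej_exe``/``rej_obs`` the BH rejection flags.
    """

    neuron_ids: list[int]
    p_exe: np.ndarray
    p_obs: np.ndarray
    rej_exe: np.ndarray
    rej_obs: np.ndarray
    alpha: float
    n_excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    # -- action-period views (n_neurons, 12) -------------------------------
    def exe_coding(self) -> np.ndarray:
        return self.rej_exe[:, action_period_slice()]

    def obs_coding(self) -> np.ndarray:
        return self.rej_obs[:, action_period_slice()]

    def both_coding(self) -> np.ndarray:
        return self.exe_coding() & self.obs_coding()

    def obs_only(self) -> np.ndarray:
        return self.obs_coding() & ~self.exe_coding()

    def family_size(self, task: str) -> int:
        p = self.p_exe if task == "execution" else self.p_obs
        return int(np.sum(~np.isnan(p)))


def _task_pvalues(population: list[BinnedNeuron], task: str) -> tuple[np.ndarray, int]:
    n = len(population)
    p = np.full((n, N_BINS), np.nan)
    excluded = 0
    for i, neuron in enumerate(population):
        for b in range(N_BINS):
            groups = neuron.task_rates(task, b)
            if any(g.size == 0 for g in groups):
                excluded += 1
                continue
            _, p[i, b] = kruskal_wallis(groups)
    return p, excluded


def coding_flags(population: list[BinnedNeuron], alpha: float = 0.05) -> CodingTable:
    """Kruskal–Wallis action-coding flags with one BH family per task.

    The family size per task is the number of testable (neuron, bin) cells,
    i.e. n_neurons × 24 minus bins excluded for empty trial groups.
    """
    n = len(population)
    rej = {}
    pvals = {}
    excluded = {}
    for task in ("execution", "observation"):
        p, n_exc = _task_pvalues(population, task)
        valid = ~np.isnan(p)
        r = np.zeros_like(p, dtype=bool)
        r[valid] = bh_reject(p[valid], alpha=alpha, m=int(valid.sum()))
        pvals[task], rej[task], excluded[task] = p, r, n_exc
    return CodingTable(
        neuron_ids=[p_.neuron_id for p_ in population],
        p_exe=pvals["execution"],
        p_obs=pvals["observation"],
        rej_exe=rej["execution"],
        rej_obs=rej["observation"],
        alpha=alpha,
        n_excluded=excluded,
    )
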