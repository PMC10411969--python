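"""Shared-code decisions for bins coding actions in both tasks.

Three alternative criteria decide, per (neuron, action-period bin) coding in
both execution and observation, whether the action→discharge mapping is
shared between the tasks:

* same discharge ("Dis"): per action, a two-sided rank-sum test of execution
  vs observation rates; shared iff no action differs (after BH over all
  examined bins × 3 actions).
* same preference ("Pref"): bootstrap the positive and negative
  action-preference similarity indices; shared iff either index is
  significantly equal to 1 (BH over examined bins × 2 polarities).
* cross-task classification ("LDA"): shared iff an execution-trained
  diagonal-LDA classifier predicts observed actions above chance (bootstrap
  p = fraction of resamples with accuracy <= 1/3, BH over examined bins).

Everything here operates on (execution-source, observation-source) neuron
pairs so that the independence permutation null — which re-pairs execution
and observation data across neurons — can run the identical code path.

Bootstrap resampling draws indices into canonically sorted per-condition
rate values, which makes every p-value exactly invariant to trial order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .action_coding import CodingTable
from .records import ACTIONS, BinnedNeuron
from .stats import bh_reject, rank_sum_matrix
from .timebase import ACTION_PERIOD_BINS

__all__ = [
    "NONE",
    "SHARED",
    "NON_SHARED",
    "OBS_ONLY",
    "LABEL_NAMES",
    "CHANCE",
    "MODES",
    "AccuracyDist",
    "preference_index",
    "classifier_accuracies",
    "same_discharge",
    "same_preference",
    "cross_task_shared",
    "shared_labels",
]

# bin labels
NONE, SHARED, NON_SHARED, OBS_ONLY = 0, 1, 2, 3
LABEL_NAMES = ("none", "shared", "non_shared", "obs_only")

CHANCE = 1.0 / 3.0

#: classifier modes: mode -> (training task, test task)
MODES = {
    "e2e": ("execution", "execution"),
    "o2o": ("observation", "observation"),
    "e2o": ("execution", "observation"),
    "o2e": ("observation", "execution"),
}

_FLOOR_TOL = 1e-12  # guards 0.999999... from float division before flooring

Pair = tuple[BinnedNeuron, BinnedNeuron]


# ---------------------------------------------------------------------------
# preference similarity index
# ---------------------------------------------------------------------------

def _positive_indicator(means: np.ndarray) -> np.ndarray:
    """1 for the highest-rate action(s), 0 otherwise (last axis = actions)."""
    m = np.asarray(means, dtype=float)
    top = m.max(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ind = np.floor(m / top + _FLOOR_TOL)
    # an all-zero vector prefers nothing in particular: every action marked
    ind = np.where(np.broadcast_to(top > 0, m.shape), ind, 1.0)
    return ind.astype(np.int64)


def _negative_indicator(means: np.ndarray) -> np.ndarray:
    """1 for the lowest-rate action(s), 0 otherwise."""
    m = np.asarray(means, dtype=float)
    w = m - m.max(axis=-1, keepdims=True)
    low = w.min(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ind = np.floor(w / low + _FLOOR_TOL)
    ind = np.where(np.broadcast_to(low < 0, m.shape), ind, 1.0)
    return ind.astype(np.int64)


def preference_index(
    exe_means: np.ndarray, obs_means: np.ndarray, polarity: str = "positive"
) -> float:
    """Action-preference similarity index in [0, 1].

    Marks the highest-rate (positive) or lowest-rate (negative) action(s) of
    each task with an indicator vector, unit-normalises, and returns the dot
    product: 1 means identical preference, 0 disjoint preference.
    """
    exe = np.asarray(exe_means, dtype=float)
    obs = np.asarray(obs_means, dtype=float)
    if exe.shape != (len(ACTIONS),) or obs.shape != (len(ACTIONS),):
        raise ValueError("expected one mean rate per action and task")
    if np.ptp(exe) == 0 or np.ptp(obs) == 0:
        raise ValueError("undefined index: all action means equal in one task")
    if polarity == "positive":
        ie, io = _positive_indicator(exe), _positive_indicator(obs)
    elif polarity == "negative":
        ie, io = _negative_indicator(exe), _negative_indicator(obs)
    else:
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    dot = int(np.dot(ie, io))
    return dot / np.sqrt(int(ie.sum()) * int(io.sum()))


# ---------------------------------------------------------------------------
# bootstrap 8-fold cross-validated diagonal-LDA accuracy (1 feature)
# ---------------------------------------------------------------------------

@dataclass
class AccuracyDist:
    """Bootstrap distribution of classifier accuracy for one (bin, mode)."""

    mode: str
    bin_index: int            # 0-based bin within the 24-bin grid
    accuracies: np.ndarray    # (n_boot,)
    mean: float
    p_vs_chance: float        # fraction of resamples with accuracy <= 1/3

    def ci(self, level: float = 95.0) -> tuple[float, float]:
        lo = (100.0 - level) / 2.0
        return tuple(np.percentile(self.accuracies, [lo, 100.0 - lo]))


def _pair_T(pair: Pair) -> int:
    """Trial budget: largest multiple of 8 <= min trials over the 6 conditions."""
    exe, obs = pair
    n_min = min(
        min(exe.rates[("execution", a)].shape[0] for a in ACTIONS),
        min(obs.rates[("observation", a)].shape[0] for a in ACTIONS),
    )
    return (n_min // 8) * 8


def _gather_sorted(vals: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """vals (C, 3, n); idx (C, B, 3, T) -> samples (C, B, 3, T)."""
    c = np.arange(vals.shape[0])[:, None, None, None]
    a = np.arange(vals.shape[1])[None, None, :, None]
    return vals[c, a, idx]


def _boot_cv_counts(
    train_vals: np.ndarray,
    test_vals: np.ndarray,
    T: int,
    n_boot: int,
    rng: np.random.Generator,
    same_task: bool,
    train_full: bool = False,
) -> np.ndarray:
    """Correct-classification counts per bootstrap resample.

    ``train_vals``/``test_vals``: (C, 3, n) sorted single-bin rate values per
    action for C cases.  Returns integer counts (C, n_boot) out of 24·(T/8)
    test decisions (8 folds × 3 actions × T/8 trials per fold).

    Per resample, T trials per condition are drawn with replacement and
    partitioned into 8 folds; the classifier is fit on the training task's
    7/8 (or on all T when ``train_full``) and tested on the held-out fold of
    the test task.  With one feature, equal priors and a pooled variance the
    diagonal-LDA decision is nearest-class-mean; ties go to the lowest class
    index, matching ``diag_lda_predict``.
    """
    C = train_vals.shape[0]
    m = T // 8
    idx_tr = rng.integers(0, train_vals.shape[2], size=(C, n_boot, 3, T))
    s_tr = _gather_sorted(train_vals, idx_tr)
    if same_task:
        s_te = s_tr
    else:
        idx_te = rng.integers(0, test_vals.shape[2], size=(C, n_boot, 3, T))
        s_te = _gather_sorted(test_vals, idx_te)
    folds_tr = s_tr.reshape(C, n_boot, 3, 8, m)
    fold_sums = folds_tr.sum(axis=-1)                    # (C, B, 3, 8)
    totals = fold_sums.sum(axis=-1)                      # (C, B, 3)
    if train_full:
        means = np.broadcast_to((totals / T)[..., None], fold_sums.shape)
    else:
        means = (totals[..., None] - fold_sums) / (T - m)
    means = means.transpose(0, 1, 3, 2)                  # (C, B, 8, 3class)
    x = s_te.reshape(C, n_boot, 3, 8, m).transpose(0, 1, 3, 2, 4)  # (C,B,8,3true,m)
    d2 = (x[..., None] - means[:, :, :, None, None, :]) ** 2       # (C,B,8,3t,m,3c)
    pred = np.argmin(d2, axis=-1)                        # ties -> lowest class
    truth = np.arange(3)[None, None, None, :, None]
    return (pred == truth).sum(axis=(2, 3, 4))           # (C, B)


def _pair_bin_values(pair: Pair, task: str, bin_index: int) -> np.ndarray:
    """(3, n) sorted per-action rate values of one task/bin of a pair."""
    source = pair[0] if task == "execution" else pair[1]
    vals = [np.sort(source.rates[(task, a)][:, bin_index]) for a in ACTIONS]
    return np.stack(vals)


def classifier_accuracies(
    neuron: BinnedNeuron,
    bins: np.ndarray | list[int] | None = None,
    modes: tuple[str, ...] = ("e2e", "o2o", "e2o", "o2e"),
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    train_full: bool = False,
) -> dict[tuple[int, str], AccuracyDist]:
    """Bootstrap 8-fold CV accuracy of single-neuron classifiers.

    ``bins`` are 0-based indices into the 24-bin grid (default: the 12
    action-period bins).  Raises when fewer than 8 trials per condition are
    available.
    """
    if rng is None:
        rng = np.random.default_rng()
    if bins is None:
        bins = ACTION_PERIOD_BINS
    pair = (neuron, neuron)
    T = _pair_T(pair)
    if T < 8:
        raise ValueError(
            f"neuron {neuron.neuron_id}: fewer than 8 trials in some condition, "
            "excluded from classification"
        )
    m = T // 8
    out: dict[tuple[int, str], AccuracyDist] = {}
    for b in bins:
        vals = {t: _pair_bin_values(pair, t, int(b)) for t in ("execution", "observation")}
        for mode in modes:
            tt, ts = MODES[mode]
            counts = _boot_cv_counts(
                vals[tt][None], vals[ts][None], T, n_boot, rng,
                same_task=(tt == ts), train_full=train_full,
            )[0]
            accs = counts / (24.0 * m)
            out[(int(b), mode)] = AccuracyDist(
                mode=mode,
                bin_index=int(b),
                accuracies=accs,
                mean=float(accs.mean()),
                p_vs_chance=float(np.mean(counts <= 8 * m)),
            )
    return out


# ---------------------------------------------------------------------------
# per-method p-values on (execution, observation) pairs
# ---------------------------------------------------------------------------

def _both_cases(both_mask: np.ndarray) -> list[tuple[int, int]]:
    """(pair index, action-period bin index) for every examined bin."""
    ii, jj = np.nonzero(both_mask)
    return list(zip(ii.tolist(), jj.tolist()))


def _discharge_pvalues(pairs: list[Pair], cases: list[tuple[int, int]]) -> np.ndarray:
    """Rank-sum p-values (n_cases, 3 actions): execution vs observation rates."""
    p = np.full((len(cases), 3), np.nan)
    groups: dict[tuple[int, int], list[tuple[int, int, np.ndarray, np.ndarray]]] = {}
    for ci, (i, j) in enumerate(cases):
        exe, obs = pairs[i]
        b = int(ACTION_PERIOD_BINS[j])
        for ai, a in enumerate(ACTIONS):
            ev = exe.rates[("execution", a)][:, b]
            ov = obs.rates[("observation", a)][:, b]
            groups.setdefault((ev.size, ov.size), []).append((ci, ai, ev, ov))
    for (ne, no), items in groups.items():
        x = np.stack([np.concatenate([ev, ov]) for _, _, ev, ov in items])
        pv = rank_sum_matrix(x, ne)
        for (ci, ai, _, _), val in zip(items, pv):
            p[ci, ai] = val
    return p


def _preference_pvalues(
    pairs: list[Pair],
    cases: list[tuple[int, int]],
    n_boot: int,
    rng: np.random.Generator,
    chunk_bytes: int = 1 << 27,
) -> np.ndarray:
    """Bootstrap p-values (n_cases, 2): positive and negative index < 1."""
    p = np.full((len(cases), 2), np.nan)
    # group cases by the 6 per-condition trial counts so sampling vectorises
    groups: dict[tuple[int, ...], list[int]] = {}
    vals_cache: list[list[np.ndarray]] = []
    for ci, (i, j) in enumerate(cases):
        exe, obs = pairs[i]
        b = int(ACTION_PERIOD_BINS[j])
        conds = [np.sort(exe.rates[("execution", a)][:, b]) for a in ACTIONS]
        conds += [np.sort(obs.rates[("observation", a)][:, b]) for a in ACTIONS]
        vals_cache.append(conds)
        groups.setdefault(tuple(v.size for v in conds), []).append(ci)
    for sizes, members in groups.items():
        max_n = max(sizes)
        per_case = n_boot * max_n * 8
        chunk = max(1, chunk_bytes // per_case)
        for lo in range(0, len(members), chunk):
            sub = members[lo : lo + chunk]
            C = len(sub)
            means = np.empty((C, n_boot, 6))
            for c_pos in range(6):
                vals = np.stack([vals_cache[ci][c_pos] for ci in sub])  # (C, L)
                idx = rng.integers(0, sizes[c_pos], size=(C, n_boot, sizes[c_pos]))
                means[:, :, c_pos] = np.take_along_axis(
                    vals[:, None, :], idx, axis=2
                ).mean(axis=2)
            exe_means = means[:, :, :3]
            obs_means = means[:, :, 3:]
            for pol, (fe, fo) in enumerate(
                (
                    (_positive_indicator(exe_means), _positive_indicator(obs_means)),
                    (_negative_indicator(exe_means), _negative_indicator(obs_means)),
                )
            ):
                dot = (fe * fo).sum(axis=-1)
                nn = fe.sum(axis=-1) * fo.sum(axis=-1)
                below_one = dot * dot < nn        # exact integer comparison
                frac = below_one.mean(axis=1)
                for k, ci in enumerate(sub):
                    p[ci, pol] = frac[k]
    return p


def _lda_pvalues(
    pairs: list[Pair],
    cases: list[tuple[int, int]],
    n_boot: int,
    rng: np.random.Generator,
    train_full: bool = False,
    chunk_bytes: int = 1 << 27,
) -> np.ndarray:
    """Bootstrap e2o p-values (n_cases,): accuracy <= chance."""
    p = np.full(len(cases), np.nan)
    groups: dict[tuple[int, int, int], list[int]] = {}
    tr_cache: list[np.ndarray] = []
    te_cache: list[np.ndarray] = []
    for ci, (i, j) in enumerate(cases):
        pair = pairs[i]
        b = int(ACTION_PERIOD_BINS[j])
        tr = _pair_bin_values(pair, "execution", b)
        te = _pair_bin_values(pair, "observation", b)
        tr_cache.append(tr)
        te_cache.append(te)
        T = _pair_T(pair)
        groups.setdefault((tr.shape[1], te.shape[1], T), []).append(ci)
    for (ntr, nte, T), members in groups.items():
        if T < 8:
            continue  # excluded from classification; p stays NaN
        m = T // 8
        per_case = n_boot * 72 * m * 8
        chunk = max(1, chunk_bytes // per_case)
        for lo in range(0, len(members), chunk):
            sub = members[lo : lo + chunk]
            tr = np.stack([tr_cache[ci] for ci in sub])
            te = np.stack([te_cache[ci] for ci in sub])
            counts = _boot_cv_counts(tr, te, T, n_boot, rng, same_task=False,
                                     train_full=train_full)
            frac = np.mean(counts <= 8 * m, axis=1)
            for k, ci in enumerate(sub):
                p[ci] = frac[k]
    return p


# ---------------------------------------------------------------------------
# label assembly and public per-method entry points
# ---------------------------------------------------------------------------

def _assemble(
    both_mask: np.ndarray,
    obs_only_mask: np.ndarray,
    cases: list[tuple[int, int]],
    shared_flags: np.ndarray,
) -> np.ndarray:
    labels = np.full(both_mask.shape, NONE, dtype=np.int8)
    labels[obs_only_mask] = OBS_ONLY
    for (i, j), s in zip(cases, shared_flags):
        labels[i, j] = SHARED if s else NON_SHARED
    return labels


def shared_labels(
    method: str,
    pairs: list[Pair],
    both_mask: np.ndarray,
    obs_only_mask: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    train_full: bool = False,
) -> np.ndarray:
    """Label matrix (n_pairs, 12) in {none, shared, non_shared, obs_only}.

    BH families follow the method definitions: examined-bins × 3 (discharge),
    × 2 (preference), × 1 (cross-task LDA).
    """
    cases = _both_cases(both_mask)
    if rng is None:
        rng = np.random.default_rng()
    if not cases:
        return _assemble(both_mask, obs_only_mask, cases, np.zeros(0, dtype=bool))
    if method == "discharge":
        p = _discharge_pvalues(pairs, cases)
        rej = bh_reject(p.ravel(), alpha=alpha).reshape(p.shape)
        shared = ~rej.any(axis=1)
    elif method == "preference":
        p = _preference_pvalues(pairs, cases, n_boot, rng)
        rej = bh_reject(p.ravel(), alpha=alpha).reshape(p.shape)
        shared = rej.any(axis=1)
    elif method == "lda":
        p = _lda_pvalues(pairs, cases, n_boot, rng, train_full=train_full)
        valid = ~np.isnan(p)
        rej = np.zeros_like(valid)
        if valid.any():
            rej[valid] = bh_reject(p[valid], alpha=alpha, m=int(valid.sum()))
        shared = rej
    else:
        raise ValueError(f"unknown method {method!r}")
    return _assemble(both_mask, obs_only_mask, cases, shared)


def cross_task_labels_from_pvalues(
    coding: CodingTable, p_e2o: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Cross-task labels from precomputed e2o bootstrap p-values (n, 12).

    Lets a pipeline that already ran the classifier bootstrap for every bin
    reuse those p-values instead of re-bootstrapping the examined bins.
    """
    both = coding.both_coding()
    cases = _both_cases(both)
    p = np.array([p_e2o[i, j] for i, j in cases])
    valid = ~np.isnan(p)
    rej = np.zeros_like(valid)
    if valid.any():
        rej[valid] = bh_reject(p[valid], alpha=alpha, m=int(valid.sum()))
    return _assemble(both, coding.obs_only(), cases, rej)


def _identity_pairs(population: list[BinnedNeuron]) -> list[Pair]:
    return [(n, n) for n in population]


def same_discharge(
    population: list[BinnedNeuron], coding: CodingTable, alpha: float = 0.05
) -> np.ndarray:
    """Same-discharge labels: shared iff no action's rate differs between tasks."""
    return shared_labels(
        "discharge", _identity_pairs(population), coding.both_coding(),
        coding.obs_only(), alpha=alpha,
    )


def same_preference(
    population: list[BinnedNeuron],
    coding: CodingTable,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> np.ndarray:
    """Same-preference labels: shared iff an index is significantly equal to 1."""
    return shared_labels(
        "preference", _identity_pairs(population), coding.both_coding(),
        coding.obs_only(), n_boot=n_boot, rng=rng, alpha=alpha,
    )


def cross_task_shared(
    population: list[BinnedNeuron],
    coding: CodingTable,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    train_full: bool = False,
) -> np.ndarray:
    """Cross-task classification labels: shared iff e2o beats chance (BH)."""
    return shared_labels(
        "lda", _identity_pairs(population), coding.both_coding(),
        coding.obs_only(), n_boot=n_boot, rng=rng, alpha=alpha,
        train_full=train_full,
    )
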