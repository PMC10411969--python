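"""Synthetic populations of trial-based spike recordings.

The generator emulates the structure of paired execution/observation
recordings from premotor cortex: per neuron, >=8 valid trials in each of the
six task x action conditions (execution/observation x lift/twist/shift), an
eight-event trial skeleton whose inter-event durations are drawn per task and
action, and inhomogeneous-Poisson spike trains whose rate is piecewise
constant over the 24 relative-time quartile bins.

Action dependence is planted per neuron according to one of four coding
profiles:

* ``shared``      — the same action→rate map in both tasks,
* ``non_shared``  — action-dependent in both tasks, but the map is cyclically
                    permuted between tasks (coding with different preference),
* ``obs_only``    — action-dependent during observation only,
* ``non_coding``  — action-independent.

Coding is confined to a per-neuron contiguous window of the 12 action-period
bins, mimicking the time-localised action segments seen in real recordings.
All profiles additionally carry an action-independent rate elevation over the
three action-period epochs in both tasks, so that simulated neurons pass the
Friedman-based mirror-neuron screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ACTIONS, CONDITIONS, TASKS, NeuronRecording, Trial
from .timebase import ACTION_PERIOD_BINS, N_BINS, TrialEvents, quartile_edges

__all__ = [
    "PROFILES",
    "INTERVALS",
    "DEFAULT_DURATIONS",
    "SimConfig",
    "GroundTruth",
    "draw_trial_events",
    "simulate_neuron",
    "simulate_population",
]

PROFILES = ("shared", "non_shared", "obs_only", "non_coding")

#: the seven inter-event intervals, in order
INTERVALS = ("bpr_led", "led_rls", "rls_tch", "tch_mov", "mov_hld", "hld_rew", "rew_wdr")

#: combined-interval key accepted in place of tch_mov + mov_hld; the
#: object-movement onset is then placed uniformly inside touch→hold
COMBINED_KEY = "tch_hld"

# Uniform duration bounds (ms) spanning the central 95% of observed epoch
# durations per actor and action.  The monkey performs the execution task,
# the human actor the observation task.
_MONKEY = {
    "twist": {"bpr_led": (1197, 4728), "led_rls": (224, 389), "rls_tch": (113, 219),
              "tch_hld": (140, 626), "hld_rew": (329, 804), "rew_wdr": (296, 1325)},
    "shift": {"bpr_led": (1242, 5211), "led_rls": (231, 404), "rls_tch": (112, 248),
              "tch_hld": (59, 672), "hld_rew": (328, 805), "rew_wdr": (316, 1380)},
    "lift": {"bpr_led": (1306, 4959), "led_rls": (221, 389), "rls_tch": (108, 243),
             "tch_hld": (199, 637), "hld_rew": (329, 803), "rew_wdr": (288, 700)},
}
_HUMAN = {
    "twist": {"bpr_led": (1029, 1507), "led_rls": (335, 662), "rls_tch": (203, 409),
              "tch_hld": (73, 287), "hld_rew": (329, 806), "rew_wdr": (229, 786)},
    "shift": {"bpr_led": (1030, 1513), "led_rls": (324, 663), "rls_tch": (213, 422),
              "tch_hld": (60, 297), "hld_rew": (328, 804), "rew_wdr": (276, 787)},
    "lift": {"bpr_led": (1029, 1510), "led_rls": (337, 679), "rls_tch": (231, 461),
             "tch_hld": (183, 550), "hld_rew": (330, 804), "rew_wdr": (257, 856)},
}

DEFAULT_DURATIONS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    **{("execution", a): dict(_MONKEY[a]) for a in ACTIONS},
    **{("observation", a): dict(_HUMAN[a]) for a in ACTIONS},
}


def _validate_duration_spec(spec: dict[str, tuple[float, float]]) -> None:
    keys = set(spec)
    explicit = set(INTERVALS)
    combined = (explicit - {"tch_mov", "mov_hld"}) | {COMBINED_KEY}
    if keys != explicit and keys != combined:
        raise ValueError(
            f"duration spec must cover {sorted(explicit)} or {sorted(combined)}; got {sorted(keys)}"
        )
    for name, (low, high) in spec.items():
        if not (0 < low <= high):
            raise ValueError(f"interval {name!r}: bounds must satisfy 0 < low <= high, got {(low, high)}")


@dataclass
class SimConfig:
    """Study conditions for a simulated population.

    Rates are in Hz; ``rate_effect`` is the offset added for the preferred
    action inside a neuron's coding window; ``epoch_modulation`` is the
    action-independent elevation over the action-period epochs that makes
    neurons pass the mirror-neuron screen.  ``coding_window`` bounds (in
    bins, inclusive) the length of the contiguous action-period window in
    which coding profiles are expressed.
    """

    n_neurons: int = 60
    trials_per_condition: int = 64
    duration_model: dict[tuple[str, str], dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DURATIONS.items()}
    )
    profile_mix: dict[str, float] = field(
        default_factory=lambda: {"shared": 0.2, "non_shared": 0.5, "obs_only": 0.1, "non_coding": 0.2}
    )
    rate_base: float = 10.0
    rate_effect: float = 20.0
    epoch_modulation: float = 20.0
    coding_window: tuple[int, int] = (1, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 8:
            raise ValueError("trials_per_condition must be >= 8")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if set(self.profile_mix) - set(PROFILES):
            raise ValueError(f"unknown profiles {set(self.profile_mix) - set(PROFILES)}")
        total = sum(self.profile_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"profile fractions must sum to 1, got {total}")
        for cond in CONDITIONS:
            if cond not in self.duration_model:
                raise ValueError(f"duration_model missing condition {cond}")
            _validate_duration_spec(self.duration_model[cond])
        lo, hi = self.coding_window
        if not (1 <= lo <= hi <= len(ACTION_PERIOD_BINS)):
            raise ValueError("coding_window must satisfy 1 <= lo <= hi <= 12")
        if self.rate_base < 0 or self.rate_base + self.epoch_modulation < 0:
            raise ValueError("rates must be nonnegative")
        if self.rate_base + self.epoch_modulation + self.rate_effect < 0:
            raise ValueError("rate_base + effects must be nonnegative")


@dataclass
class GroundTruth:
    """Planted coding structure of a simulated population.

    ``bin_code[i, j]`` is the true code class of neuron i in action-period
    bin j (one of the profile names or ``"none"``); ``preferred`` holds the
    planted preferred-action index per task (−1 where no action coding).
    """

    profiles: list[str]
    bin_code: np.ndarray                      # (n_neurons, 12) of str
    windows: np.ndarray                       # (n_neurons, 2) start, stop (0-based, action-period coords)
    preferred: dict[str, np.ndarray]          # task -> (n_neurons,) action index or -1

    def profile_counts(self) -> dict[str, int]:
        return {p: sum(1 for q in self.profiles if q == p) for p in PROFILES}


def draw_trial_events(
    task: str,
    action: str,
    duration_model: dict[tuple[str, str], dict[str, tuple[float, float]]],
    rng: np.random.Generator,
) -> TrialEvents:
    """Draw one trial's eight event times (ms, BPR at 0).

    Inter-event durations are uniform on the configured bounds.  When the
    touch→hold interval is given combined, the object-movement onset is
    placed uniformly inside it.
    """
    spec = duration_model.get((task, action))
    if spec is None:
        raise ValueError(f"duration model has no entry for {(task, action)}")
    _validate_duration_spec(spec)

    def draw(name: str) -> float:
        low, high = spec[name]
        return float(rng.uniform(low, high))

    bpr = 0.0
    led = bpr + draw("bpr_led")
    rls = led + draw("led_rls")
    tch = rls + draw("rls_tch")
    if COMBINED_KEY in spec:
        hld = tch + draw(COMBINED_KEY)
        mov = tch + rng.uniform(0.0, 1.0) * (hld - tch)
        if not (tch < mov < hld):  # guard the measure-zero edge draws
            mov = 0.5 * (tch + hld)
    else:
        mov = tch + draw("tch_mov")
        hld = mov + draw("mov_hld")
    rew = hld + draw("hld_rew")
    wdr = rew + draw("rew_wdr")
    return TrialEvents(bpr, led, rls, tch, mov, hld, rew, wdr)


def _rate_maps(
    profile: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, int], np.ndarray]:
    """Draw preferred-action indices per task and the coding window.

    Returns (preferred: task -> action index or −1, window (start, stop)
    0-based in action-period coordinates, stop exclusive).
    """
    length = int(rng.integers(cfg.coding_window[0], cfg.coding_window[1] + 1))
    start = int(rng.integers(0, len(ACTION_PERIOD_BINS) - length + 1))
    window = np.array([start, start + length])
    pref_exe = int(rng.integers(0, len(ACTIONS)))
    if profile == "shared":
        preferred = {"execution": pref_exe, "observation": pref_exe}
    elif profile == "non_shared":
        preferred = {"execution": pref_exe, "observation": (pref_exe + 1) % len(ACTIONS)}
    elif profile == "obs_only":
        preferred = {"execution": -1, "observation": pref_exe}
    elif profile == "non_coding":
        preferred = {"execution": -1, "observation": -1}
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return preferred, window


def _bin_rate_vector(
    cfg: SimConfig, task: str, action: str, preferred: dict[str, int], window: np.ndarray
) -> np.ndarray:
    """Planted per-bin rate (Hz) for one condition of one neuron."""
    rates = np.full(N_BINS, cfg.rate_base)
    rates[ACTION_PERIOD_BINS] += cfg.epoch_modulation
    pref = preferred[task]
    if pref >= 0 and ACTIONS[pref] == action:
        coding_bins = ACTION_PERIOD_BINS[window[0] : window[1]]
        rates[coding_bins] += cfg.rate_effect
    return rates


def _poisson_spikes(edges: np.ndarray, rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant-rate Poisson spike times over the bin grid (ms)."""
    widths_s = np.diff(edges) / 1000.0
    counts = rng.poisson(rates * widths_s)
    spikes = [
        rng.uniform(edges[i], edges[i + 1], size=c) for i, c in enumerate(counts) if c > 0
    ]
    if not spikes:
        return np.empty(0)
    return np.sort(np.concatenate(spikes))


def simulate_neuron(
    profile: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    neuron_id: int = 0,
) -> tuple[NeuronRecording, dict]:
    """Simulate one neuron's trials under a planted coding profile.

    Returns the recording and a metadata dict (preferred actions per task and
    the coding window in action-period coordinates).
    """
    preferred, window = _rate_maps(profile, cfg, rng)
    trials: list[Trial] = []
    for task, action in CONDITIONS:
        rates = _bin_rate_vector(cfg, task, action, preferred, window)
        for _ in range(cfg.trials_per_condition):
            events = draw_trial_events(task, action, cfg.duration_model, rng)
            grid = quartile_edges(events)
            spikes = _poisson_spikes(grid.edges, rates, rng)
            trials.append(Trial(task=task, action=action, events=events, spikes=spikes))
    rec = NeuronRecording(neuron_id=neuron_id, trials=trials)
    meta = {"profile": profile, "preferred": preferred, "window": window}
    return rec, meta


def _profile_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n neurons over the profile mix."""
    fracs = np.array([mix.get(p, 0.0) for p in PROFILES])
    raw = fracs * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return {p: int(c) for p, c in zip(PROFILES, counts)}


def simulate_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[NeuronRecording], GroundTruth]:
    """Simulate a population with planted profile fractions.

    Deterministic given the config (its ``seed`` is used when no generator is
    passed).  Profile counts follow the mix exactly up to rounding.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    counts = _profile_counts(cfg.profile_mix, cfg.n_neurons)
    profiles = [p for p in PROFILES for _ in range(counts[p])]
    recordings: list[NeuronRecording] = []
    n_ap = len(ACTION_PERIOD_BINS)
    bin_code = np.full((cfg.n_neurons, n_ap), "none", dtype=object)
    windows = np.zeros((cfg.n_neurons, 2), dtype=int)
    preferred = {t: np.full(cfg.n_neurons, -1, dtype=int) for t in TASKS}
    for i, profile in enumerate(profiles):
        rec, meta = simulate_neuron(profile, cfg, rng, neuron_id=i)
        recordings.append(rec)
        windows[i] = meta["window"]
        for t in TASKS:
            preferred[t][i] = meta["preferred"][t]
        if profile != "non_coding":
            bin_code[i, meta["window"][0] : meta["window"][1]] = profile
    truth = GroundTruth(
        profiles=profiles, bin_code=bin_code, windows=windows, preferred=preferred
    )
    return recordings, truth
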