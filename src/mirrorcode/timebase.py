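"""Event-anchored relative-time representation of trials.

A trial is anchored to eight mechanosensor events (start-button press BPR,
LED onset, start-button release RLS, object touch TCH, object-movement onset
MOV, hold onset HLD, reward REW, withdrawal WDR).  Because the absolute
durations between events vary across trials, actions and actors, analyses run
on a relative time axis: each of the six inter-event epochs (MOV excluded) is
divided into four equal-duration quartile bins, giving 24 bins per trial.
Discharge rates are computed per bin in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EVENT_NAMES",
    "GRID_EVENTS",
    "N_BINS",
    "N_EPOCHS",
    "ACTION_PERIOD_BINS",
    "TrialEvents",
    "BinGrid",
    "EpochWindows",
    "quartile_edges",
    "bin_rates",
    "epoch_windows",
]

#: the eight registered events, in temporal order
EVENT_NAMES = ("bpr", "led", "rls", "tch", "mov", "hld", "rew", "wdr")

#: the seven events spanning the 24-bin grid (MOV is not a grid node)
GRID_EVENTS = ("bpr", "led", "rls", "tch", "hld", "rew", "wdr")

N_EPOCHS = 6
N_BINS = 24

#: 0-based indices of the 12 action-period bins (start-button release to
#: reward, i.e. epochs RLS→TCH, TCH→HLD and HLD→REW; bins 9..20 1-based)
ACTION_PERIOD_BINS = np.arange(8, 20)


@dataclass(frozen=True)
class TrialEvents:
    """Event timestamps (ms) on a per-trial clock with BPR at 0."""

    bpr: float
    led: float
    rls: float
    tch: float
    mov: float
    hld: float
    rew: float
    wdr: float

    def __post_init__(self) -> None:
        times = self.as_array()
        if self.bpr != 0.0:
            raise ValueError(f"BPR must be 0 on the per-trial clock, got {self.bpr}")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ValueError(
                "event times must be strictly increasing: "
                f"{EVENT_NAMES[i]}={times[i]} !< {EVENT_NAMES[i + 1]}={times[i + 1]}"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.bpr, self.led, self.rls, self.tch, self.mov, self.hld, self.rew, self.wdr],
            dtype=float,
        )

    def grid_nodes(self) -> np.ndarray:
        """The 7 event times spanning the 24-bin grid (MOV dropped)."""
        return np.array(
            [self.bpr, self.led, self.rls, self.tch, self.hld, self.rew, self.wdr],
            dtype=float,
        )


@dataclass(frozen=True)
class BinGrid:
    """25 bin edges (ms) over BPR→WDR and the epoch index of each bin.

    Bins are half-open ``[edge_i, edge_{i+1})``; each of the six epochs
    contributes four equal-width quartile bins.
    """

    edges: np.ndarray       # (25,)
    epoch_index: np.ndarray  # (24,) values 0..5

    @property
    def widths_ms(self) -> np.ndarray:
        return np.diff(self.edges)


@dataclass(frozen=True)
class EpochWindows:
    """The five epoch windows of the mirror-neuron screen, as [start, stop) ms.

    baseline is LED−750..LED−250 (truncated at BPR when it would start before
    trial onset, with ``baseline_truncated`` set); approach RLS→TCH;
    manipulation-I TCH→MOV; manipulation-II MOV→HLD; hold HLD→HLD+150.
    """

    baseline: tuple[float, float]
    approach: tuple[float, float]
    manipulation1: tuple[float, float]
    manipulation2: tuple[float, float]
    hold: tuple[float, float]
    baseline_truncated: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.baseline, self.approach, self.manipulation1, self.manipulation2, self.hold],
            dtype=float,
        )


def quartile_edges(events: TrialEvents) -> BinGrid:
    """Build the 24-bin relative-time grid for one trial.

    Each of the six inter-event epochs (BPR→LED, LED→RLS, RLS→TCH, TCH→HLD,
    HLD→REW, REW→WDR) is split into four equal-duration quartile bins.
    """
    nodes = events.grid_nodes()
    # 4 interior points per epoch via linear interpolation
    edges = np.empty(N_BINS + 1)
    for e in range(N_EPOCHS):
        edges[4 * e : 4 * e + 5] = np.linspace(nodes[e], nodes[e + 1], 5)
    epoch_index = np.repeat(np.arange(N_EPOCHS), 4)
    return BinGrid(edges=edges, epoch_index=epoch_index)


def bin_rates(spike_times: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Per-bin discharge rates in Hz (spike count / bin width).

    Spikes outside ``[BPR, WDR)`` are ignored; interior edges follow the
    half-open convention (a spike exactly on an edge belongs to the bin on
    its right).
    """
    spikes = np.asarray(spike_times, dtype=float)
    counts, _ = np.histogram(spikes, bins=grid.edges)
    # np.histogram closes the last bin on the right; match the half-open
    # convention by dropping spikes exactly at WDR
    if counts[-1] and np.any(spikes == grid.edges[-1]):
        counts[-1] -= int(np.sum(spikes == grid.edges[-1]))
    widths_s = grid.widths_ms / 1000.0
    return counts / widths_s


def epoch_windows(events: TrialEvents) -> EpochWindows:
    """The five analysis windows used by the mirror-neuron screen."""
    start = events.led - 750.0
    truncated = start < events.bpr
    if truncated:
        start = events.bpr
    stop = events.led - 250.0
    if stop <= start:
        raise ValueError("baseline window empty: LED onset too close to trial start")
    return EpochWindows(
        baseline=(start, stop),
        approach=(events.rls, events.tch),
        manipulation1=(events.tch, events.mov),
        manipulation2=(events.mov, events.hld),
        hold=(events.hld, events.hld + 150.0),
        baseline_truncated=bool(truncated),
    )


def window_rate(spike_times: np.ndarray, window: tuple[float, float]) -> float:
    """Discharge rate (Hz) inside a half-open [start, stop) window."""
    start, stop = window
    spikes = np.asarray(spike_times, dtype=float)
    n = int(np.sum((spikes >= start) & (spikes < stop)))
    return n / ((stop - start) / 1000.0)
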