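"""Action segments: maximal runs of consecutive bins with one code type.

A segment is a maximal run of action-period bins carrying the same code
type, shared or non-shared, where bins coding the action only during
observation count as non-shared; bins without observed-action coding break
runs.  With 12 bins there are 12·13/2 = 78 possible (start, duration)
segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shared_code import NON_SHARED, OBS_ONLY, SHARED

__all__ = ["Segment", "extract_segments", "segment_histogram", "n_possible_segments"]

N_ACTION_BINS = 12


@dataclass(frozen=True)
class Segment:
    neuron: int
    code_type: str          # "shared" | "non_shared"
    start: int              # 1-based action-period bin
    duration: int           # bins

    def __post_init__(self) -> None:
        if not (1 <= self.start <= N_ACTION_BINS and 1 <= self.duration <= N_ACTION_BINS):
            raise ValueError("segment outside the 12-bin action period")
        if self.start + self.duration - 1 > N_ACTION_BINS:
            raise ValueError("segment extends past the action period")


def extract_segments(bin_labels: np.ndarray, neuron: int = 0) -> list[Segment]:
    """Maximal same-code segments of one neuron's 12 action-period labels.

    ``bin_labels`` uses the shared_code label constants; obs_only bins merge
    into non-shared, ``none`` bins break runs.
    """
    labels = np.asarray(bin_labels).ravel()
    if labels.size != N_ACTION_BINS:
        raise ValueError(f"expected {N_ACTION_BINS} labels, got {labels.size}")
    merged = np.where(labels == OBS_ONLY, NON_SHARED, labels)
    segments: list[Segment] = []
    start = None
    current = None
    for i, lab in enumerate(list(merged) + [0]):  # sentinel flushes the last run
        if lab in (SHARED, NON_SHARED):
            if current == lab:
                continue
            if current is not None:
                segments.append(_make(neuron, current, start, i))
            start, current = i, int(lab)
        else:
            if current is not None:
                segments.append(_make(neuron, current, start, i))
            start, current = None, None
    return segments


def _make(neuron: int, code: int, start0: int, stop0: int) -> Segment:
    return Segment(
        neuron=neuron,
        code_type="shared" if code == SHARED else "non_shared",
        start=start0 + 1,
        duration=stop0 - start0,
    )


def segment_histogram(
    segments: list[Segment], normalize: bool = False
) -> dict[str, np.ndarray]:
    """12×12 (start, duration) count matrix per code type.

    Normalised counts divide by the total number of bins of that code type
    (the sum of its segment durations).
    """
    out: dict[str, np.ndarray] = {}
    for code in ("shared", "non_shared"):
        mat = np.zeros((N_ACTION_BINS, N_ACTION_BINS))
        total_bins = 0
        for s in segments:
            if s.code_type != code:
                continue
            mat[s.start - 1, s.duration - 1] += 1
            total_bins += s.duration
        if normalize and total_bins > 0:
            mat /= total_bins
        out[code] = mat
    return out


def n_possible_segments(n_bins: int) -> int:
    """Number of distinct (start, duration) segments in ``n_bins`` bins."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return n_bins * (n_bins + 1) // 2
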