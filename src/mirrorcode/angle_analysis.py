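"""Accuracy-angle analysis of e2o vs o2o classifier accuracies.

Each (neuron, action-period bin) contributes a point whose coordinates are
the e2o and o2o accuracies relative to chance (percentage points).  The
angle atan2(e2o_rel, o2o_rel) places shared-like bins near the unity line
(45°) and bins whose execution-trained classifier is at chance near 0°.
After filtering on o2o accuracy (thresholds 5–15 points above chance), a
one- and a two-Gaussian model are fit to the angle histogram by nonlinear
least squares; the two-Gaussian trough between the fitted peaks is the
boundary separating shared-like from non-shared-like bins, averaged across
thresholds.  The "threshold method" labels bins shared or non-shared from
that boundary alone, without any per-bin statistical test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .shared_code import CHANCE, NON_SHARED, NONE, SHARED

__all__ = [
    "AngleSet",
    "GaussianFit",
    "BoundaryResult",
    "accuracy_angle",
    "angle_points",
    "fit_angle_mixture",
    "boundary_over_thresholds",
    "threshold_labels",
]

HIST_RANGE = (-90.0, 90.0)
DEFAULT_BIN_WIDTH = 2.0   # degrees
MIN_POINTS = 30
RETRY_BUDGET = 50
MIN_MODE_SEPARATION = 5.0  # degrees between fitted centers to count as two modes
GRID_STEP = 0.1            # degrees, for peak/boundary extraction


def accuracy_angle(e2o_rel: float, o2o_rel: float) -> float:
    """Angle (degrees) of a point in the (o2o_rel, e2o_rel) plane.

    45° lies on the unity line (equal relative accuracies), 0° on the zero
    line (e2o at chance).  Undefined (NaN) when both inputs are 0.
    """
    e = np.asarray(e2o_rel, dtype=float)
    o = np.asarray(o2o_rel, dtype=float)
    angle = np.degrees(np.arctan2(e, o))
    return np.where((e == 0) & (o == 0), np.nan, angle)[()]


@dataclass
class AngleSet:
    """Accuracy-angle points for all (neuron, action-period bin) pairs."""

    neuron: np.ndarray    # (n_points,) neuron ids
    bin_index: np.ndarray  # (n_points,) 0-based action-period bin 0..11
    e2o_rel: np.ndarray   # percentage points above chance
    o2o_rel: np.ndarray
    angle: np.ndarray     # degrees; NaN where undefined
    n_undefined: int = 0

    def __len__(self) -> int:
        return self.angle.size

    def above(self, threshold: float) -> np.ndarray:
        """Mask of points with o2o accuracy strictly above threshold (pp)."""
        return self.o2o_rel > threshold

    def subset(self, mask: np.ndarray) -> "AngleSet":
        return AngleSet(
            neuron=self.neuron[mask],
            bin_index=self.bin_index[mask],
            e2o_rel=self.e2o_rel[mask],
            o2o_rel=self.o2o_rel[mask],
            angle=self.angle[mask],
            n_undefined=self.n_undefined,
        )


def angle_points(
    neuron_ids: list[int], e2o_mean: np.ndarray, o2o_mean: np.ndarray
) -> AngleSet:
    """Build the angle set from (n_neurons, 12) mean-accuracy matrices."""
    e2o_rel = (np.asarray(e2o_mean) - CHANCE) * 100.0
    o2o_rel = (np.asarray(o2o_mean) - CHANCE) * 100.0
    n, n_bins = e2o_rel.shape
    neuron = np.repeat(np.asarray(neuron_ids), n_bins)
    bins = np.tile(np.arange(n_bins), n)
    ang = accuracy_angle(e2o_rel.ravel(), o2o_rel.ravel())
    undefined = np.isnan(ang)
    keep = ~undefined
    return AngleSet(
        neuron=neuron[keep],
        bin_index=bins[keep],
        e2o_rel=e2o_rel.ravel()[keep],
        o2o_rel=o2o_rel.ravel()[keep],
        angle=ang[keep],
        n_undefined=int(undefined.sum()),
    )


@dataclass
class GaussianFit:
    """One- or two-Gaussian least-squares fit to an angle histogram."""

    k: int
    amplitudes: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    adj_r2: float
    residuals: np.ndarray
    threshold: float
    n_points: int
    peaks: tuple[float, ...] = ()
    boundary: float | None = None
    retries: int = 0
    success: bool = True


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for j in range(0, len(params), 3):
        a, b, c = params[j : j + 3]
        y = y + a * np.exp(-(((x - b) / c) ** 2))
    return y


def _histogram(angles: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(HIST_RANGE[0], HIST_RANGE[1] + bin_width / 2, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts.astype(float)


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    r2 = 1.0 - ss_res / ss_tot
    n = y.size
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _circular_mean_deg(angles: np.ndarray) -> float:
    rad = np.radians(angles)
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def _initial_guess(
    k: int, centers: np.ndarray, counts: np.ndarray, angles: np.ndarray
) -> np.ndarray:
    if k == 1:
        return np.array([counts.max(), _circular_mean_deg(angles), 20.0])
    heights = [max(counts[np.argmin(np.abs(centers - b))], 1.0) for b in (0.0, 45.0)]
    # the two reference lines of the scatter: e2o-at-chance (0°) and unity (45°)
    return np.array([heights[0], 0.0, 15.0, heights[1], 45.0, 15.0])


def _two_mode_geometry(params: np.ndarray) -> tuple[tuple[float, float], float] | None:
    """Peaks and trough of a two-Gaussian curve, or None if not bimodal."""
    b_lo, b_hi = sorted((params[1], params[4]))
    if b_hi - b_lo < MIN_MODE_SEPARATION or params[0] <= 0 or params[3] <= 0:
        return None
    grid = np.arange(HIST_RANGE[0], HIST_RANGE[1] + GRID_STEP / 2, GRID_STEP)
    # quantize before arg-extrema so sub-ULP differences between equally
    # converged fits cannot flip a near-tied grid cell
    y = np.round(_gauss_sum(grid, *params), 6)
    between = (grid >= b_lo) & (grid <= b_hi)
    if not between.any():
        return None
    boundary = float(grid[between][np.argmin(y[between])])
    left = grid <= boundary
    right = grid >= boundary
    p_lo = float(grid[left][np.argmax(y[left])])
    p_hi = float(grid[right][np.argmax(y[right])])
    y_b = y[np.argmin(np.abs(grid - boundary))]
    y_lo = y[np.argmin(np.abs(grid - p_lo))]
    y_hi = y[np.argmin(np.abs(grid - p_hi))]
    if not (p_lo < boundary < p_hi) or y_b >= min(y_lo, y_hi):
        return None
    return (p_lo, p_hi), boundary


def fit_angle_mixture(
    points: AngleSet,
    threshold: float,
    k: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
    rng: np.random.Generator | None = None,
) -> GaussianFit:
    """Least-squares k-Gaussian fit to the thresholded angle histogram.

    Points with o2o accuracy strictly above ``threshold`` (percentage points
    over chance) enter a histogram of ``bin_width``-degree bins, fit with
    Σ a_j exp(−((x−b_j)/c_j)²).  For k=2 the fit must exhibit two distinct
    modes (centers ≥ 5° apart, positive amplitudes, an interior trough);
    failed fits are retried with jittered initial centers (±10°, budget 50).
    Fewer than 30 points refuse the fit.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if rng is None:
        rng = np.random.default_rng(0)
    angles = points.angle[points.above(threshold)]
    if angles.size < MIN_POINTS:
        raise ValueError(
            f"only {angles.size} points above threshold {threshold}; need {MIN_POINTS}"
        )
    centers, counts = _histogram(angles, bin_width)
    guess = _initial_guess(k, centers, counts, angles)
    retries = 0
    params = None
    geometry = None

    def attempt(g):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")

                p, _ = curve_fit(_gauss_sum, centers, counts, p0=g, maxfev=5000)
        except RuntimeError:
            return None
        return p

    if k == 1:
        params = attempt(guess)
        while params is None and retries < RETRY_BUDGET:
            retries += 1
            g = guess.copy()
            g[1] += rng.uniform(-10.0, 10.0)
            params = attempt(g)
    else:
        # deterministic multi-start: fit from several fixed center pairs and
        # keep the lowest-SSE fit with valid two-mode geometry.  Selecting by
        # rounded SSE makes the winner stable even when a single trajectory
        # is numerically borderline.
        candidates = []
        for off_lo, off_hi in ((0.0, 0.0), (-5.0, -5.0), (5.0, 5.0)):
            g = guess.copy()
            g[1] += off_lo
            g[4] += off_hi
            p = attempt(g)
            if p is None:
                continue
            geom = _two_mode_geometry(p)
            if geom is None:
                continue
            sse = round(float(np.sum((counts - _gauss_sum(centers, *p)) ** 2)), 6)
            candidates.append((sse, len(candidates), p, geom))
        if candidates:
            _, _, params, geometry = min(candidates)
        else:
            while retries < RETRY_BUDGET:
                retries += 1
                g = guess.copy()
                g[1::3] = g[1::3] + rng.uniform(-10.0, 10.0, size=k)
                p = attempt(g)
                if p is None:
                    continue
                geom = _two_mode_geometry(p)
                if geom is not None:
                    params, geometry = p, geom
                    break
    if params is None:
        return GaussianFit(
            k=k, amplitudes=np.full(k, np.nan), centers=np.full(k, np.nan),
            widths=np.full(k, np.nan), adj_r2=np.nan,
            residuals=np.full(centers.size, np.nan), threshold=threshold,
            n_points=angles.size, retries=retries, success=False,
        )
    yhat = _gauss_sum(centers, *params)
    fit = GaussianFit(
        k=k,
        amplitudes=params[0::3],
        centers=params[1::3],
        widths=np.abs(params[2::3]),
        adj_r2=_adjusted_r2(counts, yhat, 3 * k),
        residuals=counts - yhat,
        threshold=threshold,
        n_points=angles.size,
        retries=retries,
    )
    if k == 2 and geometry is not None:
        fit.peaks, fit.boundary = geometry
    elif k == 1:
        fit.peaks = (float(params[1]),)
    return fit


@dataclass
class BoundaryResult:
    """Per-threshold two-Gaussian fits with bootstrap CIs and mean boundary."""

    thresholds: np.ndarray
    fits: list[GaussianFit]
    average_boundary: float
    ci_boundary: np.ndarray   # (n_thresholds, 2)
    ci_adj_r2: np.ndarray
    ci_peak_lower: np.ndarray
    ci_peak_upper: np.ndarray
    failure_rates: np.ndarray = field(default_factory=lambda: np.zeros(0))


def boundary_over_thresholds(
    points: AngleSet,
    thresholds: np.ndarray | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_failure_rate: float = 0.10,
) -> BoundaryResult:
    """Two-Gaussian boundary per threshold and its across-threshold average.

    Bootstrapping resamples the full point set with replacement, reapplies
    each threshold and refits; per-resample two-mode failures are counted
    and the analysis aborts if any threshold's failure rate exceeds 10%.
    """
    if thresholds is None:
        thresholds = np.arange(5.0, 16.0)
    if rng is None:
        rng = np.random.default_rng(0)
    fits = [fit_angle_mixture(points, t, k=2, bin_width=bin_width, rng=rng)
            for t in thresholds]
    for t, f in zip(thresholds, fits):
        if not f.success:
            raise RuntimeError(f"two-Gaussian fit failed on original sample at threshold {t}")
    n = len(points)
    boot = {
        "boundary": np.full((len(thresholds), n_boot), np.nan),
        "adj_r2": np.full((len(thresholds), n_boot), np.nan),
        "p_lo": np.full((len(thresholds), n_boot), np.nan),
        "p_hi": np.full((len(thresholds), n_boot), np.nan),
    }
    failures = np.zeros(len(thresholds), dtype=int)
    for r in range(n_boot):
        resample = points.subset(rng.integers(0, n, size=n))
        for ti, t in enumerate(thresholds):
            try:
                f = fit_angle_mixture(resample, t, k=2, bin_width=bin_width, rng=rng)
            except ValueError:  # too few points in this resample
                failures[ti] += 1
                continue
            if not f.success:
                failures[ti] += 1
                continue
            boot["boundary"][ti, r] = f.boundary
            boot["adj_r2"][ti, r] = f.adj_r2
            boot["p_lo"][ti, r], boot["p_hi"][ti, r] = f.peaks
    failure_rates = failures / n_boot
    if np.any(failure_rates > max_failure_rate):
        worst = thresholds[int(np.argmax(failure_rates))]
        raise RuntimeError(
            f"two-mode failure rate {failure_rates.max():.1%} at threshold {worst} "
            f"exceeds {max_failure_rate:.0%}"
        )

    def ci(key: str) -> np.ndarray:
        return np.stack([
            np.nanpercentile(boot[key][ti], [2.5, 97.5]) for ti in range(len(thresholds))
        ])

    return BoundaryResult(
        thresholds=np.asarray(thresholds, dtype=float),
        fits=fits,
        average_boundary=float(np.mean([f.boundary for f in fits])),
        ci_boundary=ci("boundary"),
        ci_adj_r2=ci("adj_r2"),
        ci_peak_lower=ci("p_lo"),
        ci_peak_upper=ci("p_hi"),
        failure_rates=failure_rates,
    )


def threshold_labels(
    points: AngleSet,
    boundary: float,
    threshold: float = 10.0,
    n_neurons: int | None = None,
    neuron_ids: list[int] | None = None,
) -> np.ndarray:
    """Shared/non-shared labels from the boundary angle alone.

    Bins with o2o accuracy strictly above ``threshold`` percentage points are
    labeled shared iff their angle is at or above the boundary; all other
    bins stay unlabeled.  Returns an (n_neurons, 12) label matrix.
    """
    if neuron_ids is None:
        neuron_ids = sorted(set(points.neuron.tolist()))
    index = {nid: i for i, nid in enumerate(neuron_ids)}
    n = n_neurons if n_neurons is not None else len(neuron_ids)
    labels = np.full((n, 12), NONE, dtype=np.int8)
    mask = points.above(threshold)
    for nid, b, ang in zip(points.neuron[mask], points.bin_index[mask], points.angle[mask]):
        labels[index[int(nid)], int(b)] = SHARED if ang >= boundary else NON_SHARED
    return labels
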