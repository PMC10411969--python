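import numpy as np
import pytest

import mirrorcode.angle_analysis as aa
from mirrorcode.angle_analysis import (
    AngleSet,
    accuracy_angle,
    angle_points,
    boundary_over_thresholds,
    fit_angle_mixture,
    threshold_labels,
)
from mirrorcode.shared_code import NON_SHARED, SHARED


def mixture_points(n=2000, centers=(2.0, 45.0), sds=(8.0, 8.0), weight=0.5,
                   seed=0, o2o_range=(0.0, 40.0)):
    """Synthetic angle set whose angles follow a two-Gaussian mixture."""
    rng = np.random.default_rng(seed)
    pick = rng.random(n) < weight
    ang = np.where(pick,
                   rng.normal(centers[0], sds[0], n),
                   rng.normal(centers[1], sds[1], n))
    o2o = rng.uniform(*o2o_range, n)
    e2o = o2o * np.tan(np.radians(ang))
    return AngleSet(neuron=np.repeat(np.arange((n + 11) // 12), 12)[:n],
                    bin_index=np.tile(np.arange(12), (n + 11) // 12)[:n],
                    e2o_rel=e2o, o2o_rel=o2o, angle=ang)


class TestAccuracyAngle:
    @pytest.mark.parametrize("e, o, expected", [
        (30.0, 30.0, 45.0),
        (0.0, 40.0, 0.0),
        (-10.0, 10.0, -45.0),
    ])
    def test_reference_lines(self, e, o, expected):
        assert np.isclose(accuracy_angle(e, o), expected)

    def test_undefined_at_origin(self):
        assert np.isnan(accuracy_angle(0.0, 0.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        e, o = rng.normal(size=20), rng.normal(size=20)
        assert np.allclose(accuracy_angle(e, o), accuracy_angle(3.7 * e, 3.7 * o))

    def test_angle_points_counts_undefined(self):
        e2o = np.full((2, 12), 1 / 3)
        o2o = np.full((2, 12), 1 / 3)
        pts = angle_points([0, 1], e2o, o2o)
        assert len(pts) == 0 and pts.n_undefined == 24


class TestFitAngleMixture:
    def test_single_gaussian_recovery(self):
        pts = mixture_points(n=2000, weight=1.0, centers=(10.0, 0.0), sds=(8.0, 8.0))
        f1 = fit_angle_mixture(pts, threshold=5.0, k=1)
        assert f1.success and abs(f1.centers[0] - 10.0) < 2.0
        f2 = fit_angle_mixture(pts, threshold=5.0, k=2)
        if f2.success:  # a second mode adds almost nothing on unimodal data
            assert f2.adj_r2 - f1.adj_r2 < 0.02

    def test_two_gaussian_recovery_with_boundary(self):
        pts = mixture_points(n=2000)
        f = fit_angle_mixture(pts, threshold=5.0, k=2)
        assert f.success
        assert abs(min(f.centers) - 2.0) < 3.0
        assert abs(max(f.centers) - 45.0) < 3.0
        assert min(f.centers) < f.boundary < max(f.centers)
        assert f.peaks[0] < f.boundary < f.peaks[1]

    def test_noise_free_histogram_fits_exactly(self):
        """Angles engineered so the histogram equals a two-Gaussian curve."""
        edges = np.arange(-90, 91, 2.0)
        centers = (edges[:-1] + edges[1:]) / 2
        curve = 40 * np.exp(-(((centers - 2) / 10) ** 2)) \
            + 30 * np.exp(-(((centers - 45) / 10) ** 2))
        counts = np.round(curve).astype(int)
        ang = np.repeat(centers, counts)
        pts = AngleSet(neuron=np.zeros(ang.size, int), bin_index=np.zeros(ang.size, int),
                       e2o_rel=np.ones(ang.size), o2o_rel=np.full(ang.size, 20.0),
                       angle=ang)
        f = fit_angle_mixture(pts, threshold=10.0, k=2)
        assert f.success
        assert f.adj_r2 > 0.99
        assert np.max(np.abs(f.residuals)) < 2.0

    def test_too_few_points_refused(self):
        pts = mixture_points(n=40, o2o_range=(0.0, 8.0))
        with pytest.raises(ValueError, match="points above threshold"):
            fit_angle_mixture(pts, threshold=7.9, k=2)

    def test_threshold_filter_monotone(self):
        pts = mixture_points(n=500)
        counts = [pts.above(t).sum() for t in np.arange(5.0, 16.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_bin_width_sensitivity(self):
        """Boundary moves < 3 degrees between 1- and 5-degree histogram bins."""
        pts = mixture_points(n=3000, seed=3)
        boundaries = [
            fit_angle_mixture(pts, threshold=5.0, k=2, bin_width=w).boundary
            for w in (1.0, 2.0, 5.0)
        ]
        assert max(boundaries) - min(boundaries) < 3.0


class _IdentityRng(np.random.Generator):
    """Generator whose bootstrap draws reproduce the original sample."""

    def __init__(self):
        super().__init__(np.random.PCG64(0))

    def integers(self, low, high=None, size=None, **kw):  # noqa: A003
        n = high if high is not None else low
        if isinstance(size, int):
            return np.arange(size) % n
        return np.broadcast_to(np.arange(size[-1]) % n, size).copy()


class TestBoundaryOverThresholds:
    def test_recovers_planted_centers_at_all_thresholds(self):
        pts = mixture_points(n=3000, seed=4)
        res = boundary_over_thresholds(pts, n_boot=60, rng=np.random.default_rng(5))
        assert res.thresholds.size == 11
        for ti in range(11):
            lo, hi = res.ci_peak_lower[ti]
            assert lo - 3 < 2.0 < hi + 3
            lo, hi = res.ci_peak_upper[ti]
            assert lo - 3 < 45.0 < hi + 3
        assert 2.0 < res.average_boundary < 45.0

    def test_degenerate_bootstrap_zero_width_cis(self):
        pts = mixture_points(n=2000, seed=6)
        res = boundary_over_thresholds(pts, n_boot=5, rng=_IdentityRng())
        assert np.allclose(res.ci_boundary[:, 0], res.ci_boundary[:, 1])

    def test_failure_rate_bookkeeping(self, monkeypatch):
        """Planted ~2% pathological resamples are reported as ~2% failures."""
        pts = mixture_points(n=2000, seed=7)
        real_fit = aa.fit_angle_mixture
        state = {"i": 0}

        def flaky(points, threshold, k, bin_width=2.0, rng=None):
            state["i"] += 1
            f = real_fit(points, threshold, k, bin_width=bin_width, rng=rng)
            if state["i"] % 50 == 0:  # every 50th call fails -> 2%
                f.success = False
            return f

        monkeypatch.setattr(aa, "fit_angle_mixture", flaky)
        res = aa.boundary_over_thresholds(pts, thresholds=np.array([5.0]),
                                          n_boot=200, rng=np.random.default_rng(8))
        assert abs(res.failure_rates[0] - 0.02) < 0.015

    def test_excessive_failures_abort(self, monkeypatch):
        pts = mixture_points(n=2000, seed=9)
        real_fit = aa.fit_angle_mixture

        def broken(points, threshold, k, bin_width=2.0, rng=None):
            f = real_fit(points, threshold, k, bin_width=bin_width, rng=rng)
            if rng is not None and rng.random() < 0.5:
                f.success = False
            return f

        monkeypatch.setattr(aa, "fit_angle_mixture", broken)
        with pytest.raises(RuntimeError, match="failure rate"):
            aa.boundary_over_thresholds(pts, thresholds=np.array([5.0]),
                                        n_boot=60, rng=np.random.default_rng(10))


class TestThresholdLabels:
    def test_label_conventions(self):
        pts = AngleSet(
            neuron=np.array([0, 0, 1, 1]),
            bin_index=np.array([0, 1, 0, 1]),
            e2o_rel=np.array([30.0, 2.0, 30.0, 5.0]),
            o2o_rel=np.array([30.0, 25.0, 10.0, 25.0]),
            angle=np.array([45.0, 5.0, 71.6, 11.3]),
        )
        labels = threshold_labels(pts, boundary=25.0, threshold=10.0, n_neurons=2,
                                  neuron_ids=[0, 1])
        assert labels[0, 0] == SHARED        # 45 >= 25
        assert labels[0, 1] == NON_SHARED    # 5 < 25
        assert labels[1, 0] == 0             # o2o_rel == 10 exactly: excluded
        assert labels[1, 1] == NON_SHARED
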