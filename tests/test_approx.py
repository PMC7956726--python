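import numpy as np
import pytest

import gaussecg as g
from gaussecg.approx import (DegenerateGridError, build_kernel, matched_scan,
                             sigma_bounds)


class TestSigmaBounds:
    @pytest.mark.parametrize("duration,n,smin,smax", [
        (0.1, 100, 0.005, 0.1 / 3),
        (0.3, 300, 0.005, 0.1),
    ])
    def test_limits_from_segment_length(self, duration, n, smin, smax):
        grid = sigma_bounds(duration, n)
        assert grid.sigma_min == pytest.approx(smin, rel=1e-12)
        assert grid.sigma_max == pytest.approx(smax, rel=1e-12)
        assert grid.values[0] == pytest.approx(smin, rel=1e-12)
        assert grid.values[-1] <= smax + 1e-15
        # 0.3-sample increments
        assert grid.step == pytest.approx(0.3 * duration / n, rel=1e-12)

    def test_degenerate_grid_on_short_segment(self):
        # 12 samples: sigma_min (5 sample intervals) exceeds duration/3
        with pytest.raises(DegenerateGridError):
            sigma_bounds(0.012, 12)


class TestBuildKernel:
    @pytest.mark.parametrize("ns,expected", [
        (4, [-1, 0, 1, 2]),
        (5, [-2, -1, 0, 1, 2, 3]),
    ])
    def test_support_range(self, ns, expected):
        k = build_kernel(0.01, ns, 0.001)
        assert list(k.support) == expected

    def test_center_weight_is_one(self):
        for sigma in (0.001, 0.05, 1.0):
            k = build_kernel(sigma, 7, 0.002)
            assert k.weights[list(k.support).index(0)] == 1.0
            assert np.all(k.weights > 0) and np.all(k.weights <= 1)

    def test_symmetry_excluding_extra_endpoint(self):
        # odd Ns appends one extra positive offset; the rest is symmetric
        k = build_kernel(0.02, 9, 0.003)
        w = k.weights[:-1]
        assert np.allclose(w, w[::-1], rtol=1e-14)


def single_gaussian_segment(n, center_idx, sigma_samples, amp=1.0, fs=360.0):
    t = np.arange(n) / fs
    x = amp * np.exp(-((t - center_idx / fs) ** 2) / (2 * (sigma_samples / fs) ** 2))
    return g.Signal(x, fs=fs)


class TestMatchedScan:
    def test_zero_segment(self):
        seg = g.Signal(np.zeros(50), fs=360.0)
        scan = matched_scan(seg, sigma_bounds(seg.duration, 50))
        assert scan.best.A1 == 0.0
        assert scan.best.t1 == 0.0
        assert scan.best.rmse == 0.0

    def test_single_gaussian_recovery(self):
        seg = single_gaussian_segment(100, center_idx=50, sigma_samples=3.0)
        fs = seg.fs
        # explicit grid covering 3 samples (default floor is 5 samples)
        step = 0.3 / fs
        values = np.arange(1.5 / fs, 10.0 / fs, step)
        grid = g.SigmaGrid(sigma_min=values[0], sigma_max=values[-1],
                           step=step, values=values)
        scan = matched_scan(seg, grid)
        assert abs(scan.best.t1 * fs - 50) <= 1.0
        assert abs(scan.best.sigma - 3.0 / fs) <= grid.step + 1e-15

    def test_dominant_center_of_two_gaussians(self):
        fs = 360.0
        t = np.arange(150) / fs
        x = (1.0 * np.exp(-((t - 40 / fs) ** 2) / (2 * (4 / fs) ** 2))
             + 0.3 * np.exp(-((t - 110 / fs) ** 2) / (2 * (5 / fs) ** 2)))
        seg = g.Signal(x, fs=fs)
        scan = matched_scan(seg, sigma_bounds(seg.duration, 150))
        assert abs(scan.best.t1 * fs - 40) <= 1.0

    def test_best_is_minimum_of_records(self):
        seg = single_gaussian_segment(80, 30, 4.0)
        scan = matched_scan(seg, sigma_bounds(seg.duration, 80))
        assert scan.best.rmse == min(r.rmse for r in scan.records)
        assert len(scan.records) == len(sigma_bounds(seg.duration, 80).values)

    def test_grid_refinement_never_worsens_best(self):
        seg = single_gaussian_segment(90, 40, 5.0)
        grid = sigma_bounds(seg.duration, 90)
        coarse = g.SigmaGrid(grid.sigma_min, grid.sigma_max, grid.step * 2,
                             grid.values[::2])
        r_coarse = matched_scan(seg, coarse).best.rmse
        r_full = matched_scan(seg, grid).best.rmse
        assert r_full <= r_coarse + 1e-15


class TestApproximate:
    def test_second_gaussian_is_exact_replica(self, p_segment):
        seg, _ = p_segment
        init, _ = g.approximate(seg, "P")
        assert init.A2 == init.A1
        assert init.t2 == init.t1
        assert init.sigma2 == init.sigma1

    def test_flat_segment_goes_to_baseline(self):
        seg = g.Signal(np.full(60, 0.3), fs=360.0)
        init, _ = g.approximate(seg, "T")
        assert init.A1 == pytest.approx(0.0, abs=1e-12)
        assert init.A2 == pytest.approx(0.0, abs=1e-12)
        assert init.c == pytest.approx(0.3, abs=1e-12)

    def test_bounds_contain_init(self, p_segment):
        seg, _ = p_segment
        init, bounds = g.approximate(seg, "P")
        assert bounds.contains(init.params)

    def test_refinement_never_worse_than_approximation(self, p_segment):
        seg, _ = p_segment
        init, bounds = g.approximate(seg, "P")
        t = np.arange(len(seg)) / seg.fs
        approx_rmse = float(np.sqrt(np.mean(
            (g.evaluate_component(init, t) - seg.samples) ** 2)))
        refined = g.local_refine(seg, init, bounds)
        assert refined.rmse <= approx_rmse + 1e-15
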