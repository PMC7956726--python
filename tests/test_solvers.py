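import numpy as np
import pytest

import gaussecg as g
from gaussecg.approx import Bounds


def rmse_of(model, seg):
    t = np.arange(len(seg)) / seg.fs
    return float(np.sqrt(np.mean((g.evaluate_component(model, t) - seg.samples) ** 2)))


def wide_bounds(seg, duration):
    amax = max(float(np.max(np.abs(seg.samples))), 1e-6)
    lo = np.array([-2 * amax, 0.0, 1e-4, -2 * amax, 0.0, 1e-4, -amax - 1e-6])
    hi = np.array([2 * amax, duration, duration, 2 * amax, duration, duration,
                   amax + 1e-6])
    return Bounds(lower=lo, upper=hi)


class TestLocalRefine:
    def test_start_at_truth_stays_at_truth(self, p_segment):
        seg, truth = p_segment
        bounds = wide_bounds(seg, truth.duration)
        res = g.local_refine(seg, truth, bounds)
        assert res.rmse <= 1e-8

    def test_recovery_from_10pct_perturbation(self, p_segment):
        seg, truth = p_segment
        bounds = wide_bounds(seg, truth.duration)
        perturbed = truth.with_params(truth.params * 1.10 + 1e-4)
        res = g.local_refine(seg, perturbed, bounds)
        est = res.model.canonical().params
        tru = truth.canonical().params
        nz = np.abs(tru) > 1e-12
        assert np.all(np.abs(est[nz] - tru[nz]) / np.abs(tru[nz]) < 0.01)

    def test_result_respects_bounds(self, p_segment):
        seg, truth = p_segment
        init, bounds = g.approximate(seg, "P")
        res = g.local_refine(seg, init, bounds)
        assert bounds.contains(res.model.canonical().params) or \
            bounds.contains(res.model.params)

    def test_objective_self_consistency(self, p_segment):
        seg, _ = p_segment
        init, bounds = g.approximate(seg, "P")
        res = g.local_refine(seg, init, bounds)
        assert res.rmse == pytest.approx(rmse_of(res.model, seg), rel=1e-12)


class TestMultistart:
    def test_single_start_equals_local_refine(self, p_segment):
        seg, _ = p_segment
        init, bounds = g.approximate(seg, "P")
        cfg = g.SolverConfig(method="approxi_mul", n_starts=1, seed=0)
        ms = g.solve_multistart(seg, init, bounds, cfg)
        lr = g.local_refine(seg, init, bounds, cfg)
        assert np.array_equal(ms.model.params, lr.model.params)
        assert ms.rmse == lr.rmse

    def test_deterministic_under_seed(self, p_segment):
        seg, _ = p_segment
        init, bounds = g.approximate(seg, "P")
        cfg = g.SolverConfig(method="approxi_mul", n_starts=6, seed=42)
        a = g.solve_multistart(seg, init, bounds, cfg)
        b = g.solve_multistart(seg, init, bounds, cfg)
        assert np.array_equal(a.model.params, b.model.params)
        assert a.rmse == b.rmse
        assert a.start_points == b.start_points

    def test_never_worse_than_approximation_or_single_refine(self, normal_beat):
        comp = normal_beat.component("T")  # asymmetric two-Gaussian wave
        ns = normal_beat.segment_samples[4]
        t = np.arange(ns) / normal_beat.fs
        seg = g.Signal(g.evaluate_component(comp, t), fs=normal_beat.fs)
        init, bounds = g.approximate(seg, "T")
        approx_rmse = rmse_of(init, seg)
        lr = g.local_refine(seg, init, bounds)
        ms = g.solve_multistart(seg, init, bounds,
                                g.SolverConfig(n_starts=8, seed=0))
        assert ms.rmse <= approx_rmse + 1e-15
        assert ms.rmse <= lr.rmse + 1e-15


class TestScatterSearch:
    def test_deterministic_under_seed(self, p_segment):
        seg, _ = p_segment
        init, bounds = g.approximate(seg, "P")
        cfg = g.SolverConfig(method="approxi_glo", n_starts=6, seed=7)
        a = g.solve_scattersearch(seg, init, bounds, cfg)
        b = g.solve_scattersearch(seg, init, bounds, cfg)
        assert np.array_equal(a.model.params, b.model.params)
        assert a.rmse == b.rmse

    def test_never_worse_than_approximation(self, p_segment):
        seg, _ = p_segment
        init, bounds = g.approximate(seg, "P")
        approx_rmse = rmse_of(init, seg)
        res = g.solve_scattersearch(seg, init, bounds,
                                    g.SolverConfig(method="approxi_glo",
                                                   n_starts=6, seed=0))
        assert res.rmse <= approx_rmse + 1e-15

    def test_escapes_deceptive_single_wide_basin(self):
        # two distinct bells; a single wide Gaussian start is a deceptive
        # local basin that the scatter search must not end up above
        fs = 360.0
        n = 140
        t = np.arange(n) / fs
        truth = g.ComponentModel(label="T", A1=0.8, t1=40 / fs, sigma1=5 / fs,
                                 A2=0.6, t2=100 / fs, sigma2=6 / fs, c=0.0,
                                 duration=n / fs)
        seg = g.Signal(g.evaluate_component(truth, t), fs=fs)
        bounds = wide_bounds(seg, truth.duration)
        deceptive = truth.with_params([0.7, 70 / fs, 30 / fs,
                                       0.0, 70 / fs, 30 / fs, 0.0])
        deceptive_fit = g.local_refine(seg, deceptive, bounds)
        res = g.solve_scattersearch(
            seg, deceptive, bounds,
            g.SolverConfig(method="approxi_glo", n_starts=12, seed=0))
        assert res.rmse <= deceptive_fit.rmse + 1e-15


class TestFitBeat:
    def test_noiseless_recovery(self, normal_beat_signal):
        segs = g.extract_components(normal_beat_signal)
        fit = g.fit_beat(normal_beat_signal, segs,
                         g.SolverConfig(n_starts=6, seed=0))
        assert fit.whole_beat.corr > 0.999
        assert not fit.failed

    def test_empty_segmentation_rejected(self, normal_beat_signal):
        with pytest.raises(ValueError):
            g.fit_beat(normal_beat_signal, [], g.SolverConfig())

    def test_canonical_gaussian_order(self, normal_beat_signal):
        segs = g.extract_components(normal_beat_signal)
        fit = g.fit_beat(normal_beat_signal, segs,
                         g.SolverConfig(n_starts=2, seed=0))
        for res in fit.components.values():
            assert res.model.t1 <= res.model.t2
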