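import json
import math

import numpy as np
import pytest

import gaussecg as g
from gaussecg.model import COMPONENT_LABELS, InvalidModelError


def make_component(**kw):
    defaults = dict(label="P", A1=1.0, t1=0.05, sigma1=0.01,
                    A2=0.2, t2=0.07, sigma2=0.02, c=0.0, duration=0.1)
    defaults.update(kw)
    return g.ComponentModel(**defaults)


class TestEvaluateComponent:
    def test_baseline_only(self):
        comp = make_component(A1=0.0, A2=0.0, c=0.5)
        t = np.linspace(0, 0.1, 11)
        assert np.allclose(g.evaluate_component(comp, t), 0.5)

    def test_shared_center_peak(self):
        comp = make_component(t1=0.05, t2=0.05, c=0.3)
        val = g.evaluate_component(comp, [0.05])[0]
        assert val == pytest.approx(comp.A1 + comp.A2 + comp.c, abs=1e-15)

    def test_scalar_arithmetic_oracle(self):
        # independent evaluation of the two exponentials with math.exp
        comp = make_component()
        expected = (1.0 * math.exp(-((0.06 - 0.05) ** 2) / (2 * 0.01**2))
                    + 0.2 * math.exp(-((0.06 - 0.07) ** 2) / (2 * 0.02**2)))
        assert g.evaluate_component(comp, [0.06])[0] == pytest.approx(
            expected, rel=1e-14)
        assert expected == pytest.approx(0.7830300402295528, rel=1e-12)

    def test_linear_in_amplitudes_and_baseline(self):
        comp = make_component(c=0.1)
        doubled = make_component(A1=2.0, A2=0.4, c=0.2)
        t = np.linspace(0, 0.1, 37)
        assert np.allclose(2 * g.evaluate_component(comp, t),
                           g.evaluate_component(doubled, t), rtol=1e-14)

    def test_gaussian_swap_invariance(self):
        comp = make_component()
        swapped = make_component(A1=0.2, t1=0.07, sigma1=0.02,
                                 A2=1.0, t2=0.05, sigma2=0.01)
        t = np.linspace(-0.02, 0.12, 53)
        assert np.array_equal(g.evaluate_component(comp, t),
                              g.evaluate_component(swapped, t))

    def test_coincident_gaussians_collapse_to_one(self):
        comp = make_component(A1=0.7, A2=0.3, t1=0.04, t2=0.04,
                              sigma1=0.015, sigma2=0.015)
        t = np.linspace(0, 0.1, 41)
        single = 1.0 * np.exp(-((t - 0.04) ** 2) / (2 * 0.015**2))
        assert np.allclose(g.evaluate_component(comp, t), single, rtol=1e-12)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(InvalidModelError):
            make_component(A1=float("nan"))
        with pytest.raises(InvalidModelError):
            make_component(sigma1=-0.01)


class TestEvaluateBeat:
    def test_zero_beat(self, normal_beat):
        comps = tuple(
            g.ComponentModel(label=c.label, A1=0, t1=c.t1, sigma1=c.sigma1,
                             A2=0, t2=c.t2, sigma2=c.sigma2, c=0,
                             duration=c.duration)
            for c in normal_beat.components)
        beat = g.BeatModel(comps, fs=normal_beat.fs,
                           segment_samples=normal_beat.segment_samples)
        sig = g.evaluate_beat(beat)
        assert len(sig) == normal_beat.n_samples
        assert np.all(sig.samples == 0)

    def test_single_component_disjoint_support(self, normal_beat):
        comps = []
        for c in normal_beat.components:
            amp = (0.0, 0.0) if c.label != "T" else (c.A1, c.A2)
            comps.append(g.ComponentModel(
                label=c.label, A1=amp[0], t1=c.t1, sigma1=c.sigma1,
                A2=amp[1], t2=c.t2, sigma2=c.sigma2, c=0.0, duration=c.duration))
        beat = g.BeatModel(tuple(comps), fs=normal_beat.fs,
                           segment_samples=normal_beat.segment_samples)
        sig = g.evaluate_beat(beat)
        t_start = sum(normal_beat.segment_samples[:4])
        assert np.all(sig.samples[:t_start] == 0)
        assert np.any(sig.samples[t_start:] != 0)

    def test_r_segment_holds_beat_maximum(self, normal_beat, normal_beat_signal):
        idx = int(np.argmax(normal_beat_signal.samples))
        bounds = np.cumsum((0,) + normal_beat.segment_samples)
        assert bounds[2] <= idx < bounds[3]  # inside the R window

    def test_global_sum_assembly_close_to_piecewise(self, normal_beat):
        pw = g.evaluate_beat(normal_beat).samples
        gs = g.evaluate_beat(normal_beat, assembly="global_sum").samples
        # contained Gaussians make the two assemblies nearly identical
        assert np.max(np.abs(pw - gs)) < 0.06

    def test_wrong_component_order_rejected(self, normal_beat):
        comps = normal_beat.components[::-1]
        with pytest.raises(InvalidModelError):
            g.BeatModel(comps, fs=360.0, segment_samples=normal_beat.segment_samples)


class TestAssembleTrain:
    def test_output_length_is_duration_times_fs(self, normal_beat):
        for bpm in (50, 72, 120):
            sig = g.assemble_train(normal_beat, bpm=bpm, duration_s=10.0)
            assert len(sig) == 3600

    def test_72_bpm_gives_12_periods(self, normal_beat):
        sig = g.assemble_train(normal_beat, bpm=72, duration_s=10.0)
        peaks = g.detect_qrs(sig)
        assert len(peaks) == 12

    @pytest.mark.parametrize("bpm,period_s", [(50, 1.2), (120, 0.5)])
    def test_bradycardia_tachycardia_periods(self, normal_beat, bpm, period_s):
        sig = g.assemble_train(normal_beat, bpm=bpm, duration_s=10.0)
        peaks = g.detect_qrs(sig)
        rr = np.diff(peaks) / sig.fs
        assert np.all(np.abs(rr - period_s) <= 2 / sig.fs)

    def test_absurd_bpm_rejected(self, normal_beat):
        with pytest.raises(ValueError):
            g.assemble_train(normal_beat, bpm=4000, duration_s=1.0)


class TestJsonSchema:
    def test_round_trip_lossless(self, normal_beat, tmp_path):
        path = tmp_path / "beat.json"
        g.save_beat_json(normal_beat, path)
        loaded = g.load_beat_json(path)
        assert loaded == normal_beat
        d = json.loads(path.read_text())
        assert d["exponent_convention"] == "A*exp(-(t-tc)^2/(2*sigma^2))"
        assert [c["label"] for c in d["components"]] == list(COMPONENT_LABELS)
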