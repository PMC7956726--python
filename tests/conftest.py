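import numpy as np
import pytest

import gaussecg as g


@pytest.fixture(scope="session")
def normal_beat():
    return g.get_beat("normal")


@pytest.fixture(scope="session")
def normal_beat_signal(normal_beat):
    return g.evaluate_beat(normal_beat)


@pytest.fixture(scope="session")
def default_train():
    """10 s, 72 bpm, 360 Hz noiseless strip from the generator defaults."""
    signal, clean = g.generate(g.GeneratorConfig())
    return signal


@pytest.fixture
def p_segment(normal_beat):
    """Noiseless P-wave segment rendered from the library parameters."""
    comp = normal_beat.component("P")
    ns = normal_beat.segment_samples[0]
    t = np.arange(ns) / normal_beat.fs
    return g.Signal(g.evaluate_component(comp, t), fs=normal_beat.fs), comp
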