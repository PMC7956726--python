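"""Hand-tuned beat parameter library for the synthetic generator.

Four beat morphologies are shipped: a normal sinus beat, an atrial
premature beat (early, narrow, peaked P wave), a paced beat (narrow
biphasic pacing spike followed by a widened QRS with discordant T) and a
premature ventricular contraction (no P wave, broad high-amplitude QRS,
discordant T).  All values are provisional stand-ins tuned by qualitative
morphology — amplitudes in mV, times in seconds on a 0.8333 s beat at a
360 Hz base rate — and every library entry can be replaced by a JSON
parameter file with the same schema.
"""

from __future__ import annotations

import numpy as np

from .model import BeatModel, ComponentModel

__all__ = ["BEAT_LIBRARY", "beat_types", "get_beat"]

_BASE_FS = 360.0

# (fractions of the beat window, per-component (A1,t1,s1,A2,t2,s2,c))
_LIBRARY_SPECS: dict[str, dict] = {
    "normal": {
        "fractions": (0.25, 0.10, 0.10, 0.10, 0.45),
        "components": {
            "P": (0.08, 0.095, 0.022, 0.05, 0.125, 0.028, 0.0),
            "Q": (-0.06, 0.055, 0.009, -0.03, 0.065, 0.012, 0.0),
            "R": (1.10, 0.040, 0.011, 0.35, 0.047, 0.018, 0.0),
            "S": (-0.18, 0.025, 0.010, -0.07, 0.038, 0.016, 0.0),
            "T": (0.22, 0.160, 0.045, 0.10, 0.210, 0.060, 0.0),
        },
    },
    "atrial_premature": {
        "fractions": (0.25, 0.10, 0.10, 0.10, 0.45),
        "components": {
            # early, narrow, peaked P of ectopic atrial origin
            "P": (0.10, 0.060, 0.012, 0.04, 0.075, 0.018, 0.0),
            "Q": (-0.05, 0.055, 0.010, -0.025, 0.065, 0.013, 0.0),
            "R": (1.05, 0.040, 0.011, 0.33, 0.047, 0.018, 0.0),
            "S": (-0.16, 0.025, 0.010, -0.06, 0.038, 0.016, 0.0),
            "T": (0.18, 0.150, 0.042, 0.08, 0.190, 0.055, 0.0),
        },
    },
    "paced": {
        "fractions": (0.25, 0.10, 0.10, 0.10, 0.45),
        "components": {
            "P": (0.03, 0.100, 0.020, 0.02, 0.120, 0.030, 0.0),
            # narrow biphasic pacing stimulus artifact
            "Q": (-0.90, 0.045, 0.003, 0.15, 0.052, 0.004, 0.0),
            # widened ventricular depolarization
            "R": (0.90, 0.042, 0.024, 0.45, 0.058, 0.030, 0.0),
            "S": (-0.35, 0.030, 0.018, -0.12, 0.050, 0.022, 0.0),
            # discordant repolarization
            "T": (-0.20, 0.160, 0.050, -0.08, 0.210, 0.060, 0.0),
        },
    },
    "pvc": {
        "fractions": (0.15, 0.10, 0.20, 0.15, 0.40),
        "components": {
            # no atrial activity before a ventricular ectopic beat
            "P": (0.0, 0.040, 0.020, 0.0, 0.060, 0.020, 0.0),
            "Q": (-0.04, 0.050, 0.012, -0.02, 0.060, 0.015, 0.0),
            # broad, high-amplitude ventricular complex
            "R": (1.30, 0.075, 0.022, 0.50, 0.100, 0.030, 0.0),
            "S": (-0.45, 0.045, 0.020, -0.15, 0.075, 0.026, 0.0),
            # discordant T wave
            "T": (-0.30, 0.130, 0.048, -0.12, 0.180, 0.058, 0.0),
        },
    },
}


def _build(name: str) -> BeatModel:
    spec = _LIBRARY_SPECS[name]
    fractions = np.asarray(spec["fractions"])
    total = int(round(_BASE_FS * 60.0 / 72.0))  # one 72-bpm beat period
    edges = np.round(np.cumsum(np.concatenate([[0.0], fractions])) * total).astype(int)
    seg = tuple(int(b - a) for a, b in zip(edges[:-1], edges[1:]))
    comps = []
    for (label, p), ns in zip(spec["components"].items(), seg):
        A1, t1, s1, A2, t2, s2, c = p
        comps.append(ComponentModel(label=label, A1=A1, t1=t1, sigma1=s1,
                                    A2=A2, t2=t2, sigma2=s2, c=c,
                                    duration=ns / _BASE_FS))
    return BeatModel(components=tuple(comps), fs=_BASE_FS, segment_samples=seg)


BEAT_LIBRARY: dict[str, BeatModel] = {name: _build(name) for name in _LIBRARY_SPECS}


def beat_types() -> list[str]:
    return list(BEAT_LIBRARY)


def get_beat(name: str) -> BeatModel:
    try:
        return BEAT_LIBRARY[name]
    except KeyError:
        raise KeyError(
            f"unknown beat type {name!r}; available: {', '.join(BEAT_LIBRARY)}"
        ) from None
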