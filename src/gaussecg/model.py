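"""Sum-of-two-Gaussians ECG beat model.

Each of the five ECG deflections (P, Q, R, S, T) is modeled as the sum of
two Gaussian bells plus a constant baseline,

    y_i(t) = A_{i,1} exp(-(t - t_{i,1})^2 / (2 sigma_{i,1}^2))
           + A_{i,2} exp(-(t - t_{i,2})^2 / (2 sigma_{i,2}^2)) + c_i,

with ``t`` measured from the start of the component's segment.  Two
Gaussians per component capture the mild asymmetry of real P and T waves
that a single symmetric bell cannot; the baseline ``c_i`` absorbs local
baseline wander so no separate detrending step is required.

A full beat is the piecewise concatenation of the five component segments,
and a rhythm strip is the beat tiled at the requested heart rate.  The
exponent convention exp(-(t-tc)^2/(2 sigma^2)) is used uniformly across the
model, the matched-filter initializer and the codec, and is recorded in the
JSON parameter schema.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "COMPONENT_LABELS",
    "Signal",
    "ComponentModel",
    "BeatModel",
    "InvalidModelError",
    "evaluate_component",
    "evaluate_beat",
    "evaluate_beat_at_times",
    "assemble_train",
    "beat_to_dict",
    "beat_from_dict",
    "save_beat_json",
    "load_beat_json",
]

COMPONENT_LABELS = ("P", "Q", "R", "S", "T")

#: Exponent convention recorded in every serialized parameter file.
EXPONENT_CONVENTION = "A*exp(-(t-tc)^2/(2*sigma^2))"


class InvalidModelError(ValueError):
    """Raised when model parameters are non-finite or violate invariants."""


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled single-channel signal.

    Attributes
    ----------
    samples : ndarray
        Amplitudes in mV.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Start time offset in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds: t0 + k/fs, 0-based."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class ComponentModel:
    """Seven-parameter model of one ECG component (P, Q, R, S or T).

    Times are seconds relative to the start of the component segment,
    amplitudes in mV.  ``duration`` is the segment length x_R.
    """

    label: str
    A1: float
    t1: float
    sigma1: float
    A2: float
    t2: float
    sigma2: float
    c: float
    duration: float

    def __post_init__(self) -> None:
        if self.label not in COMPONENT_LABELS:
            raise InvalidModelError(
                f"label must be one of {COMPONENT_LABELS}, got {self.label!r}"
            )
        vals = (self.A1, self.t1, self.sigma1, self.A2, self.t2, self.sigma2,
                self.c, self.duration)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidModelError(f"non-finite parameter in {self.label}: {vals}")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise InvalidModelError(
                f"{self.label}: widths must be positive "
                f"(sigma1={self.sigma1}, sigma2={self.sigma2})"
            )
        if self.duration <= 0:
            raise InvalidModelError(f"{self.label}: duration must be > 0")

    @property
    def params(self) -> np.ndarray:
        """Parameter vector (A1, t1, sigma1, A2, t2, sigma2, c)."""
        return np.array(
            [self.A1, self.t1, self.sigma1, self.A2, self.t2, self.sigma2, self.c]
        )

    def with_params(self, p: Sequence[float]) -> "ComponentModel":
        A1, t1, s1, A2, t2, s2, c = (float(v) for v in p)
        return replace(self, A1=A1, t1=t1, sigma1=s1, A2=A2, t2=t2, sigma2=s2, c=c)

    def canonical(self) -> "ComponentModel":
        """Order the two Gaussians so that t1 <= t2 (swap symmetry)."""
        if self.t1 <= self.t2:
            return self
        return replace(self, A1=self.A2, t1=self.t2, sigma1=self.sigma2,
                       A2=self.A1, t2=self.t1, sigma2=self.sigma1)


@dataclass(frozen=True)
class BeatModel:
    """Ordered P, Q, R, S, T component models forming one beat."""

    components: tuple[ComponentModel, ...]
    fs: float
    segment_samples: tuple[int, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "segment_samples", tuple(int(n) for n in self.segment_samples))
        if len(comps) != 5 or tuple(c.label for c in comps) != COMPONENT_LABELS:
            raise InvalidModelError(
                "BeatModel needs exactly 5 components in P,Q,R,S,T order, got "
                f"{[c.label for c in comps]}"
            )
        if self.fs <= 0:
            raise InvalidModelError("fs must be > 0")
        if len(self.segment_samples) != 5 or any(n < 2 for n in self.segment_samples):
            raise InvalidModelError("segment_samples must be 5 counts, all >= 2")

    @property
    def n_samples(self) -> int:
        return int(sum(self.segment_samples))

    @property
    def duration(self) -> float:
        """Natural beat duration in seconds (sum of component durations)."""
        return sum(c.duration for c in self.components)

    def component(self, label: str) -> ComponentModel:
        return self.components[COMPONENT_LABELS.index(label)]


def evaluate_component(model: ComponentModel, times: Sequence[float]) -> np.ndarray:
    """Evaluate a two-Gaussian component at the given times (s).

    Times outside [0, duration] are allowed and evaluated by the same
    formula (the Gaussians simply decay).
    """
    t = np.asarray(times, dtype=float)
    g1 = model.A1 * np.exp(-((t - model.t1) ** 2) / (2.0 * model.sigma1**2))
    g2 = model.A2 * np.exp(-((t - model.t2) ** 2) / (2.0 * model.sigma2**2))
    return g1 + g2 + model.c


def evaluate_beat(beat: BeatModel, assembly: str = "piecewise") -> Signal:
    """Render one beat on its sample grid.

    ``assembly="piecewise"`` (default) evaluates each component on its own
    segment grid and concatenates the five segments, matching per-component
    fitting; each segment keeps its own baseline c.  ``assembly="global_sum"``
    evaluates all ten Gaussians over the whole beat with a single shared
    baseline (the sum of the per-component baselines).
    """
    if assembly == "piecewise":
        parts = []
        for comp, ns in zip(beat.components, beat.segment_samples):
            t = np.arange(ns) / beat.fs
            parts.append(evaluate_component(comp, t))
        return Signal(np.concatenate(parts), fs=beat.fs)
    if assembly == "global_sum":
        t = np.arange(beat.n_samples) / beat.fs
        out = np.zeros_like(t)
        start = 0.0
        for comp in beat.components:
            shifted = replace(comp, c=0.0)
            out += evaluate_component(shifted, t - start)
            start += comp.duration
        out += sum(c.c for c in beat.components)
        return Signal(out, fs=beat.fs)
    raise ValueError(f"assembly must be 'piecewise' or 'global_sum', got {assembly!r}")


def evaluate_beat_at_times(beat: BeatModel, times: Sequence[float]) -> np.ndarray:
    """Evaluate the piecewise beat model at arbitrary beat-relative times.

    Each time is routed to the component whose segment [start, start+dur)
    contains it; times at or beyond the total duration use the T component.
    """
    t = np.asarray(times, dtype=float)
    out = np.empty_like(t)
    starts = np.cumsum([0.0] + [c.duration for c in beat.components])
    for i, comp in enumerate(beat.components):
        lo, hi = starts[i], starts[i + 1]
        mask = (t >= lo) & (t < hi) if i < 4 else (t >= lo)
        if np.any(mask):
            out[mask] = evaluate_component(comp, t[mask] - lo)
    out[t < 0] = evaluate_component(beat.components[0], t[t < 0])
    return out


def assemble_train(beat: BeatModel, bpm: float, duration_s: float,
                   fs: float | None = None) -> Signal:
    """Tile a beat at the requested heart rate into a rhythm strip.

    The beat period is 60/bpm seconds; the beat's time axis is rescaled
    proportionally to fill each period (amplitudes fixed), so changing bpm
    is a pure rate change.  Output length is round(duration_s * fs) samples.
    """
    if bpm <= 0:
        raise ValueError("bpm must be > 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    fs = beat.fs if fs is None else float(fs)
    period = 60.0 / bpm
    if period * fs < 10:
        raise ValueError(
            f"bpm {bpm} leaves fewer than 10 samples per beat at fs {fs} Hz"
        )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = np.mod(t, period)
    scale = period / beat.duration
    # rescaled phase maps the period back onto the beat's natural time axis
    samples = evaluate_beat_at_times(beat, phase / scale)
    return Signal(samples, fs=fs)


# ---------------------------------------------------------------------------
# JSON parameter schema

def beat_to_dict(beat: BeatModel) -> dict:
    return {
        "schema": "gaussecg-beat-v1",
        "exponent_convention": EXPONENT_CONVENTION,
        "fs": beat.fs,
        "components": [
            {
                "label": c.label,
                "A1": c.A1, "t1_s": c.t1, "sigma1_s": c.sigma1,
                "A2": c.A2, "t2_s": c.t2, "sigma2_s": c.sigma2,
                "c": c.c, "duration_s": c.duration,
                "n_samples": int(ns),
            }
            for c, ns in zip(beat.components, beat.segment_samples)
        ],
    }


def beat_from_dict(d: dict) -> BeatModel:
    comps = []
    seg = []
    for cd in d["components"]:
        comps.append(ComponentModel(
            label=cd["label"],
            A1=cd["A1"], t1=cd["t1_s"], sigma1=cd["sigma1_s"],
            A2=cd["A2"], t2=cd["t2_s"], sigma2=cd["sigma2_s"],
            c=cd["c"], duration=cd["duration_s"],
        ))
        seg.append(int(cd.get("n_samples", round(cd["duration_s"] * d["fs"]))))
    return BeatModel(components=tuple(comps), fs=float(d["fs"]),
                     segment_samples=tuple(seg))


def save_beat_json(beat: BeatModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(beat_to_dict(beat), fh, indent=1)


def load_beat_json(path) -> BeatModel:
    with open(path) as fh:
        return beat_from_dict(json.load(fh))
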