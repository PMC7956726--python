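"""Parameterized synthetic ECG generator with calibrated noise injection.

Generates rhythm strips from the beat parameter library (or any user
BeatModel) at a chosen heart rate, duration and sampling rate, optionally
adding one of six noise classes at a requested SNR:

``WN``  white Gaussian noise;
``CN``  colored (1/f, pink) noise via FFT spectral shaping;
``BW``  baseline wander — low-frequency sinusoids (0.05-0.5 Hz) with
        random phases plus a slow random walk;
``EM``  electrode-movement artifact — sparse step transients;
``MA``  muscle artifact — band-limited (5-50 Hz) Gaussian bursts under
        random envelopes;
``MX``  equal-power mixture of BW, EM and MA.

BW/EM/MA are synthetic surrogates of the classic ambulatory noise-stress
recordings; a real noise record (CSV) can be substituted via
``NoiseSpec.source``.  Noise is scaled so the realized SNR, with signal
power measured as energy per sample Py = (1/N) sum y^2, matches the
request exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import butter, filtfilt, resample_poly

from .library import get_beat
from .model import BeatModel, Signal, assemble_train

__all__ = [
    "GeneratorConfig",
    "NoiseSpec",
    "NOISE_KINDS",
    "SUPPORTED_FS",
    "generate",
    "noise_power",
    "add_noise",
    "resample",
]

NOISE_KINDS = ("WN", "CN", "MA", "EM", "BW", "MX")
SUPPORTED_FS = (256.0, 360.0, 512.0, 1000.0)
_BASE_FS = 360.0


@dataclass(frozen=True)
class NoiseSpec:
    kind: str
    snr_db: float
    seed: int = 0
    source: str | None = None  # path to a CSV noise record, else synthetic

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}")
        if math.isnan(self.snr_db):
            raise ValueError("snr_db must not be NaN")


@dataclass(frozen=True)
class GeneratorConfig:
    beat_type: str | BeatModel = "normal"
    duration_s: float = 10.0
    bpm: float = 72.0
    fs: float = 360.0
    noise: NoiseSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.bpm <= 0:
            raise ValueError("bpm must be > 0")
        if float(self.fs) not in SUPPORTED_FS:
            raise ValueError(f"fs must be one of {SUPPORTED_FS}, got {self.fs}")


def noise_power(signal_power_py: float, snr_db: float) -> float:
    """Noise power required for a target SNR: Py / 10^(SNR/10)."""
    if signal_power_py <= 0:
        raise ValueError("signal power must be > 0")
    return signal_power_py / 10.0 ** (snr_db / 10.0)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])  # power ~ 1/f
    return np.fft.irfft(spec * shaping, n)


def _baseline_wander(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(5):
        f0 = rng.uniform(0.05, 0.5)
        out += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    walk = np.cumsum(rng.standard_normal(n)) / np.sqrt(n)
    return out + walk


def _electrode_movement(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    n_steps = max(int(n / fs * 1.5), 2)  # ~1.5 transients per second
    for _ in range(n_steps):
        pos = rng.integers(0, n)
        out[pos:] += rng.normal(0.0, 1.0)
    # slight smoothing keeps steps abrupt but finite-bandwidth
    win = max(int(0.02 * fs), 1)
    return np.convolve(out, np.ones(win) / win, mode="same")


def _muscle_artifact(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    hi = min(50.0 / nyq, 0.99)
    lo = min(5.0 / nyq, 0.9 * hi)
    b, a = butter(2, [lo, hi], btype="band")
    band = filtfilt(b, a, white)
    # random burst envelope: smoothed on/off activity
    env = (rng.random(n) < 0.3).astype(float)
    win = max(int(0.15 * fs), 1)
    env = np.convolve(env, np.ones(win) / win, mode="same")
    return band * (0.2 + env)


def _unit_power(d: np.ndarray) -> np.ndarray:
    p = np.mean(d**2)
    if p <= 0:
        raise ValueError("generated noise has zero power")
    return d / np.sqrt(p)


def _draw_noise(kind: str, n: int, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    if kind == "WN":
        return rng.standard_normal(n)
    if kind == "CN":
        return _pink_noise(n, rng)
    if kind == "BW":
        return _baseline_wander(n, fs, rng)
    if kind == "EM":
        return _electrode_movement(n, fs, rng)
    if kind == "MA":
        return _muscle_artifact(n, fs, rng)
    if kind == "MX":
        parts = [_unit_power(_baseline_wander(n, fs, rng)),
                 _unit_power(_electrode_movement(n, fs, rng)),
                 _unit_power(_muscle_artifact(n, fs, rng))]
        return sum(parts)
    raise ValueError(f"unknown noise kind {kind!r}")


def add_noise(clean: Signal, spec: NoiseSpec) -> Signal:
    """Add the requested noise class at an exactly calibrated SNR.

    The raw noise draw is rescaled so that 10*log10(Py/Pd) equals
    ``spec.snr_db`` to within floating-point precision; an infinite SNR
    disables noise and returns the clean signal unchanged.
    """
    if math.isinf(spec.snr_db) and spec.snr_db > 0:
        return Signal(clean.samples.copy(), fs=clean.fs, t0=clean.t0)
    y = clean.samples
    py = float(np.mean(y**2))
    if py <= 0:
        raise ValueError("clean signal has zero power; cannot set an SNR")
    n = y.size
    if spec.source is not None:
        import os

        if not os.path.exists(spec.source):
            raise FileNotFoundError(
                f"noise record {spec.source!r} not found; omit `source` to "
                "use the synthetic surrogate instead"
            )
        from .io import read_signal

        rec = read_signal(spec.source).samples
        reps = int(np.ceil(n / rec.size))
        d = np.tile(rec, reps)[:n].astype(float)
        if np.mean(d**2) <= 0:
            raise ValueError("noise record has zero power")
    else:
        rng = np.random.default_rng(spec.seed)
        d = _draw_noise(spec.kind, n, clean.fs, rng)
    target = noise_power(py, spec.snr_db)
    d = d * np.sqrt(target / np.mean(d**2))
    return Signal(y + d, fs=clean.fs, t0=clean.t0)


def resample(signal: Signal, fs_out: float) -> Signal:
    """Polyphase rational resampling with Kaiser-windowed FIR antialiasing.

    Output length is round(N * fs_out / fs_in); equal rates return the
    signal unchanged.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be > 0")
    if fs_out == signal.fs:
        return signal
    frac = Fraction(fs_out / signal.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    y = resample_poly(signal.samples, up, down, window=("kaiser", 5.0))
    n_out = int(round(signal.samples.size * fs_out / signal.fs))
    if y.size > n_out:
        y = y[:n_out]
    elif y.size < n_out:
        y = np.pad(y, (0, n_out - y.size), mode="edge")
    return Signal(y, fs=fs_out, t0=signal.t0)


def generate(config: GeneratorConfig) -> tuple[Signal, Signal]:
    """Generate a rhythm strip; returns (output, clean_reference).

    Without noise the two are the same object's data.  The beat is
    assembled at the library's native 360 Hz and resampled to the
    requested rate with the antialiasing polyphase filter.
    """
    if isinstance(config.beat_type, BeatModel):
        beat = config.beat_type
    else:
        try:
            beat = get_beat(config.beat_type)
        except KeyError as exc:
            raise ValueError(str(exc)) from None
    clean = assemble_train(beat, bpm=config.bpm, duration_s=config.duration_s,
                           fs=_BASE_FS)
    if config.fs != _BASE_FS:
        clean = resample(clean, config.fs)
    if config.noise is None:
        return clean, clean
    noisy = add_noise(clean, config.noise)
    return noisy, clean
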