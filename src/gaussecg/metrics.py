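"""Time, frequency and time-frequency goodness-of-fit measures.

Time domain: MSE, NMSE (error energy over real-signal energy), RMSE, NRMSE
(RMSE over the real signal's range) and the Pearson correlation CORR.
Frequency domain: one-sided FFT magnitude and Welch power spectral density.
Time-frequency: the scalogram difference ScD, the elementwise absolute
difference of continuous-wavelet-transform magnitudes, which localizes
where in time and scale a model departs from the signal it imitates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.fft import rfft, rfftfreq
from scipy.signal import welch

from .model import Signal

__all__ = [
    "MetricsReport",
    "SpectrumReport",
    "ScalogramDiff",
    "compare",
    "spectrum",
    "scalogram_difference",
]


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    nmse: float
    rmse: float
    nrmse: float
    corr: float
    n: int
    corr_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "mse": self.mse, "nmse": self.nmse, "rmse": self.rmse,
            "nrmse": self.nrmse, "corr": self.corr, "n": self.n,
            "corr_defined": self.corr_defined,
            "conventions": {
                "nmse": "sum(err^2)/sum(real^2)",
                "nrmse": "rmse/(max(real)-min(real))",
            },
        }


@dataclass(frozen=True)
class SpectrumReport:
    frequencies: np.ndarray   # FFT bin frequencies, Hz
    magnitude: np.ndarray     # one-sided FFT amplitude
    psd_frequencies: np.ndarray
    psd: np.ndarray           # Welch PSD, power / Hz


@dataclass(frozen=True)
class ScalogramDiff:
    scales: np.ndarray
    diff: np.ndarray  # | |CWT(real)| - |CWT(model)| |, shape (scales, N)


def _as_samples(x) -> np.ndarray:
    return x.samples if isinstance(x, Signal) else np.asarray(x, dtype=float)


def compare(real, model) -> MetricsReport:
    """Time-domain goodness of fit between a real and a modeled signal.

    Normalization conventions (recorded in the report): NMSE divides the
    error energy by the real signal's energy; NRMSE divides the RMSE by the
    real signal's peak-to-peak range.  A zero-variance real signal leaves
    CORR undefined (NaN, ``corr_defined=False``).
    """
    r = _as_samples(real)
    m = _as_samples(model)
    if r.size != m.size:
        raise ValueError(f"length mismatch: real {r.size} vs model {m.size}")
    e = m - r
    mse = float(np.mean(e**2))
    rmse = float(np.sqrt(mse))
    energy = float(np.sum(r**2))
    nmse = float(np.sum(e**2) / energy) if energy > 0 else float("inf")
    rng = float(np.max(r) - np.min(r))
    nrmse = rmse / rng if rng > 0 else float("inf")
    sr = float(np.std(r))
    sm = float(np.std(m))
    if sr == 0 or sm == 0:
        corr, defined = float("nan"), False
    else:
        corr = float(np.corrcoef(r, m)[0, 1])
        defined = True
    return MetricsReport(mse=mse, nmse=nmse, rmse=rmse, nrmse=nrmse,
                         corr=corr, n=int(r.size), corr_defined=defined)


def spectrum(signal: Signal, nperseg: int | None = None) -> SpectrumReport:
    """One-sided FFT magnitude and Welch PSD of a signal.

    Welch defaults: Hann window, segment length min(N, 256), 50% overlap.
    """
    x = signal.samples
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 samples for a spectrum")
    freqs = rfftfreq(n, d=1.0 / signal.fs)
    mag = np.abs(rfft(x))
    nper = min(n, 256) if nperseg is None else int(nperseg)
    pf, psd = welch(x, fs=signal.fs, window="hann", nperseg=nper,
                    noverlap=nper // 2)
    return SpectrumReport(frequencies=freqs, magnitude=mag,
                          psd_frequencies=pf, psd=psd)


def scalogram_difference(real: Signal, model: Signal,
                         scales=None, wavelet: str = "mexh") -> ScalogramDiff:
    """Scalogram difference ScD between a real and a modeled signal.

    Both signals are transformed with a Mexican-hat CWT over the given
    scales (default 1..128) and the elementwise absolute difference of the
    coefficient magnitudes is returned; larger entries localize where in
    time/scale the model misses.
    """
    if len(real) != len(model):
        raise ValueError("length mismatch between real and model signals")
    if scales is None:
        scales = np.arange(1, 129)
    scales = np.asarray(scales, dtype=float)
    dt = 1.0 / real.fs
    cr, _ = pywt.cwt(real.samples, scales, wavelet, sampling_period=dt)
    cm, _ = pywt.cwt(model.samples, scales, wavelet, sampling_period=dt)
    diff = np.abs(np.abs(cr) - np.abs(cm))
    return ScalogramDiff(scales=scales, diff=diff)
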