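"""Step-1 approximation: matched-filter initialization of Gaussian parameters.

Given one ECG component segment, a Gaussian template of trial width sigma is
swept over a grid of widths; for each width the template is correlated with
the (mean-removed) segment and the maximum-magnitude response locates the
candidate center t1 and amplitude A1.  The width minimizing the RMSE of the
single-Gaussian reconstruction wins, and the second Gaussian is seeded as an
exact replica (A2=A1, t2=t1, sigma2=sigma1).  The result, together with a
parameter bound box, initializes the global refinement step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ComponentModel, Signal

__all__ = [
    "SigmaGrid",
    "FilterKernel",
    "ScanRecord",
    "ScanResult",
    "Bounds",
    "DegenerateGridError",
    "sigma_bounds",
    "build_kernel",
    "matched_scan",
    "approximate",
]

#: Width-grid increment, in samples.
SIGMA_STEP_SAMPLES = 0.3


class DegenerateGridError(ValueError):
    """The segment is too short for the sigma grid (sigma_max < sigma_min)."""


@dataclass(frozen=True)
class SigmaGrid:
    """Ascending grid of trial Gaussian widths (seconds)."""

    sigma_min: float
    sigma_max: float
    step: float  # seconds (SIGMA_STEP_SAMPLES converted via duration/n_samples)
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.sigma_min > self.sigma_max:
            raise DegenerateGridError(
                f"sigma_min {self.sigma_min:.6g} s > sigma_max {self.sigma_max:.6g} s"
            )
        if v.size == 0 or np.any(np.diff(v) <= 0):
            raise ValueError("grid values must be non-empty, strictly increasing")


@dataclass(frozen=True)
class FilterKernel:
    """Gaussian matched-filter kernel on an integer sample-offset support."""

    support: np.ndarray  # integer offsets S
    weights: np.ndarray  # exp(-(S*dt)^2 / (2 sigma^2)), all in (0, 1]


@dataclass(frozen=True)
class ScanRecord:
    sigma: float
    A1: float
    t1: float
    rmse: float


@dataclass(frozen=True)
class ScanResult:
    records: tuple[ScanRecord, ...]
    best: ScanRecord


@dataclass(frozen=True)
class Bounds:
    """Per-parameter box for (A1, t1, sigma1, A2, t2, sigma2, c)."""

    lower: np.ndarray
    upper: np.ndarray

    def contains(self, p, atol: float = 1e-12) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= self.lower - atol) and np.all(p <= self.upper + atol))


def sigma_bounds(duration: float, n_samples: int) -> SigmaGrid:
    """Width-grid limits from the segment length.

    sigma_min = 5 * duration / n_samples (five sample intervals) and
    sigma_max = duration / 3; the grid steps by 0.3 sample intervals.
    Very short segments where sigma_max < sigma_min raise
    :class:`DegenerateGridError` — lengthen the segment.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    dt = duration / n_samples
    smin = 5.0 * dt
    smax = duration / 3.0
    if smax < smin:
        raise DegenerateGridError(
            f"segment too short: sigma_min {smin:.6g} s > sigma_max {smax:.6g} s; "
            "lengthen the segment (need n_samples >= 15)"
        )
    step = SIGMA_STEP_SAMPLES * dt
    n_steps = int(math.floor((smax - smin) / step + 1e-12))
    values = smin + step * np.arange(n_steps + 1)
    # keep sigma_max itself on the grid if the last step falls short of it
    if values[-1] < smax - 1e-12 * max(1.0, smax):
        values = np.append(values, smax)
    return SigmaGrid(sigma_min=smin, sigma_max=smax, step=step, values=values)


def build_kernel(sigma: float, n_samples: int, dt: float) -> FilterKernel:
    """Gaussian filter on the support S = -ceil(Ns/2)+1 : ceil(Ns/2).

    The support range is intentionally asymmetric for odd Ns (one extra
    positive offset) — it reproduces the integer-increment construction the
    scan is defined with.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = math.ceil(n_samples / 2)
    support = np.arange(-half + 1, half + 1)
    weights = np.exp(-((support * dt) ** 2) / (2.0 * sigma**2))
    return FilterKernel(support=support, weights=weights)


def _correlate_at_centers(x: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    """response[n] = sum_i w[i] * x[n + S[i]] with zero padding."""
    s0 = int(kernel.support[0])
    s_last = int(kernel.support[-1])
    xpad = np.concatenate([np.zeros(-s0), x, np.zeros(s_last)])
    return np.correlate(xpad, kernel.weights, mode="valid")


def matched_scan(segment: Signal, grid: SigmaGrid,
                 amp_mode: str = "signal") -> ScanResult:
    """Sweep the width grid, matched-filtering the segment at each width.

    For each sigma the convolution response is maximized in magnitude over
    all centers (ties broken toward the smallest index); the amplitude is
    read from the signal at the located center (``amp_mode="signal"``,
    default) or from the peak response divided by the kernel energy
    (``amp_mode="mf_gain"``).  Each record stores the RMSE of the
    single-Gaussian reconstruction against the segment.

    The scan runs on the segment as given (callers remove the baseline
    first; :func:`approximate` does).
    """
    x = segment.samples
    n = x.size
    if n < 2:
        raise ValueError("segment must have at least 2 samples")
    dt = 1.0 / segment.fs
    tgrid = np.arange(n) * dt
    records = []
    for sigma in grid.values:
        kernel = build_kernel(sigma, n, dt)
        response = _correlate_at_centers(x, kernel)
        idx = int(np.argmax(np.abs(response)))  # argmax -> smallest index on ties
        t1 = idx * dt
        if amp_mode == "signal":
            A1 = float(x[idx])
        elif amp_mode == "mf_gain":
            A1 = float(response[idx] / np.sum(kernel.weights**2))
        else:
            raise ValueError(f"unknown amp_mode {amp_mode!r}")
        recon = A1 * np.exp(-((tgrid - t1) ** 2) / (2.0 * sigma**2))
        rmse = float(np.sqrt(np.mean((recon - x) ** 2)))
        records.append(ScanRecord(sigma=float(sigma), A1=A1, t1=t1, rmse=rmse))
    best = min(records, key=lambda r: r.rmse)
    return ScanResult(records=tuple(records), best=best)


def approximate(segment: Signal, label: str = "P",
                amp_mode: str = "signal") -> tuple[ComponentModel, Bounds]:
    """Full Step-1 approximation of one component segment.

    Removes the segment mean (which initializes the baseline c), scans the
    sigma grid, and replicates the winning Gaussian into the second one
    (A2=A1, t2=t1, sigma2=sigma1).  Also emits the bound box used by the
    Step-2 solvers: t in [0, duration], sigma in [dt, 2*sigma_max],
    A in +/- 2*max|segment|, c in [min, max] of the segment.  The sigma
    floor of the refinement box is one sample interval, below the scan
    grid's 5-interval floor: the matched filter needs a few samples under
    the template for a stable response, but the refinement must be able to
    reach narrow deflections (a QRS wave spans only a handful of samples
    at ambulatory rates).
    """
    x = segment.samples
    n = x.size
    duration = segment.duration
    grid = sigma_bounds(duration, n)
    c0 = float(np.mean(x))
    centered = Signal(x - c0, fs=segment.fs)
    scan = matched_scan(centered, grid, amp_mode=amp_mode)
    b = scan.best
    init = ComponentModel(label=label, A1=b.A1, t1=b.t1, sigma1=b.sigma,
                          A2=b.A1, t2=b.t1, sigma2=b.sigma, c=c0,
                          duration=duration)
    amax = float(np.max(np.abs(x)))
    a_half = max(2.0 * amax, 1e-6)  # keep the box non-degenerate on flat input
    c_lo, c_hi = float(np.min(x)), float(np.max(x))
    if c_hi - c_lo < 1e-9:
        c_lo -= 1e-6
        c_hi += 1e-6
    dt = duration / n
    lower = np.array([-a_half, 0.0, dt,
                      -a_half, 0.0, dt, c_lo])
    upper = np.array([a_half, duration, 2.0 * grid.sigma_max,
                      a_half, duration, 2.0 * grid.sigma_max, c_hi])
    return init, Bounds(lower=lower, upper=upper)


def scan_to_csv(scan: ScanResult, path) -> None:
    """Dump a scan trace (sigma, A1, t1, rmse) for debugging."""
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in scan.records]).to_csv(path, index=False)
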