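"""Lossy ECG compression via per-beat model parameters.

A record is compressed by fitting the two-Gaussian model to every beat and
storing, per beat, the 7 Gaussian parameters of each of the 5 components
(35 values) plus the 5 segment sizes — 40 numbers per beat regardless of
sampling rate.  Decoding re-evaluates each beat model on its stored
segment grid, which also acts as a denoiser since noise does not survive
the smooth parametric reconstruction.

The closed-form compression ratio for a one-minute record is

    CR = (fs * 60) / (ceil(HR) * (NG*NS + NSS)),   NG=7, NS=5, NSS=5,

where the ceiling covers the worst case of a fractional final beat; the
precision bits cancel because samples and parameters are stored at the
same precision.
"""

from __future__ import annotations

import base64
import json
import math
from dataclasses import dataclass

import numpy as np

from .model import COMPONENT_LABELS, BeatModel, ComponentModel, Signal, evaluate_beat
from .preprocess import DEFAULT_FRACTIONS, detect_qrs, extract_components
from .solvers import SolverConfig, fit_beat

__all__ = [
    "N_GAUSS_PARAMS",
    "N_SEGMENTS",
    "CompressionRecord",
    "compression_ratio",
    "encode",
    "decode",
    "save_record_json",
    "load_record_json",
]

N_GAUSS_PARAMS = 7   # A1, t1, sigma1, A2, t2, sigma2, c per segment
N_SEGMENTS = 5       # P, Q, R, S, T
N_SIZE_ENTRIES = N_SEGMENTS
VALUES_PER_BEAT = N_GAUSS_PARAMS * N_SEGMENTS + N_SIZE_ENTRIES  # 40


@dataclass(frozen=True)
class CompressionRecord:
    fs_in: float
    hr: float                       # measured heart rate, beats/min
    bits: int                       # parameter precision (64 or 32)
    beats: tuple[tuple[float, ...], ...]  # 40 values each
    duration_s: float
    n_gauss: int = N_GAUSS_PARAMS
    n_seg: int = N_SEGMENTS
    n_sizeseg: int = N_SIZE_ENTRIES
    flagged: tuple[int, ...] = ()   # beat indices whose fit did not converge

    def __post_init__(self) -> None:
        if self.n_gauss != N_GAUSS_PARAMS or self.n_seg != N_SEGMENTS:
            raise ValueError("record must use 7 parameters x 5 segments")
        if self.n_sizeseg != self.n_seg:
            raise ValueError("one size entry per segment is required")
        for i, b in enumerate(self.beats):
            if len(b) != VALUES_PER_BEAT:
                raise ValueError(
                    f"beat {i}: expected {VALUES_PER_BEAT} values, got {len(b)}"
                )

    @property
    def stored_values(self) -> int:
        return len(self.beats) * VALUES_PER_BEAT


def compression_ratio(fs: float, hr: float, minutes: float = 1.0) -> float:
    """Closed-form compression ratio for a record of the given length.

    CR = (fs * 60 * minutes) / (ceil(hr * minutes) * 40); monotone
    increasing in fs and non-increasing in hr.
    """
    if fs <= 0 or hr <= 0:
        raise ValueError("fs and hr must be > 0")
    n_beats = math.ceil(hr * minutes)
    return (fs * 60.0 * minutes) / (n_beats * VALUES_PER_BEAT)


def _beat_vector(beat: BeatModel) -> tuple[float, ...]:
    vals: list[float] = []
    for comp in beat.components:
        vals.extend(comp.params.tolist())
    vals.extend(float(n) for n in beat.segment_samples)
    return tuple(vals)


def _beat_from_vector(vec, fs: float) -> BeatModel:
    vec = list(vec)
    if len(vec) != VALUES_PER_BEAT:
        raise ValueError(f"beat vector must hold {VALUES_PER_BEAT} values")
    sizes = [int(round(v)) for v in vec[N_GAUSS_PARAMS * N_SEGMENTS:]]
    comps = []
    for i, label in enumerate(COMPONENT_LABELS):
        A1, t1, s1, A2, t2, s2, c = vec[i * 7:(i + 1) * 7]
        comps.append(ComponentModel(label=label, A1=A1, t1=t1, sigma1=s1,
                                    A2=A2, t2=t2, sigma2=s2, c=c,
                                    duration=sizes[i] / fs))
    return BeatModel(components=tuple(comps), fs=fs,
                     segment_samples=tuple(sizes))


def encode(signal: Signal, solver_config: SolverConfig | None = None,
           fractions=DEFAULT_FRACTIONS, peaks=None, start_offset=None,
           bits: int = 64) -> CompressionRecord:
    """Compress a multi-beat record into per-beat model parameters.

    QRS peaks (detected unless supplied) define the beat windows; the first
    window is extended back to the record start and a tail window to the
    record end, so K peaks give K beats and the decoded record spans the
    full input.  Each beat is segmented into components and fitted with the
    hybrid solver; a failed component leaves its beat flagged (the flat
    fallback keeps the stream decodable).
    """
    cfg = solver_config or SolverConfig(method="approxi_mul", n_starts=8)
    if peaks is None:
        peaks = detect_qrs(signal)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        raise ValueError("need at least 2 detected beats to encode")
    if start_offset is None:
        # Under the fraction layout, the R peak sits at cumulative fraction
        # f_P + f_Q + f_R/2 of a beat; shifting each window back by that
        # fraction of the RR interval aligns windows with beat boundaries.
        fr = np.asarray(fractions, dtype=float)
        r_frac = float(fr[0] + fr[1] + fr[2] / 2.0)
        sp = int(round(r_frac * float(np.median(np.diff(peaks)))))
    else:
        sp = int(start_offset)
    n = len(signal)
    cuts = [int(p - sp) for p in peaks[1:]]
    edges = [0] + [c for c in cuts if 0 < c < n] + [n]
    beats: list[tuple[float, ...]] = []
    flagged: list[int] = []
    for bi, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        window = Signal(signal.samples[a:b], fs=signal.fs)
        segs = extract_components(window, fractions)
        fit = fit_beat(window, segs, cfg)
        if fit.failed:
            flagged.append(bi)
        beats.append(_beat_vector(fit.beat))
    rr = np.diff(peaks) / signal.fs
    hr = 60.0 / float(np.mean(rr))
    return CompressionRecord(fs_in=signal.fs, hr=hr, bits=bits,
                             beats=tuple(beats),
                             duration_s=n / signal.fs, flagged=tuple(flagged))


def decode(record: CompressionRecord) -> Signal:
    """Reconstruct the record by evaluating each stored beat model."""
    parts = []
    for i, vec in enumerate(record.beats):
        try:
            beat = _beat_from_vector(vec, record.fs_in)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed parameter vector for beat {i}: {exc}") from exc
        parts.append(evaluate_beat(beat).samples)
    return Signal(np.concatenate(parts), fs=record.fs_in)


def save_record_json(record: CompressionRecord, path, packed: bool = False) -> None:
    d = {
        "schema": "gaussecg-compressed-v1",
        "fs_in": record.fs_in, "hr": record.hr, "bits": record.bits,
        "duration_s": record.duration_s,
        "n_gauss": record.n_gauss, "n_seg": record.n_seg,
        "n_sizeseg": record.n_sizeseg, "flagged": list(record.flagged),
    }
    if packed:
        dtype = "<f8" if record.bits == 64 else "<f4"
        arr = np.asarray(record.beats, dtype=dtype)
        d["beats_packed"] = base64.b64encode(arr.tobytes()).decode("ascii")
        d["n_beats"] = len(record.beats)
    else:
        d["beats"] = [list(b) for b in record.beats]
    with open(path, "w") as fh:
        json.dump(d, fh)


def load_record_json(path) -> CompressionRecord:
    with open(path) as fh:
        d = json.load(fh)
    if "beats_packed" in d:
        dtype = "<f8" if d["bits"] == 64 else "<f4"
        arr = np.frombuffer(base64.b64decode(d["beats_packed"]), dtype=dtype)
        beats = tuple(tuple(float(v) for v in row)
                      for row in arr.reshape(d["n_beats"], VALUES_PER_BEAT))
    else:
        beats = tuple(tuple(b) for b in d["beats"])
    return CompressionRecord(fs_in=d["fs_in"], hr=d["hr"], bits=d["bits"],
                             beats=beats, duration_s=d["duration_s"],
                             flagged=tuple(d.get("flagged", ())))
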