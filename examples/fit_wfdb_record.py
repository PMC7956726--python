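"""Qualitative demo: fit the model to a locally available WFDB record.

Requires the optional `wfdb` package and a record you have already
downloaded (for example an ambulatory arrhythmia recording); nothing is
fetched over the network.  Usage:

    python examples/fit_wfdb_record.py /path/to/record_name [channel]

Prints per-beat fit quality over the first few beats.
"""

import sys

import numpy as np

import gaussecg as g
from gaussecg.io import read_wfdb


def main() -> None:
    if len(sys.argv) < 2:
        print(__doc__)
        return
    record = sys.argv[1]
    channel = int(sys.argv[2]) if len(sys.argv) > 2 else 0
    sig = read_wfdb(record, channel=channel)
    sig = g.Signal(sig.samples[: int(30 * sig.fs)], fs=sig.fs)  # first 30 s
    den = g.dwt_denoise(sig)
    peaks = g.detect_qrs(den)
    if peaks.size < 3:
        print("fewer than 3 QRS peaks found; check the channel")
        return
    sp = int(0.3 * np.median(np.diff(peaks)))
    seg = g.segment_beats(den, peaks, sp)
    cfg = g.SolverConfig(method="approxi_mul", n_starts=10, seed=0)
    for k, (a, b) in enumerate(seg.beat_windows[:5]):
        window = g.Signal(den.samples[a:b], fs=den.fs)
        fit = g.fit_beat(window, g.extract_components(window), cfg)
        print(f"beat {k}: CORR {fit.whole_beat.corr:.4f} "
              f"RMSE {fit.whole_beat.rmse:.4f} mV")


if __name__ == "__main__":
    main()
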