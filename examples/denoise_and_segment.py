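"""Denoise a noisy strip, locate R peaks, and cut beat windows.

Adds 10 dB white noise to a clean strip, applies Coiflet-6 wavelet
shrinkage, and reports the SNR gain and the beat segmentation.  (Shrinkage
gains several dB against broadband noise; noise concentrated inside the
ECG's own 5-50 Hz band, like muscle artifact, is much harder to remove.)
"""

import numpy as np

import gaussecg as g

clean, _ = g.generate(g.GeneratorConfig())
noisy = g.add_noise(clean, g.NoiseSpec("WN", snr_db=10.0, seed=1))
denoised = g.dwt_denoise(noisy)

def snr(ref, x):
    return 10 * np.log10(np.mean(ref.samples**2)
                         / np.mean((x.samples - ref.samples) ** 2))

print(f"SNR before denoising: {snr(clean, noisy):6.2f} dB")
print(f"SNR after  denoising: {snr(clean, denoised):6.2f} dB")

peaks = g.detect_qrs(denoised)
seg = g.segment_beats(denoised, peaks,
                      start_offset_sp=int(0.3 * np.median(np.diff(peaks))))
print(f"{len(peaks)} R peaks; first inter-peak interval "
      f"{(peaks[1] - peaks[0]) / denoised.fs:.3f} s")
print(f"{len(seg.beat_windows)} beat windows, e.g. {seg.beat_windows[0]}")
# Wavelet shrinkage raises the SNR several dB; the windows tile the strip
# between successive R peaks, shifted earlier so each opens before its P wave.
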