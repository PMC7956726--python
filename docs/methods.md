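# Methods

## Model

A single ECG beat is the concatenation of five component segments (P, Q,
R, S, T). Each component is the sum of two Gaussians plus a constant
baseline, with seven parameters: amplitudes A₁, A₂ (mV), centers t₁, t₂
(s, relative to the segment start), widths σ₁, σ₂ (s, both > 0) and the
baseline c (mV). The exponent convention is exp(−(t−t_c)²/(2σ²))
everywhere — model evaluation, the matched filter, and the codec — and is
recorded in the JSON parameter schema so stored widths are unambiguous.
(The alternative σ² denominator is an exact reparameterization: fits are
unchanged, stored σ values would differ by √2.)

Beat assembly is piecewise by default: each component is evaluated on its
own segment grid with its own baseline, matching the per-component
fitting. A `global_sum` assembly option evaluates all ten Gaussians over
the whole beat with one shared baseline (the sum of the per-component
baselines); for the shipped parameter library, whose bells decay within
their segments, the two differ by at most a few tens of µV. Rhythm strips
tile the beat at period 60/bpm s, rescaling the beat's time axis
proportionally while holding amplitudes fixed — a pure rate change, with
no interval-specific scaling between the PQ, QRS and ST portions. Sample
grids are uniform and 0-based: sample k sits at t = k/fs.

## Step 1: matched-filter approximation

The width grid runs from σ_min = 5 sample intervals to σ_max = one third
of the segment duration, in steps of 0.3 sample intervals (the grid
increment is interpreted in samples, consistent with the sample-unit
support vector of the filter). Segments too short to satisfy
σ_min ≤ σ_max (fewer than 15 samples) raise a degenerate-grid error.

For each trial width a Gaussian kernel is built on the integer support
S = −⌈Ns/2⌉+1 … ⌈Ns/2⌉ — deliberately asymmetric for odd Ns, reproducing
the integer-increment construction; symmetry holds for the sub-vector
excluding the extra endpoint and is tested as such. The segment (with its
mean removed; the mean initializes c) is correlated with the kernel under
zero padding; the maximum-magnitude response locates t₁, ties broken
toward the smallest index. The amplitude is read from the signal at the
located center (default) rather than from the response — the matched
filter locates, the signal provides amplitude; a matched-filter-gain mode
(peak response ÷ kernel energy) is available as `amp_mode="mf_gain"`. The
trial width with the lowest single-Gaussian reconstruction RMSE wins, and
the second Gaussian is seeded as an exact replica of the first.

On segments containing one well-contained bell, the scan's winner agrees
with an exhaustive (A, t, σ) grid search to within one grid step in σ and
one sample in t (tested on 50 random segments). Two qualifications,
verified during development and kept as documented limitations: when the
bell's width is comparable to the segment (no room to decay before the
edges), zero padding biases the response peak toward the segment center
and the scan can land several grid steps from the exhaustive optimum; and
on two-Gaussian segments the scan's signal-amplitude rule and the
exhaustive search's least-squares amplitude can prefer single-Gaussian
compromises several steps apart, although both find the dominant center.
Neither case harms the pipeline — the scan only seeds Step 2.

### Bound box for Step 2

t ∈ [0, duration]; σ ∈ [one sample interval, 2σ_max]; A ∈ ±2·max|segment|;
c ∈ [min, max] of the segment. The σ floor of the *refinement* box is one
sample interval, deliberately below the scan grid's 5-interval floor: the
matched filter needs several samples under the template for a stable
response, but narrow deflections — a QRS wave at ambulatory sampling
rates spans only a handful of samples — have true widths of 3–4 sample
intervals, and a refinement box floored at 5 intervals cannot reach them
(recovery error on synthetic components drops from ~15% to <1% median
when the floor is lowered). Degenerate boxes on flat segments are widened
by 10⁻⁶ so the bounded solver always has an interior.

## Step 2: hybrid global refinement

The local solver is scipy's bounded trust-region-reflective least squares
on the residual vector (the same minimizer as the RMSE, without the outer
square root). Because the trust-region iteration is monotone and the
start point is always included, the refined RMSE never exceeds the
approximation RMSE — this holds unconditionally, not just in expectation,
and is asserted on every fixture.

**ApproxiMul** refines from the approximation plus n_starts−1 uniform
draws within the box and keeps the best optimum. **ApproxiGlo** builds a
Latin-hypercube pool of 10·n_starts candidates, scores each by its
unrefined RMSE, and refines in score order, skipping candidates within an
L∞ distance of 5% of each bound width from an already-refined start; the
approximation is always refined first. This scatter-search realization is
the package's own design (pool size, ordering, basin radius); published
implementations of scatter search leave these internals unspecified, so
no claim is made that it replicates any particular one, and the relative
ranking of the two methods on any given fixture is not asserted anywhere.

Defaults: n_starts = 50, seed = 0 (mandatory — both solvers are
bit-reproducible given the seed), ε = 0 as a pure reporting threshold
(`converged_to_epsilon` flag, never a stopping rule). Returned Gaussians
are canonicalized to t₁ ≤ t₂, so parameter comparisons are well-defined
under the model's swap symmetry.

## Preprocessing

Denoising: Coiflet-6 wavelet, 8 decomposition levels, soft thresholding.
The noise scale is the median absolute deviation of the finest detail
level divided by 0.6745, applied to all levels (single-level rescaling);
each level's threshold minimizes Stein's unbiased risk estimate for soft
shrinkage. A zero threshold leaves coefficients untouched, so clean and
zero signals pass through with negligible distortion. Signals shorter
than 2^levels raise an error naming the maximum feasible level.

QRS detection is not part of the model contribution and uses a standard
energy recipe: band-pass 5–20 Hz, derivative, square, 120 ms moving
average, adaptive threshold (max of 8× the median envelope and 10% of its
peak), 200 ms refractory, followed by refinement to the local maximum of
the raw signal. On generator output it recovers the exact beat count for
SNR ≥ 10 dB at 50–120 bpm.

Beat isolation: with R peaks Tp₁…Tp_K and a start offset Sp, beat k spans
the half-open window [Tp_k − Sp, Tp_{k+1} − Sp) — the windows tile the
span exactly. Sp shifts windows *earlier* so each opens before its P wave
(records can start mid-beat); it defaults to 30% of the median RR
interval, standing in for a manual choice. Component windows are cut at
fractional boundaries, default (P 0.25, Q 0.10, R 0.10, S 0.10, T 0.45),
config-overridable and recorded in output metadata. All indices are
0-based, all windows half-open.

## Metrics

MSE, RMSE as usual; NMSE = Σe²/Σy²_real (energy normalization); NRMSE =
RMSE/(max−min of the real signal) (range normalization); CORR = Pearson,
flagged undefined for zero-variance input. These conventions are written
into every serialized report, because the two normalizations are easy to
confuse across publications. Spectra: one-sided FFT magnitude and Welch
PSD (Hann, segment min(N, 256), 50% overlap); total Welch power agrees
with the time-domain variance within 5% on white noise. The scalogram
difference uses a Mexican-hat CWT (parameter-free) over scales 1–128.

## Generator

The beat parameter library (normal, atrial premature, paced, PVC) is
hand-tuned to qualitative textbook morphology and explicitly provisional:
atrial premature = early narrow peaked P; paced = narrow biphasic
stimulus spike, widened QRS, discordant T; PVC = absent P, broad
high-amplitude QRS with its own segment fractions, discordant T. Entries
are validated by morphology properties (e.g., the PVC's P window is flat,
the R segment holds the beat maximum) and by self-fit correlation, and
any entry can be replaced via the JSON schema. Defaults follow the
generator's reference configuration: 10 s, 72 bpm, fs ∈ {256, 360, 512,
1000} Hz (library native rate 360 Hz; other rates via polyphase
resampling with a Kaiser-windowed antialiasing FIR).

Noise: white (Gaussian), colored (1/f via FFT shaping), and synthetic
surrogates of the classic ambulatory artifacts — baseline wander (0.05 to
0.5 Hz sinusoids with random phases plus a slow random walk), electrode
movement (sparse step transients, lightly smoothed), muscle artifact
(5–50 Hz band-limited bursts under random envelopes), and an equal-power
mixture. Signal power is energy per sample, Py = (1/N)Σy²; the drawn
noise is rescaled so the realized SNR equals the request to floating-point
precision, which is why the calibration tests use a 0.5 dB gate without
any statistical slack. Real noise recordings can be substituted via a CSV
path but are never required.

What the surrogates do *not* emulate: the nonstationarity, electrode
physics and spectral detail of real ambulatory artifacts, beat-to-beat
morphology variability, or heart-rate variability (the generator's RR
intervals are exactly periodic). Passing the synthetic suites therefore
demonstrates correctness of the algorithms under the model's own
assumptions, not clinical performance on real recordings.

## Codec

Encoding stores, per beat, 35 Gaussian parameters plus 5 segment sizes =
40 values. Beat windows come from the detected R peaks; since the
inter-peak construction yields K−1 windows from K peaks, the encoder
extends the first window back to the record start and appends a tail
window to the record end, so K peaks give K beats and the decoded record
spans the full input. The encoder's default start offset is derived from
the fraction layout (the R peak sits at cumulative fraction
f_P + f_Q + f_R/2 of a beat), which aligns component windows with beat
boundaries. Segment sizes are stored per beat; fractional final beats are
handled by the actual stored sizes — the ceiling ⌈HR⌉ appears only in the
closed-form CR. Parameters serialize as 64-bit floats (precision bits
cancel in the CR since samples and parameters share one precision); a
32-bit packed mode halves file size without changing the CR as defined.
Decoding simply re-evaluates each beat model, which discards additive
noise — the codec doubles as a denoiser.

## Problem sizes and test design

The test and acceptance suites run entirely on generator output: 10 s
strips (3600 samples at 360 Hz) for pipeline checks, a 60 s strip for the
empirical-vs-closed-form compression-ratio check, 100 synthetic
components (library parameters perturbed ±20%, noiseless) for parameter
recovery at n_starts = 50, and 50 random single-Gaussian segments of
60–200 samples for the scan-vs-brute-force equivalence. Codec round-trip
tests use n_starts = 4 per component, which already sits deep in the
diminishing-returns regime on clean and 10 dB data. All randomness flows
through explicit seeds; property tests run derandomized.

## Known limitations

- The beat library is a morphological stand-in, not fitted to any
  recording; amplitudes and intervals are plausible, not population
  statistics.
- Piecewise assembly admits small discontinuities (tens of µV) at segment
  boundaries when a bell does not fully decay; real ECGs are continuous.
- The matched scan is biased for bells wide relative to their segment
  (see above); the refinement step, not the scan, is responsible for
  accuracy.
- Single-lead only; no heart-rate variability; no beat-to-beat morphology
  dynamics.
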