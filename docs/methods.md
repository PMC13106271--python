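# Methods

`camhrv` measures heart rate and short-term heart-rate variability (HRV)
from ordinary webcam video traces by remote photoplethysmography (rPPG),
and validates those measurements against an ECG reference. This note
documents the models, the numerical choices, and what the synthetic test
bed does and does not establish.

## Signal model and processing chain

Cardiac ejection modulates the blood volume in facial skin; hemoglobin
absorbs green light most strongly, so the per-frame mean RGB values of
skin pixels carry a small pulsatile component (fractions of a percent of
the baseline) on top of much larger common-mode disturbances: specular
reflection from the epidermis, global illumination changes, and sensor
noise.

**ROI extraction.** Frames plus a face annotation (mask or landmarks —
no detector is bundled; the annotation is an input contract) yield either
one whole-face ("holistic") trace or one trace per 40×40 px patch on the
forehead and cheeks. Non-skin pixels are removed by convex-hull masking
of eye/mouth polygons and by RGB thresholding, keeping only pixels with
every channel in [40, 255]. Patch samples invalid in single frames are
linearly interpolated when the gap is at most 0.5 s; a patch with longer
gaps is dropped for the recording (a choice this package makes; any
interpolation threshold well below the POS window would do).

**POS.** The plane-orthogonal-to-the-skin projection slides a 1.6 s
window (hop one frame) over the trace; each window is normalized by its
per-channel mean, projected onto the fixed chrominance axes (0, 1, −1)
and (−2, 1, 1) — both orthogonal to the intensity direction, so any
common-mode signal is annihilated — and combined as `h = s1 + α·s2` with
`α = σ(s1)/σ(s2)` (α = 0 when σ(s2) = 0). Windows are mean-removed and
overlap-added. Because the normalization divides by the window mean,
static per-channel gains cancel exactly: the output is invariant to
camera white balance.

**Time-domain pulse estimation (pipelines 1–2).** The BVP is smoothed
with a six-frame moving average, bandpassed 0.5–2.5 Hz with a
third-order Butterworth filter, and upsampled to 330 Hz by cubic
splines. Systolic peaks are detected by the event-related moving-average
scheme: the clipped, squared signal is averaged at the peak scale
(111 ms) and the beat scale (667 ms); blocks where the peak-scale
average exceeds the beat-scale average plus 0.08× the mean squared
signal, and which span at least the peak window, each contribute one
peak (the block argmax), with a 0.4 s refractory rule keeping the larger
of two close peaks. All detector terms scale with the square of the
signal, so peak times are invariant to amplitude scaling. The detector
constants are the published defaults of the cited algorithm family.
Filtering throughout is zero-phase (forward–backward) so no group delay
is added to the alignment budget; stated orders refer to the designed
filter before the two passes. Moving averages shrink at record
boundaries instead of padding, avoiding spurious edge beats.

**Frequency-domain pulse estimation (pipelines 3–4).** The BVP is cut
into 12 s windows with 50% overlap. Per window, a Hann periodogram gives
the center frequency f_c (argmax in the 0.5–2.5 Hz search band) and an
SNR — power in f_c ± 0.1 Hz over the rest of the band, in dB. The SNR
maps to a bandwidth by a clamped linear ramp: 0.2 Hz at ≤ 0 dB up to
0.8 Hz at ≥ 10 dB (any monotone map would satisfy the design intent;
the ramp is the simplest and is config-exposed). The window is
bandpassed to f_c ± B/2 (intersected with the search band) and
demodulated with DESA-1: with the Teager–Kaiser operator
Ψ[x](n) = x(n)² − x(n−1)x(n+1) and y the backward difference,
Ω(n) = arccos(1 − (Ψ[y](n) + Ψ[y](n+1)) / (4Ψ[x](n))), exact for a pure
sinusoid. Samples with Ψ[x] below 1e−6 of the window maximum are marked
invalid and filled by linear interpolation. Window tracks are stitched
by Hann-weighted overlap-add (invalid samples excluded from numerator
and weight) and scaled to BPM; instantaneous frequency is clamped to the
search band, so HR stays in [30, 150] BPM.

Two numerical choices here matter and were genuinely open:

* *Window length 12 s.* The periodogram bin width is 1/T; at 10 s the
  0.1 Hz quantization of f_c is as large as half the narrowest adaptive
  band, which mis-centers the filter often enough to attenuate HRV
  sidebands. 12 s gives 0.083 Hz bins while still adapting to drifting
  HR; both are config-exposed.
* *Adaptive-filter order 8.* The zero-phase pass squares the magnitude
  response; a low-order Butterworth then attenuates in-band FM sidebands
  (the HRV information) by several percent near the band edge. Order 8
  makes the squared response near-rectangular, preserving in-band
  sidebands while keeping the stopband.

**MRC patch weighting (pipeline 4).** Each patch's goodness is its
spectral power within ±0.1 Hz of the recording-level center frequency
divided by its total power in 0.5–5 Hz; weights are normalized to sum to
one. The recording-level center frequency is a peak-power-weighted
median of the per-patch periodogram argmaxes: a plain median is
undefined behavior for an even number of patches (it can fall between a
strong patch's pulse peak and a junk patch's noise peak); the weighted
median reduces to the plain one when peak powers are comparable. The
0.1 Hz narrow half-width is this package's choice — a finite band is
needed on a discrete spectrum.

**Pseudo-beat reconstruction.** The frequency-domain pipelines produce
no discrete beats, so SDNN/RMSSD are computed from pseudo-beats:
f(t) = HR/60 is integrated by the trapezoid rule and a beat is placed at
each unit crossing of cumulative phase (sub-step position by linear
interpolation). For an instantaneous-HR series generated by a
linear-between-beats phase model this inverse is exact to one grid step,
which the tests exploit. Direct statistics on the 60000/HR(t) trajectory
would be a different estimand (they weight by time, not by beat) and are
deliberately not the default.

**ECG reference.** The ECG is high-pass filtered above 0.5 Hz
(fifth-order Butterworth, zero-phase) and notch-filtered at 50 Hz
(quality factor 30). R-peaks: the absolute gradient is smoothed at the
QRS scale (100 ms) and compared with 1.5× its 0.75 s rolling mean;
supra-threshold regions at least 0.4× the mean region width long are QRS
candidates; the maximum of |signal| in each region is the R-peak, with a
0.3 s refractory period. Both the gradient magnitude and |signal| are
sign-blind, so inverted electrode polarity yields the same beats.
Flagged noisy segments (an input — identifying them was a human step in
the original workflow; only the repair rule is normative) are repaired
by inserting beats at the mean spacing of the three preceding intervals
when the gap is at most 3 s, stopping when the next detected beat is
closer than one spacing; longer interior gaps exclude the record, and
boundary gaps trim the record instead. Intervals become instantaneous
HR (60000/IBI, anchored at the later beat — the causal choice, matching
the pseudo-beat inverse), interpolated by a monotone cubic spline (no
overshoot beyond anchors) on the 330 Hz grid and decimated by stride 11
to 30 Hz.

**Benchmarking.** After advancing the rPPG timeline by the alignment
shift (500 ms by default, compensating pulse-arrival time plus camera
latency; zero for synthetic sessions, which model neither), five scores
are computed per recording: Pearson's r and normalized DTW on the
instantaneous-HR series, and absolute errors of mean HR, SDNN (sample SD
of intervals), and RMSSD (RMS of successive differences). Normalized DTW
divides the optimal alignment cost (|a_i − b_j| local cost, steps down/
right/diagonal, no window) by the optimal warping-path length, choosing
the shortest path among minimum-cost paths; ties are detected with a
small relative tolerance so the normalization is stable under
floating-point perturbation. Aggregation reports mean, sample SD, and
unscaled median absolute deviation (no 1.4826 factor), optionally
averaging within participant first. Bland–Altman limits of agreement
are bias ± 1.96 × sample SD of paired differences.

**Equivalence statistics.** TOST power uses the normal approximation of
the sampling distribution with t critical values:
power = Φ((U − t*·SE − μ)/SE) − Φ((L + t*·SE − μ)/SE), SE = σ/√n_eff,
df = n_eff − 1 (fractional df handled natively); clustering enters
through the design effect deff = 1 + (m − 1)·ICC, n_eff = n·m/deff. A
noncentral-t variant is available behind `method="noncentral_t"`. The
cluster bootstrap resamples participants with replacement (as many as
observed, keeping all their recordings), refits both outcome models per
resample with the injectable fitter (ordinary least squares by default —
mixed-model engines are deliberately out of scope), and declares a
coefficient equivalent when at least 90% of the bootstrapped
rPPG-minus-ECG differences fall within the SESOI (±15 ms for HRV
metrics; ±0.1/±0.2 SD for standardized contrasts). Emotion-task
preprocessing converts instantaneous HR to change scores against a 1 s
pre-trial baseline, bins them in half-second half-open windows relative
to the second stimulus (S2 defaults to trial start + 6 s: 1.5 s cue +
4.5 s anticipation), averages bins into the D1/A1/D2/PDP component
windows by bin midpoint (boundary midpoints join the later component),
and z-standardizes by the ECG dataset's moments so both modalities live
on one effect-size scale.

## Synthetic test bed

The generator produces ground-truthed physiology, not realistic video:

* Intervals: IBI_k = mean + A_LF·sin(2π·0.1·t) + A_HF·sin(2π·0.25·t) +
  white jitter, all intervals constrained to [300, 2000] ms. Defaults —
  800 ms mean (75 BPM), 35 ms LF, 25 ms HF, 10 ms jitter — give
  SDNN ≈ 32 ms and RMSSD ≈ 28 ms, typical resting short-term values.
  Cardiac phase is linear between beats (integral-pulse-frequency-
  modulation style), so pseudo-beat reconstruction has an exact inverse.
* ECG: unit Gaussian R-waves (σ = 10 ms) at beat times with 0.5 s
  pre/post-roll, plus optional white noise.
* RGB: c(t) = base_c·(1 + g_c·A·p(φ(t)) + s(t) + d(t)) + ε(t) with the
  two-harmonic pulse p(φ) = sin φ + 0.3 sin(2φ+1), green-dominant gains
  (0.35, 1, 0.6), pulse amplitude 0.5% — the weak-signal regime rPPG
  operates in. Specular flicker s is common-mode by construction; drift
  d is a slow sinusoid; ε is white sensor noise on the *per-frame mean*,
  defaulting to 0.05 counts: per-pixel noise of a consumer sensor
  (~1–2 counts) averaged over thousands of skin pixels leaves a few
  hundredths of a count, and 0.05 adds margin for quantization and mask
  imperfection. Motion bursts (Poisson-timed 0.5 s Hann bursts, drawn
  independently per channel so they are *not* common-mode) emulate head
  movement at ~6/min with 2% relative amplitude in the motion preset.
* Frames: uniform fill of a face box with the trace (8-bit quantized),
  background constant 10 — below the skin threshold. Quantization is
  applied only at the frame level so trace-level tests stay exact.

What passing tests show: the chain recovers the generator's HR and HRV
under weak-signal, mild-noise conditions, the POS/DESA/DTW/TOST
implementations agree with analytic or enumerative oracles, and the
frequency-domain pipeline degrades more gracefully than the peak-based
one under non-common-mode motion. What they do not show: performance
under real illumination changes, head pose, skin-tone variation,
compression artifacts, or face-tracking error — none of which the
generator models. Real-data error levels are roughly an order of
magnitude above the synthetic ones.

## Degenerate inputs and tie-breaks

* POS: σ(s2) = 0 in a window → α = 0 (s1 alone); a zero-mean channel is
  a hard error ("degenerate channel").
* Peak detector: no qualifying blocks → empty result with quality flag,
  not an exception; the pipeline raises only when an HR series is
  requested from fewer than two peaks.
* MRC: all patches with zero band power → uniform weights.
* Stitching: zero accumulated weight → nearest-valid fill, flagged.
* DTW: cost ties within 1e−9 relative tolerance break toward the
  shorter path.
* Aggregation: missing (NaN) metric values are excluded listwise per
  metric; a single recording reports SD as missing and MAD 0.
* Plausibility: intervals outside [300, 2000] ms are flagged and
  excluded from HRV statistics, never silently dropped from the series.

## Problem sizes

The test suite and the acceptance script use 60 s recordings at 30 Hz
(camera) and 330 Hz (ECG): long enough for stable ultrashort-term
SDNN/RMSSD, matching the measurement setting the package targets.
Recovery statistics use 50–100 recordings; the bootstrap uses 50
clusters × 5 recordings and 1,000 resamples per run, with the
equivalence rule unchanged from the 10,000-resample default
configuration.

## Known limitations

* No face detector or tracker is included; annotations are inputs.
* Patch anchor defaults are a documented placeholder (3 forehead + 2×2
  per cheek on a normalized face box), not a claim about any specific
  landmark scheme.
* The SNR→bandwidth ramp and demodulation window are heuristics
  satisfying a qualitative design objective; both are config-exposed.
* Noisy-segment *identification* for ECG is a non-normative helper
  (beat-free spans > 2 s); production use should supply curated segment
  lists.
* OLS is the only bundled fitter for the equivalence bootstrap; mixed
  models must be injected.
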