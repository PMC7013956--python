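# Methods

## Signal model and codec chain

`adaptecg` treats a multi-lead ECG as a uniformly sampled voltage
matrix (μV) at rate fs with a known ADC quantum (default 12 bits over
±5 mV, ≈2.44 μV/LSB). The encoder runs five stages:

1. **Beat detection.** Band-pass 5–25 Hz (zero-phase Butterworth),
   RMS combination over leads, squaring, 150 ms moving-window
   integration, peak picking above an adaptive (purely relative)
   threshold with a 200 ms refractory period, and refinement of each
   fiducial to the local band-passed-amplitude maximum. All
   thresholds are relative, so detection is invariant to overall
   gain.
2. **Wave delineation.** The five borders (P-onset, P-end, QRS-onset,
   QRS-end, T-end) are found once for all leads on the RMS-combined
   signal. For each wave, a smoothed derivative-energy envelope is
   followed outward from the wave's energy peak until it stays below
   `max(2 × noise RMS, 5 % of the wave's envelope peak)` for 6 ms.
   The noise RMS is the 20th percentile of the envelope (baseline
   sections dominate that statistic); the 5 % floor corresponds to
   the point three Gaussian widths from a wave centre and keeps the
   criterion meaningful in noise-free signals. QRS borders use a
   0.5–40 Hz version with light (6 ms) smoothing; P/T borders use a
   0.5–25 Hz version with heavier (8 ms) smoothing. When envelope
   skirts of adjacent waves overlap and no crossing exists, the
   border falls back to the inter-wave energy minimum. Beats whose P
   or T wave stays below twice the noise floor are dropped; the codec
   covers such spans at maximum relevance (never under-sample on
   uncertainty). External reference annotations are accepted
   everywhere as a drop-in substitute.
3. **Relevance adaptation.** The template (44 bins × 32 ms, values in
   [0, 1], landmarks at samples (106, 196, 246, 338, 672) of the
   500 Hz normalized-beat grid) is projected per beat by continuous
   piecewise-linear landmark registration; values between bin centres
   are linearly interpolated (monotonicity-safe). Outside the
   annotated span the template head/tail continue at native speed and
   hold the edge value; overlapping continuations of neighbouring
   beats merge by pointwise maximum, so the relevance between beats
   decays to the template's edge (floor) level.
4. **Interval law and quantization.** ls(t) = Tm + (Ts − Tm)·aMRF(t),
   snapped to the 2^q-level grid Ts + p·(Tm − Ts)/2^q. With the
   default (fs, fm, q) = (500 Hz, 100 Hz, 6 bits) the step is
   0.125 ms and the longest representable interval is 9.875 ms — code
   63, one step short of Tm; with fm = 50 Hz the step is 0.28125 ms.
   The encoder walks the record accumulating quantized intervals, so
   sample times are exact sums of grid quantities and the decoder
   reproduces them bit-identically from the codes.
5. **Anti-alias filtering and resampling.** One order-10 linear-phase
   FIR kernel per interval code, least-squares fitted (frequency
   sampling) to the first-order magnitude 1/√(1 + (f/fc)²) — a gentle
   6 dB/octave roll-off — with fc = 0.45× the code's local rate and
   DC gain normalized to exactly 1. Code 0 (native rate) uses the
   identity impulse: its cutoff would sit at the Nyquist margin, and
   this makes full-relevance coding an exact identity path. Filtering
   happens on the uniform grid (sample-wise kernel selection,
   reflection-padded edges, zero phase); cubic splines (not-a-knot)
   then evaluate all leads at the shared non-uniform times.
   Filter-then-interpolate was chosen over interleaving the two; the
   alternatives differ only at segment edges.

Because the maximum interval (9.875 ms) is shorter than Tm, the
encoder output has lower-uniform (Beurling-style) sampling density
above fm = 100 Hz everywhere, i.e. at least twice the slowest
kernel's 45.6 Hz cutoff — the stable-reconstruction density condition
holds by construction.

Sample values are re-quantized to the record's ADC grid and stored
bit-packed (default 12 bits) next to the 6-bit code stream in the
NUECG container (little-endian header: version, lead count, quantizer
bits, bit depth, fs, fm, code count, uniform sample count of the
covered span, amplitude resolution in nV/LSB, lead labels). The
uniform sample count makes decode(encode(x)) exactly span-aligned
with x; the resolution is stored as float64 so containers round-trip
bit-exactly.

## Relevance templates

The packaged `gmrf_default` is a hand-drawn approximation of the
gaze-derived generalized relevance histogram (the published bin
values exist only graphically): low baseline attention (0.05–0.08), a
P-wave bump (≈0.55), the maximum over the QRS complex (1.0), a broad
ST/T shoulder (≈0.4–0.5) decaying toward T-end. `smrf_qrs_roi` is a
region-of-interest variant for conduction-defect work-ups: relevance
concentrated at QRS-end and the ST segment, P-wave de-emphasized.
Both are user-replaceable via JSON/CSV files with the same schema
(name, bin_length_s, values, five landmarks); values above 1 are
interpreted as raw histogram counts and rescaled by the maximum.

## Synthetic data

Each beat is a sum of five Gaussian kernels (P, Q, R, S, T) with
textbook amplitudes (P 120, Q −100, R 1000, S −200, T 250 μV in lead
II scale), one shared morphology scaled per lead by fixed uneven
gains, plus white Gaussian noise (default 5 μV RMS) and 12-bit
amplitude quantization. Ground-truth borders are wave centres ± 3
widths, clipped to non-overlap. The generator emulates what the codec
assumes — clean, pre-filtered resting 12-lead records at 500 Hz — and
deliberately omits baseline wander, powerline interference, ectopy,
atrial fibrillation and beat-to-beat morphology variability.
Consequently the test results show that the codec chain is correct
and that distortion localizes outside the waves under realistic
morphology and noise; they do not certify performance on abnormal
rhythms or noisy ambulatory data, where delineation quality dominates
(unresolvable beats degrade compression, not fidelity, by design).
One quirk of the synthetic records: between beats the reference
signal is almost pure noise, so the out-of-wave *relative* error
(PRD ≈ 90 %) is much larger than on real records whose baseline
carries physiological content — the absolute μV errors remain modest.

## Distortion metrics

PRD is computed without mean subtraction, over all leads jointly;
local PRD restricts the same formula to the union of P, QRS and T
(QRS-end→T-end; no T-onset fiducial exists) spans and their
complement, with an average per-beat peak-to-peak error in μV per
region. The compression ratio counts payload bits only:
CR = N·L·sr / (M·L·sr + M·q).

The 18 diagnostic features are measured on one lead (lead II when
present) relative to the PR-segment baseline. Conventions the feature
list does not itself fix: QT-peak is QRS-onset→T-peak; ST elevation
is read 60 ms after QRS-end; ST slope is the regression slope over
QRS-end+40…120 ms, with shape classes horizontal/up-/downsloping at
±0.5 μV/ms; P/T shape is positive/negative/biphasic by the signed-
area ratio (80 %/20 % cutoffs); QRS peak count is the number of
alternating-sign extrema above 10 % of the dominant QRS amplitude; a
Q wave exists when the pre-R trough drops below −25 μV; a delta wave
is flagged when the first 20 ms of a long (>110 ms) QRS rise at under
10 % of its steepest slope.

WDD normalization divides each numeric difference by
max(|β|, |β̂|, ε) and clips to [0, 1], so the trace normalization
bounds WDD at 100. The floor ε is per feature class: 10 ms for
durations (the delineation tolerance), 25 μV for amplitudes (the
wideband-noise acceptability level of interpretive
electrocardiographs), 250 μV/s for the ST slope, 1 for counts.
Without these floors a feature that sits near zero on normal beats
(ST elevation, typically ±5 μV of noise) would saturate its
distortion term on sub-noise disagreements and dominate the metric.
Booleans and shape classes contribute 1 on mismatch. With
max-normalization the WDD is symmetric in its arguments.

The analytic stream estimate d = [fm + (fs − fm)·bl·ΣMRF]·sr is
implemented literally. Its units balance only when ΣMRF is taken per
duration-normalized beat with bl in seconds — it is an approximation
that over-estimates for slow rhythms (long floor-relevance gaps) and
under-estimates for fast ones, and is exposed as a planning aid, not
a guarantee.

The Beurling density diagnostic uses the finite-record estimate
min over sliding windows of (count in window)/window length; tests
and the acceptance script use a 1 s window on 10 s records.

## Problem sizes and numerical choices

Test and acceptance runs use 10 s, 12-lead, 500 Hz records (5000
samples/lead, 10–14 beats) and ten independent seeds with heart rates
drawn in 60–90 bpm; this exercises every code path while keeping the
full suite in a few seconds. Reconstruction oracles: a cubic
polynomial must survive encode→decode to <1e−6 of its range (splines
reproduce cubics; run with the anti-alias stage off, since any
unity-DC smoothing kernel perturbs a polynomial at ~1e−5, and with a
31-bit sample container so value quantization does not mask the
spline property), and a 5 Hz tone coded entirely at the minimum rate
must round-trip below 1 % PRD with the filter on (measured ≈0.33 %,
mostly the filter's in-band droop at 5/45.6 of the cutoff).
Tie-breaks and degenerate inputs: interval codes round half away
from zero and clip to [0, 63]; flat records yield no beats and are
coded, with a warning, at maximum relevance; annotations that are
non-monotone or leave the record fall back to maximum relevance over
their span; empty metric regions are reported absent rather than
zero.

## Known limitations

- Delineation is derivative-energy based; wavelet delineators are out
  of scope, as are beat classification and arrhythmia logic. Border
  accuracy on clean synthetic beats is within ±16 ms (half a template
  bin, the codec's stated tolerance margin); heavy noise (≥10 μV RMS)
  degrades P-onset first.
- The packaged gMRF is an approximation; quantitative compression
  figures depend on the template's relevance mass (mean bin value
  ≈0.41 → CR ≈ 2.6–2.9 at fm = 100 Hz on the synthetic records).
- Electrical-axis features (P/QRS/T axis) are not computed (they need
  a defined lead geometry); the feature set is the 18-component WDD
  vector only.
- No beat-to-beat prediction or lead decorrelation; the codec exploits
  only local oversampling.
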