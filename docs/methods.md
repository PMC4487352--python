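# Methods

## Scope and model of the data

`isocall` analyzes session recordings of kitten vocalizations: long mono
recordings (reference sampling rate 44.1 kHz) containing a few hundred
calls above a stationary noise floor. The call type of interest is the
voiced isolation call — a harmonic stack with fundamental frequency (F0)
near 1 kHz, durations from a few hundred milliseconds up to ~2 s, and, in
young animals, an upward/downward FM sweep at call onset that disappears
with maturation. Unvoiced (purr-like) and combined calls (unvoiced start
switching into a voiced call) occur alongside and are classified but not
structurally analyzed. Nonlinear phonation phenomena — subharmonics,
frequency jumps, biphonation — appear inside voiced calls and perturb the
harmonic ratio F1/F0, the package's central structure statistic.

All amplitudes are full-scale relative; a single per-session constant
`calibration_db` (default 94 dB SPL at RMS 1.0, configurable) converts RMS
to sound pressure level. Absolute SPL is therefore reproducible only up to
this additive constant, which is how a calibrated measurement chain enters
the analysis. Times are seconds from session start; sample `i` covers
`[i/fs, (i+1)/fs)`. Sessions at other sampling rates are accepted without
resampling: every window is specified in milliseconds and converted to
samples by rounding.

## Detection

The session is high-pass filtered (Butterworth, order 10, 500 Hz cutoff)
to remove low-frequency energy not present in isolation calls. The filter
is designed as second-order sections and applied forward–backward, so the
effective response is the squared Butterworth magnitude and segment
boundaries carry no group delay.

A sliding RMS with a 90-ms window and 10-ms hop (the hop is a package
choice — it aligns RMS positions with the 10-ms voicing frames at
sub-window resolution) is computed over the whole session; the detection
threshold is 130 % of the session minimum RMS. Each RMS value is attributed
to its **window center**: with the threshold crossing anywhere inside the
window, this bounds onset/offset errors by half a window (45 ms) at any
SNR, whereas start-of-window attribution biases onsets early by up to a
full window at high SNR. Above-threshold runs separated by less than 50 ms
are merged (guarding against the splitting of single calls at brief
amplitude dips) and runs shorter than 30 ms are dropped; both are
configurable. A session whose minimum RMS is exactly 0 (digital silence)
would yield a zero threshold; the smallest positive RMS value is then used
instead, with a warning.

## Voicing and call classes

Detected segments are cut into non-overlapping 10-ms frames. A frame is
voiced when the ratio of the maximum autocorrelation over positive lags to
the lag-0 value exceeds 0.6; the lag search covers fundamentals of
400–2000 Hz, generous slack around the ~1 kHz kitten F0. The biased
(unnormalized-taper) autocorrelation estimator is used; at the longest
searched lag it shrinks the ratio by ~25 %, which the 0.6 criterion
tolerates for genuinely periodic frames while keeping white and purr-like
noise far below threshold.

The simple-inverse-filter-tracking correction whitens each frame with an
order-12 LPC inverse filter (autocorrelation method, solved via Toeplitz
recursion with light diagonal loading) and re-scores the residual's
autocorrelation peak. The final flag is `raw OR residual`: whitening can
reveal periodicity masked by strong spectral coloration, but a
high-order predictor annihilates a clean low-harmonic-count stack (the
residual is numerical noise), so the residual score must not overrule a
positive raw decision. A continuity rule then flips isolated single-frame
disagreements with both neighbours.

Whole-call classification: `combined` when a leading unvoiced run of
≥ 100 ms is followed by a voiced run of ≥ 100 ms; otherwise `voiced` when
at least half the frames are voiced and the leading unvoiced run is short;
otherwise `unvoiced`. The 50 %/100 ms decision constants are package
conventions.

## F0 and F1 tracking

Per voiced frame, F0 = fs / (best autocorrelation lag), with the lag search
restricted to frequencies within ±30 % of the expected F0 maximum (default
1000 Hz, configurable per session). The constraint is what defends against
octave errors: a stack with strong components at F0/2 has its *global*
autocorrelation maximum at twice the true period, but that lag lies outside
the band. The winning lag is refined by parabolic interpolation of the
autocorrelation peak, giving sub-sample period resolution (~0.1 % at 1 kHz
and 44.1 kHz). Frames whose in-band peak ratio falls below 0.3 are marked
invalid — the automatic replacement for manual contour screening; features
are computed over valid frames only, and calls with fewer than 3 valid
frames yield no structure features.

F1 is located on a 10-ms/50 %-overlap time–frequency representation
(Hamming window, zero-padded to 1024 bins, ~43 Hz bin spacing), smoothed
along frequency with a 5-point median filter. The dominant bin within
[1.5, 2.5]·F0 is taken from the smoothed frame; since the median filter
flattens a smooth peak into a plateau of equal values, ties are broken
toward the bin the raw spectrum favours, and the frequency is refined by
parabolic interpolation of raw log-power. The [1.5, 2.5]·F0 band is a
package convention: wide enough that F1/F0 is informative (it can deviate
from 2, e.g. when a 1.5·F0 subharmonic outweighs the second harmonic —
deliberate, documented behaviour), narrow enough to exclude F0 itself and
the third harmonic.

**Median-filter invariance.** The smoothing step is asserted not to move
per-frame dominant-frequency positions. Exact `argmax` equality is the
wrong formalization: for a smooth peak, the filtered values at the peak and
at a neighbour can be the *same* input sample, and first-occurrence
tie-breaking then reports a one-bin "shift" that is pure tie artefact. The
package therefore checks that the raw dominant bin remains a maximizer of
the smoothed frame, excluding frames whose total power is below 10⁻⁴ of
the strongest frame (an essentially empty frame has no meaningful dominant
bin).

## Spectra

Average spectrograms use a Hamming window of 1024 samples with 75 %
overlap; each eligible call's linear-power spectrogram is normalized to its
own maximum, all calls are left-aligned at onset, and frames are averaged
with a denominator that counts only the calls still defined at that frame
index — zero-padding shorter calls would bias late frames downward.
Eligibility: voiced calls of 100–1500 ms (unvoiced and combined calls are
excluded so the onset region stays homogeneous). Linear power is averaged
(normalization before averaging); a power-vs-amplitude normalization
switch is deliberately not exposed — power is used throughout. Welch
spectra (FFT 1024, Hamming) are normalized to their maximum per call and
averaged arithmetically per group. A 5-ms/97 %-overlap rendering preset
exists only for visual inspection via the CLI `report` command.

## Statistics

Analysis is session-first: features are averaged per session (duration and
level over all calls; F0 and harmonic-ratio statistics over voiced calls
only), and grand means average session means — never call-weighted pools.
Age bins map postnatal days 30–35, 36–42, 44–58, 64–103 to 1, 1.5, 2, 3
months; days in the gaps are flagged out-of-range and excluded.

Normality is checked with the Anderson–Darling statistic using Stephens'
small-sample case with estimated mean and variance (scipy's implementation)
at α = 0.10. Group comparisons use an F test for variance equality (larger
variance over smaller, two-sided p) and a two-tailed t test: pooled when
the F test does not reject at α = 0.05, Welch otherwise; the choice is
recorded per comparison. Normality failures are flagged in the output but
do not switch the test, and no multiple-testing correction is applied —
both deliberate properties of the emulated battery. Sessions with zero
detected calls are excluded from summaries with a warning.

## The simulator

Voiced calls are sums of harmonics `k·F0(t)` with amplitudes rolling off
6 dB per harmonic (log-normal per-call jitter, SD 0.1–0.25 by group),
10-ms raised-cosine ramps, and RMS scaled exactly to the target level. The
F0 contour is a raised-cosine up/down sweep of extent `sweep_up` (default
150 Hz) within the first `sweep_frac` (default 0.2) of the call, then the
base F0. Phenomena: subharmonics add components at 0.5/1.5/2.5·F0 with a
per-call amplitude drawn U(0.2, 0.5) — occasionally rivalling the second
harmonic, which is exactly what perturbs measured F1; frequency jumps step
F0 by ×1.15±ε at a random interior time; biphonation adds a second
two-harmonic stack at an incommensurate fundamental (ratio U(1.17, 1.28)).
Unvoiced calls are 0.5–8 kHz bandpass noise with 20–30 Hz amplitude
modulation — wideband enough that autocorrelation decays before the
shortest voicing lag. Combined calls crossfade an unvoiced part into a
voiced part over 10 ms, with the truth boundary at the crossfade midpoint.

Sessions place calls at random non-overlapping onsets with ≥ 200 ms gaps
(slack distributed by normalized uniform draws) over a white noise floor
(default 40 dB SPL against 65 dB calls: SNR ≥ ~20 dB). A master seed
spawns per-call seeds by a counter scheme, so sessions are bit-reproducible
and individual calls reproducible in isolation.

Cohort presets encode the study conditions the simulator emulates. The F0
schedule is 1100/1000/900/800 Hz at 1/1.5/2/3 months — a simulator
convention matching "near 1 kHz" with a developmental decline, not a
measured table. Hearing: baseline, onset sweep present below 2 months,
5 % phenomena, 6 % unvoiced. Hearing-impaired: more unvoiced calls (20 %),
more combined calls, the largest harmonic-amplitude jitter, sweep
persisting until 3 months, slight harmonic instability. Deaf: +10 dB
level, sweep persisting at all ages, more phenomena (30 %), and a
continuous phonation-instability term — harmonics ≥ 2 drift in relative
frequency (low-pass-filtered noise below 20 Hz, SD 1.5 %) and sit slightly
sharp (+1 % detune). The drift term models the smeared/broadened spectral
peaks of deaf phonation as a property of *every* call, rather than leaving
group differences to rare discrete events; its bandwidth is chosen slow
against the 10-ms analysis frame yet fast enough that each call samples
many independent excursions, so per-call harmonic-ratio SD concentrates
around its expectation. The simulator does **not** model vocal-tract
formants, purr biomechanics, motivational state, or animal movement
relative to the microphone (level is exact up to the programmed jitter) —
so passing tests demonstrate estimator correctness under the generative
model, not robustness to everything real recordings contain.

## Validation design and problem sizes

The validation battery (tests and `scripts/acceptance.py`) runs at desk
scale: a 120-s, 40-call session for segmentation scoring (call rate
~20/min, within the realistic 200–600-calls-per-30-min range); 10,000
frames for voicing accuracy; 200 constant-F0 calls in 700–1300 Hz for F0
recovery; 50 matched cohort pairs of 12 calls for the harmonic-ratio
phenomena response; 100 calls for the median-filter invariance; 2,000
replicates for the type-I-error and normality-pass rates; and a full study
of 3 groups × 4 ages × 8 sessions × 40 calls for pattern recovery. Session
count per cell and calls per session were sized so the programmed group
effects are statistically recoverable with the battery's own two-sample
tests at these scales; sessions are generated and analyzed one at a time,
so memory stays bounded by a single 120-s waveform.

## Known limitations

* Absolute SPL depends on an externally supplied calibration constant.
* The harmonic-ratio estimator reports F1 from a bounded search band;
  under strong subharmonics it legitimately returns 1.5·F0, which raises
  within-call variability — an intended signal, but one that conflates
  "second harmonic moved" with "a different component won the band".
* The F0 estimator's ±30 % constraint assumes the expected F0 maximum is
  roughly known (a two-pass mode re-estimating it from the session median
  is available via the config's expected-F0 field); calls whose true F0
  leaves the band lose frames to the validity floor rather than producing
  wrong values.
* Overlapping calls are not resolved; detection is a single-threshold
  energy scheme by design, with no spectral subtraction or learned
  components.
* The t-test battery is run regardless of normality outcomes (failures are
  flagged, not acted on), and p-values are uncorrected for multiplicity.
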