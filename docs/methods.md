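# Methods

This note records the models and procedures the package implements, the
parameter choices that matter, and what the synthetic validation does and
does not establish. Conventions throughout: time in seconds from recording
start, intervals half-open [start, end), sampling rate 1017 Hz, theta =
5–12 Hz, angles in radians in (−π, π].

## Signals and filtering

Two FIR filter scales are used deliberately, because they answer different
questions:

- **Narrow-transition filters** (windowed-sinc, Hamming window; transition
  0.5 Hz for delta/theta/beta, 2 Hz for the gamma bands) for stationary
  spectral quantities — band power, envelope statistics over whole
  sessions, envelope-lag cross-correlation. The symmetric kernel is applied
  once by FFT convolution and re-centred by its integer group delay, which
  is exactly zero-phase. The cost is a long impulse response (~6.6 s for
  theta), acceptable when the quantity is averaged over windows much longer
  than the kernel.
- **Event-scale filters** (same design, kernel spanning 3 cycles of the
  band centre ≈ 0.35 s for theta) for anything resolved around discrete
  bursts: burst detection, peri-burst phase-locking, post-burst phase
  offsets. A narrow-transition kernel smears a 0.4-s burst over seconds and
  leaks its phase into the pre- and post-burst windows; the 3-cycle kernel
  is the standard wavelet-like compromise. Sessions shorter than a kernel
  raise an error (event-scale) or fall back to a truncated kernel with a
  warning (narrow).

The 60 Hz notch is an IIR notch (Q = 30) applied forward–backward
(`filtfilt`), giving > 30 dB rejection at 60 Hz and < 1 dB ripple below
55 Hz. Welch PSDs use 6-s non-overlapping Hann windows with nfft = 8096;
band power integrates the density over the band limits (trapezoid) and
relative power divides by the 0–55 Hz total. The analytic signal uses the
Hilbert transform; phase follows the cosine convention (zero at a positive
peak).

Lagged coherence is computed per integer-Hz centre frequency in the band:
the signal is cut into consecutive epochs of `n_cycles`/f seconds (default
3 cycles), the Hann-tapered Fourier coefficient at f is taken per epoch,
and λ_f = |Σₜ Fₜ F*ₜ₊ₗ| / √(Σ|Fₜ|² Σ|Fₜ₊ₗ|²) with lag l = 1 cycle; λ is the
mean over frequencies. Epoch length and lag are configurable; these
defaults follow the method's usual convention since no canonical values
exist. Values are reported per 5-min bin for time-resolved comparisons.

## Burst detection

Detection runs on the continuous median-normalised envelope of the
event-scale theta-filtered trace. Candidate events are maximal intervals
with envelope ≥ `low_thresh`, bridged across sub-threshold gaps shorter
than one band cycle, and retained if they contain a sample ≥ `high_thresh`.
Defaults are low = 2.5 and high = 4.0 in units of the session median
envelope. The rationale: for a Gaussian 1/f background the theta envelope
is approximately Rayleigh, whose median is ≈ 1.18 σ_env; a high threshold
of 4 × median ≈ 4.7 σ_env is exceeded by background noise with probability
~1.6 × 10⁻⁵ per sample, so false events are rare, while bursts that
dominate the theta band clear it easily. A low threshold at the median
itself would be degenerate (half of all samples exceed it, so crossings
merge into arbitrarily long intervals); 2.5 × median marks envelope levels
clearly above background while still capturing most of each burst's
extent. Both thresholds are exposed in configuration, and raising them can
only reduce the event count (tested property).

Threshold crossings inherit the detection kernel's temporal smear, so
boundaries are refined with a half-maximum model: the envelope full width
at half maximum (FWHM) within the event is deconvolved from the kernel
envelope's own FWHM in quadrature, and boundaries are placed one
deconvolved FWHM either side of the envelope peak. For a raised-cosine
(Hanning) burst envelope the full duration is exactly twice the FWHM, so
this is unbiased by construction for that family and, in the validation
sweeps, recovers onsets with a median error of ~12 ms and durations within
~30 ms at realistic SNR. The refinement can be disabled
(`refine_boundaries=False`) to obtain raw supra-threshold extents.

The minimum-duration rule is 1.5 cycles of the band's low cutoff (300 ms
for theta's 5 Hz cutoff, ≈ 115 ms for beta). Because the movement-locked
analyses use a 200-ms theta cut, `filter_min_duration` also accepts an
explicit `min_duration_s`, and the pipeline default for theta is 200 ms —
both readings of the rule are available.

Per-burst features: duration; envelope peak/mean/variance, skewness,
kurtosis; Shannon spectral entropy of the normalised 1–55 Hz periodogram of
the burst segment; peak frequency; cycle count (duration × band centre);
rise-time fraction (time-to-peak / duration); inter-burst interval
(flagged missing for a session's first burst); onset time; band relative
power in the burst ± 0.5 s context window (edge-truncated contexts are
flagged).

## Interregional timing and phase

Pairing is greedy and one-to-one: each MS burst takes the next unused CA1
burst whose onset follows the MS offset, with delay = CA1 onset − MS
offset and pairs beyond `max_delay_s` (1 s) discarded. Greedy matching
avoids double-counting that all-pairs schemes introduce. The
coupled/uncoupled flag takes an explicit window argument with no default,
because the analyses legitimately use 0.2, 0.4, and 1.0 s in different
places. Latency classes split pairs at the 25th/75th delay percentiles;
duration correlations are compared across conditions by Fisher's r-to-z.

PLV is computed per 8-s non-overlapping window and averaged (session
value), per 5-min bin, and in 2-s peri-burst windows (pre = before MS
onset, post = after CA1 offset; truncated windows excluded). Post-burst
phase offsets are circular means of φ_MS − φ_CA1 over 1.25 s from the CA1
burst onset, restricted to pairs whose MS burst ended within 200 ms of
that onset.

Circular tests: Rayleigh uses Z = nR̄² with
p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = nR̄ — the standard
approximation with small-sample correction, accurate for n ≥ 5 (verified
against an independent implementation and by type-I calibration).
Watson–Williams uses the F statistic with the 1 + 3/(8κ̂) concentration
correction, κ̂ estimated from the pooled within-group resultant; it assumes
von Mises data with reasonably high common concentration and flags
low-concentration input. Mardia–Watson–Wheeler replaces angles by uniform
scores 2π·rank/N (average ranks on ties); W = 2Σ(C²ᵢ + S²ᵢ)/nᵢ is χ² with
2(k − 1) degrees of freedom. All three hold 5% type-I error within
[0.03, 0.07] over 2000 null simulations.

Envelope lag takes, per 10-s window (5-s overlap), the argmax of the
normalised cross-correlation of mean-subtracted theta envelopes within
± `max_lag_s`; positive lag = MS leads. Peaks are taken on the sample grid
(no sub-sample interpolation; ± 1 sample ≈ 1 ms at 1017 Hz). Reported
summaries are the session median, median-centred lags, and the SD of the
signed and absolute lags; the absolute-lag SD is the within-subject
variability measure used for condition comparisons. For burst-driven
signals the envelope lag concentrates near the onset-to-onset separation
(MS burst duration + transmission delay ≈ 0.65 s at the defaults), so
condition-recovery analyses widen the search to ± 1 s; windows with
near-constant envelopes are skipped.

## Behaviour

The centre point is the back/tail-base midpoint (nose if unavailable);
positions are smoothed with a 5-frame moving average before
differentiation (the tracking-smoothing parameters are not canonical, so
this is a package choice). Heading is the velocity arctangent, undefined
below 0.25 cm/s where the angle is noise-dominated. Bout segmentation uses
hysteresis (enter > 1.5 cm/s sustained ≥ 1 s; exit < 0.5 cm/s sustained
≥ 1 s); rest is < 0.25 cm/s for > 2 s (the alternative 0.5 cm/s rest
threshold is exposed as a parameter). A movement initiation is a bout
onset preceded by ≥ 2 s below 0.5 cm/s, evaluated just before the
acceleration ramp (a 1-s grace window) so the rise through 0.5–1.5 cm/s at
onset does not disqualify genuine rest-to-movement transitions.

Burst–movement alignment reports both the percentage of initiations with a
burst within ± 2 s (the condition-comparison metric) and the percentage of
bursts near any initiation, plus a 40-bin histogram of burst-minus-onset
times over ± 2 s, Gaussian-smoothed (σ = 1 bin) and normalised to unit
area. The 0.1-s bin width is an assumption, exposed as a parameter.
Peri-burst velocity aligns interpolated velocity (0.1-s bins, −3 to +3 s)
to onsets of bursts ≥ 200 ms, averages within subject, and compares each
post-onset bin to the subject's pre-onset baseline mean with paired
t-tests under Benjamini–Hochberg correction; bins with numerically zero
variance are assigned p = 1 rather than letting floating-point noise
produce spurious significance.

Egocentric curvature rotates the bout's nose trajectory so the bout-onset
tail-base→nose vector points along +y, resamples it to 100 equally spaced
arc-length points, takes heading from central differences (one-sided at
the endpoints), and defines curvature as dθ/ds (rad/cm). The AUC is the
trapezoidal integral of |κ| over arc length — the path's total turning in
radians (π for a semicircle, independent of radius), which is what makes
it a size-invariant tortuosity index. Paths shorter than 2 cm or 10 frames
are excluded. The paired permutation test enumerates all 2ⁿ sign flips
exactly for ≤ 12 subjects (p = #{|mean| ≥ observed}/2ⁿ) and uses 10,000
Monte-Carlo flips with the +1 correction otherwise.

## Classification

The feature table keeps subject/session identifiers for grouping but never
feeds them to the model; constant features are dropped with a warning.
Normalisation (z-score) and median imputation are fit on training folds
only. Folds are stratified by label and grouped by subject
(`StratifiedGroupKFold`), so evaluation is always on unseen animals; a
pooled mode exists for comparison and is knowingly optimistic.
Hyperparameters are fixed (depth 4, 200 trees, learning rate 0.1,
histogram tree method, single thread) — the artifact's value is the
pipeline, not a tuned model. Reported: pooled out-of-fold ROC AUC, average
precision, row-normalised confusion at the 0.5 threshold, per-class
precision/recall, predicted-probability histograms, and mean fold feature
importances.

## The synthetic generator

Each region's trace is unit-variance Gaussian noise with a 1/f^α spectrum
(α = 2 by default, the typical LFP broadband slope; the synthesis is
spectral shaping, so the log-log slope is exact in expectation). Bursts
are Hanning-enveloped sinusoids — the smooth on/offset avoids spectral
splatter that would confound detection tests — with frequencies uniform in
5–12 Hz, Poisson arrival (MS 6/min, CA1 intrinsic 3/min, mPFC 3/min),
truncated-normal durations (MS 0.45 ± 0.10 s; CA1 0.40 ± 0.06 s), and
log-normal amplitude jitter (σ = 0.1). **SNR** is the burst peak amplitude
in units of the broadband noise RMS (default 4): because the 1/f
background carries only a small fraction of its power inside theta, an
SNR-4 burst stands far above the theta-band noise envelope, matching how
clearly theta bursts dominate raw CA1 traces. Overlapping injected events
are merged in the ground truth, since no detector can separate them.

MS bursts spawn CA1 bursts with probability 0.7 at delay ~
Normal(0.20 s, 0.10 s) truncated at zero; the spawned burst shares its
parent's frequency and is phase-shifted by a von Mises(0.5 rad, κ = 4)
angle. After each coupled event a shared low-amplitude theta tail (1.5 s,
envelope ≈ 2 × the median theta noise envelope — deliberately below the
detection thresholds) continues in both regions at the same phase offset,
emulating post-burst interregional synchrony so that peri-burst PLV has a
recoverable post > pre structure.

Tracking alternates rest epochs and motion bouts (trapezoidal speed
profile, peak 3–8 cm/s) on a heading random walk inside a 20 × 33 cm
arena, with six landmarks placed along the body axis plus 0.03-cm tracking
noise; a configurable fraction of bout onsets (default 0.6) is placed
0–2 s after a true CA1 burst. The "etoh" condition multiplies burst rates
×1.5, CA1 burst durations ×0.7, locomotor speed ×0.7, and the delay SD
×0.6 — the directions of the pharmacological effects the pipeline is
designed to detect; magnitudes are configurable. Cohorts give each subject
stable baselines shared across its two sessions (delay offset up to
± 50 ms, duration scale e^{N(0,0.05)}, velocity scale ± 10%). All
randomness flows from one seeded generator per session, with per-subject
substreams derived from fixed offsets, so every output is bit-reproducible.

Where neither the burst literature nor the analysis conventions fix a
value (SNR, duration spread, rates, delay parameters), the defaults above
were chosen once as a plausible regime and then left alone. The CA1
duration spread (± 0.06 s) is deliberately modest so that the injected
condition effects are identifiable by construction — with it, the
burst-feature classifier's grouped-CV AUC exceeds 0.9 and the
duration-distribution shift is detectable at a few hundred bursts. Real
burst-duration distributions are wider and right-skewed, so passing these
recovery tests demonstrates that the pipeline is correct and unbiased, not
that real-data effect sizes will be as large.

## What the validation shows, and does not

The generator emulates the statistical structure the analyses assume:
band-limited transient events on a 1/f background, directed MS→CA1 delays,
phase coupling, and burst-locked movement. It does not emulate volume
conduction, non-sinusoidal waveform shape, movement artefacts, electrode
drift, or cross-frequency coupling; conclusions about robustness to those
belong to real data. Problem sizes in the test suite and acceptance script
(5–20-min sessions, 4–8 subjects, 20–50 cohort replicates, 1000–2000 null
simulations) were chosen as the smallest scales at which the recovery
statistics are stable.

## Known limitations

- Detected burst boundaries assume a unimodal envelope per event; plateaued
  or multi-peaked events are assigned FWHM-based extents that may split the
  difference between sub-events.
- The greedy pairing attributes intrinsic (non-spawned) CA1 bursts that
  happen to follow an MS burst to that burst; with intrinsic CA1 activity
  present, recovered mean delays are biased upward by this contamination,
  which is inherent to the next-burst definition rather than to the
  implementation.
- The minimum-duration filter truncates the short end of the detected
  duration distribution, which attenuates observed count ratios between
  conditions whose durations differ (the EtOH count ratio recovered from
  detected bursts is below the injected rate multiplier for exactly this
  reason).
- Watson–Williams is a large-concentration approximation; for diffuse
  samples the MWW test is the appropriate choice and the implementation
  flags the former's low-concentration regime.
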