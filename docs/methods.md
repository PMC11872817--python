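# Methods

This note documents the models, estimators, numerical choices and known
limitations of `eegprepost`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

The processing order is fixed: average reference → zero-phase filtering →
amplitude-based artifact screening. The average reference subtracts the
instantaneous mean across all channels; it requires at least two channels
and is idempotent. Filtering combines a 4th-order Butterworth high-pass at
0.1 Hz with a Q = 30 IIR notch at 50 Hz, each applied forward–backward
(`sosfiltfilt`) so that the net phase response is zero — mandatory because
instantaneous phase feeds the coupling stage. Edge handling uses
even-reflection padding over up to three corner periods of the high-pass:
with a 0.1 Hz corner the default odd extension excites low-frequency edge
transients comparable to the signal itself (we measured ~30% residual RMS
on a pure 50 Hz tone before switching; ~2% after, and the tests assert
<10% residual on that tone and <5% amplitude error in the passband).

Artifact screening is an automated stand-in for the manual rejection used
in clinical practice, and its 150 µV default threshold is our choice, not
a literature value: any sample where any channel exceeds the threshold is
discarded together with 0.5 s on each side, and the surviving maximal runs
become the retained segments. All downstream stages operate per segment
(windowing, filtering, trimming) and pool across segments; segments
shorter than one analysis window (spectra), 500 samples (entropy), or
three modulating-band cycles (coupling) are skipped by the respective
stage.

Channel labels are normalized case-insensitively to the classic 10/20
names with a T3/T7-style synonym table. Units are microvolts throughout;
intervals are half-open `[start, end)` with 0-based samples.

## Spectra and coherence

Power spectra are Welch averages of Hanning-windowed periodograms, window
512 samples and 50% overlap, one-sided density scaling (Parseval holds to
within the window correction; asserted at 2% on a sinusoid). At 200 Hz
the grid step is 200/512 = 0.390625 Hz. Band power is the mean PSD over
the bins with `low ≤ f < high`, averaged over the region's channels;
half-open edges keep adjacent bands from double counting. Coherence uses
the same windows for cross- and auto-spectra; at least two windows are
required since a single-window magnitude-squared coherence is identically
one. Multi-segment recordings pool spectra with window-count weights.
Region power averages per-channel spectra while coherence uses
region-average signals (within-region coherence averages the region's
channel pairs, which for two-channel regions is simply the coherence of
those channels) — the asymmetry is deliberate and mirrors how each
quantity is defined. The independent-noise bias E[Coh] ≈ 1/K for K
windows is asserted in the tests, as is agreement with
`scipy.signal.coherence` on contiguous input.

The 50 Hz notch trough lies inside the gamma and composite bands. Band
means include those bins by default; `exclude_notch_band` drops 48–52 Hz.
Since pre and post pass through the identical filter chain the trough
cancels in the paired comparison, which is why the default is off.

## Binned-variance Tsallis entropy

For interval length L the estimator partitions the first `M·L` samples
(`M = ⌊N/L⌋`) into consecutive non-overlapping intervals and computes

    Ĥ(L) = 1 − Σ_j Var_j / (M · σ̂²)

with population variances (divisor L per interval, divisor N for the full
series). The channel's TE is the mean of Ĥ(L) over 100 equally spaced
lengths on the arithmetic grid 1 + k·499/99, k = 0..99, rounded to the
nearest integer with duplicates retained, so the average is always over
exactly 100 values. Design choices, made where the estimator's definition
is genuinely open:

- population variance makes L = 1 well defined (single-sample intervals
  have zero variance, so Ĥ = 1);
- remainder samples beyond M·L are dropped from the partition but kept in
  σ̂², keeping the denominator common across lengths;
- the double interval index in the defining sum is read as interval
  indexing within one partition; the across-lengths average is the
  separate "across bins" step;
- region values are means of the member channels' TEs, and "all" is the
  mean over all channels (not TE of pooled samples).

Consequences verified in tests: amplitude invariance (variances scale
identically in numerator and denominator), Ĥ ∈ [0, 1] when L divides N,
Ĥ(white noise) ≈ 1/L at a single length and ≈ 0.02 averaged over the
grid, and the closed-form limit Ĥ → c²/(c²+σ²) for a two-level step of
height ±c in noise of variance σ² at L = N/2 (law of total variance).
TE is computed on preprocessed retained samples per channel; an
alternative reading of the estimator (squared normalized probabilities)
is deliberately not implemented — the literal formula is the reference
behavior.

## Phase-amplitude coupling

The modulation index is the magnitude of the time-averaged
envelope-weighted phasor, `MI = |⟨A_f1 · exp(i φ_f2)⟩|`, with envelope and
phase taken from the analytic signal (zero-phase 4th-order Butterworth
band-pass, then Hilbert transform). One cycle of the modulating band's
low edge is trimmed from each segment end to suppress analytic-signal
edge artifacts. Raw MI is reported — it is scale-equivariant in the
amplitude source and rotation-invariant in phase — and an optional
circular time-shift surrogate z-score (seeded) is available but off by
default; note that time-shift surrogates only destroy coupling when the
modulating rhythm is aperiodic, as it is in real EEG.

Comodulograms evaluate MI on modulating centers 1–10 Hz (1 Hz steps,
bands ±1 Hz clipped below at 0.5 Hz) by modulated centers 20–85 Hz (5 Hz
steps). The modulated band around each center is ±(5 + f_phase) Hz rather
than a fixed ±5 Hz: amplitude modulation at rate f_phase places sidebands
at f_amp ± f_phase, and a band narrower than the modulating frequency
excludes them, leaving the coupled cell itself with a flat envelope so
the comodulogram maximum lands on a neighbouring cell (with fixed ±5 Hz
bands the 6 Hz → 60 Hz localization test located the true cell in 0 of 50
replicates; with the adaptive band, 50 of 50). This widening is the one
place the implementation departs from the fixed-band grid originally
sketched for it; grid spacing and ranges are configurable. For
cross-region pairs the first-named region supplies phase and the second
amplitude, and both directions are computed and written.

## Paired statistics

Wilcoxon signed-rank with the conventions of the major statistics
packages: zero differences dropped, midranks on ties, W the smaller rank
sum, and the tie-corrected normal approximation

    Z = (W − m(m+1)/4) / sqrt(m(m+1)(2m+1)/24 − Σ(t³−t)/48)

with no continuity correction — the uncorrected form is the one that
reproduces published worked values such as |Z| = 19.5/√96.25 = 2.4973 for
m = 10 with a rank sum of 3. Z is signed by the direction of change
(negative when post dominates), p is the two-sided normal tail, and the
effect size is r = Z/√n reported to four decimals. A one-sample
Kolmogorov–Smirnov screen on the standardized differences is reported
alongside, motivating the nonparametric choice without gating it.

Because the approximation omits the continuity correction, it estimates
the *mid-p* exact probability (half weight on the observed rank sum): at
n = 8 the exhaustive 2⁸ sign enumeration shows agreement within 0.0273
under the mid-p convention and within 0.0094 under the inclusive-tail
convention wherever exact p ≤ 0.10; mid-range inclusive-tail deviations
reach 0.068 for any uncorrected approximation, which is a property of the
estimator, not a defect. Features whose differences are all zero are
reported as non-testable rather than raising. No multiple-comparison
correction is applied by default (the analysis is exploratory and
per-feature); `fdr=True` switches the significance flags to
Benjamini–Hochberg-adjusted p-values. The trend band 0.05 ≤ p < 0.10 is
flagged separately. A partial-eta-squared-style effect size is
deliberately not provided: no well-defined formula exists for this design
that we could validate.

## Synthetic cohorts

`SyntheticCohortConfig` describes a cohort of paired recordings
(default 10 subjects × {pre, post}, 21 channels, 200 Hz, 120 s; a
`clinical_scale()` preset lengthens recordings to 757 s, the mean
artifact-free duration of the clinical recordings this emulates). Each
channel is the sum of:

- 1/f^β Gaussian background (β = 1, 15 µV RMS by default), independent
  across channels;
- per-region band-limited oscillations (posterior alpha, frontal theta,
  temporal beta by default), each mixed from a region-shared narrowband
  source with weight √s and an independent per-channel source with weight
  √(1−s); the shared fraction s (default 0.7) controls within-region band
  coherence;
- optional phase-amplitude components: a slow rhythm injected into the
  phase region and a fast rhythm, envelope-modulated by the slow phase
  with depth ∈ [0, 1] and small carrier phase jitter (SD 0.1 rad), into
  the amplitude region.

Subject-level amplitude variation (log-normal, σ = 0.15) is drawn once
per subject and shared between conditions, giving the paired structure
the statistics assume; realization noise is independent between
conditions. All randomness derives from the master seed through stable
per-subject/per-condition sub-seeding, so cohorts are bit-reproducible.

Planted pre→post effects: *power* effects rescale the Fourier
coefficients of the target region's channels inside the band by √m, so
the realized band power changes by exactly m in expectation; *coherence*
effects rescale the shared fraction of the region's oscillations in the
band; *entropy* effects scale a slow (≈0.1–0.6 Hz) structured drift added
to the target region in both conditions; *cfc* effects add to the
coupling depth. Effect magnitudes are detectability choices for n = 10
cohorts, not values taken from any dataset.

What the generator does **not** emulate: volume conduction and field
spread (channel correlations come only from the explicit shared sources),
physiological artifact waveforms (only optional amplitude spikes for
testing the screening stage), non-stationarity, and realistic
channel-specific spectra. Passing tests therefore demonstrate estimator
correctness and pipeline-level statistical calibration on data with the
assumed structure, not clinical validity on patient EEG.

## Verification strategy and problem sizes

The acceptance-style tests check, in increasing scale:

1. analytic worked examples (printed effect sizes r = Z/√10, the
   0.390625 Hz resolution, the rank-sum-3 Wilcoxon statistic);
2. closed forms: MI = 1/2 for envelope 1 + cos φ over whole cycles;
   entropy limits (unit intervals → 1, step-plus-noise → c²/(c²+σ²),
   white noise ≈ 0);
3. the exhaustive n = 8 Wilcoxon enumeration;
4. pipeline-level type-I calibration: 1000 seeded null cohorts of 10
   subjects at 10 s per recording with the comodulogram stage disabled —
   the rank test's level does not depend on the feature kind, and these
   sizes keep a 1000-replicate calibration tractable; per-feature
   rejection rates at α = 0.05 are required to lie in [0.03, 0.08].
   The exact achievable level of the n = 10 test at this α is
   2·25/1024 = 0.0488, so per-feature rates at 1000 replicates have a
   binomial standard error of ≈ 0.007; with ~118 features, occasional
   ~3-SD excursions below 0.03 are expected from sampling alone even for
   a perfectly calibrated test, and the fixed-seed run used by the test
   suite is reported as-is rather than re-seeded.
5. planted-effect recovery (×1.5 occipital beta-gamma power, 100 seeded
   cohorts) and comodulogram localization (6 Hz → 60 Hz at depth 1, 50
   seeded 60 s replicates over a 1/f background).

`scripts/acceptance.py` recomputes the same families of quantities at
reduced replicate counts (200 null cohorts, 30 effect cohorts, 20
coupling replicates) so a full from-scratch reproduction stays within a
few minutes on one CPU.

## Known limitations

- EDF support is read via MNE and written by a minimal internal plain-EDF
  16-bit writer (one-second records, symmetric physical ranges); EDF+
  annotations are not supported.
- No ICA/regression artifact removal, bad-channel interpolation or
  resampling; the amplitude threshold is a crude stand-in for expert
  rejection.
- Coherence is sensor-space magnitude-squared coherence; volume
  conduction is not addressed (no imaginary coherency or phase-lag
  index).
- The Wilcoxon p uses the normal approximation at all n; exact
  small-sample p-values are available only through the test-suite
  oracles.
- An 80 Hz low-pass is deliberately not applied offline: the gamma band
  extends to 80 Hz and the modulated coupling range to 85 Hz.
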