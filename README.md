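# eegprepost

Pre/post-intervention resting-state EEG analysis for small paired cohorts:
region band power, region-pair coherence, a binned-variance Tsallis-entropy
estimator, phase-amplitude comodulograms, and paired nonparametric
statistics — together with a seeded synthetic EEG generator so that every
stage of the pipeline can be verified without patient data.

## What it computes

Given one *pre* and one *post* recording per subject (21-channel 10/20
montage, 200 Hz), the pipeline applies average-reference re-referencing, a
zero-phase 0.1 Hz high-pass and 50 Hz notch, and amplitude-threshold
artifact screening, then extracts per-subject features over five scalp
regions (occipital, frontal-complete, fronto-polar, temporal, parietal):

- **Band power** — Welch spectra (Hanning window of 512 samples, 50%
  overlap, 200/512 = 0.390625 Hz resolution), averaged over each region's
  channels in eight bands: delta 1–4, theta 4–8, alpha 8–14, beta 14–31,
  gamma 31–80, theta-alpha 4–14, alpha-beta-gamma 8–80, beta-gamma
  14–80 Hz.
- **Coherence** — magnitude-squared coherence of region-average signals,

  `Coh_XY(f) = |S_XY(f)|² / (S_XX(f) S_YY(f))`,

  with cross- and auto-spectra averaged over the same windows; band means
  per region pair (within-region values average the region's channel
  pairs).
- **Tsallis entropy (TE)** — for interval length `L`, partition the series
  into `M = ⌊N/L⌋` consecutive intervals and compute
  `Ĥ(L) = 1 − Σ_j S²_j / (M σ̂²)` with population variances; TE is the mean
  of `Ĥ(L)` over 100 equally spaced lengths in [1, 500] samples, per
  channel, then averaged per region. White noise gives TE ≈ 0, strongly
  structured signals approach 1.
- **Cross-frequency coupling** — Canolty's modulation index
  `MI = |⟨A_f1[n] · exp(i φ_f2[n])⟩|` between the analytic-signal phase of
  a modulating band (centers 1–10 Hz) and the envelope of a modulated band
  (centers 20–85 Hz), on comodulogram grids within and between regions.
- **Statistics** — every feature is compared pre vs post with the Wilcoxon
  signed-rank test (zero differences dropped, midranks, tie-corrected
  normal approximation without continuity correction), effect size
  `r = Z/√n`, significance at α = 0.05 and a trend band 0.05 ≤ p < 0.10;
  optional Benjamini–Hochberg correction.

The synthetic module generates seeded cohorts — 1/f background, shared
region oscillations (controlling coherence), optional phase-amplitude
coupling, and configurable pre→post effects on power, coherence, entropy
and coupling — with the paired subject structure the statistics assume.

## Worked example

Simulate a 10-subject cohort with a planted ×1.5 occipital beta-gamma
power increase, analyze it, and report:

```bash
cat > cohort.yaml <<EOF
n_subjects: 10
duration_s: 60
seed: 7
effects:
- kind: power
  target: occipital
  band: beta-gamma
  multiplier: 1.5
EOF
eegprepost simulate --config cohort.yaml --out cohort --format edf
eegprepost analyze --manifest cohort/manifest.tsv --out results --no-cfc
eegprepost report --results results/results.tsv
```

which prints (abridged):

```
significant (p < 0.05): 14
  power     occipital                    beta-gamma       Z=-2.8031 p=0.0051 r=-0.8864
  power     occipital                    beta             Z=-2.8031 p=0.0051 r=-0.8864
  power     occipital                    gamma            Z=-2.8031 p=0.0051 r=-0.8864
  power     occipital                    alpha-beta-gamma Z=-2.8031 p=0.0051 r=-0.8864
  entropy   occipital                    broadband        Z=+2.2934 p=0.0218 r=+0.7252
  ...
```

The planted feature (occipital beta-gamma power) is recovered with
`Z = −2.8031` — all ten subjects increased, so the negative-rank sum is 0 —
and a large effect size `|r| = 2.8031/√10 = 0.8864`. The bands overlapping
14–80 Hz (beta, gamma, alpha-beta-gamma) necessarily move with it, and the
extra high-frequency power whitens the occipital signal enough to shift
its entropy; the remaining flags are the ~5% false-positive rate expected
at α = 0.05 without multiple-comparison correction (`--fdr` enables
Benjamini–Hochberg).

The same analysis is available as a library:

```python
from eegprepost import (SyntheticCohortConfig, simulate_cohort,
                        analyze_cohort, AnalysisConfig)
cohort = simulate_cohort(SyntheticCohortConfig(seed=7))
features, results = analyze_cohort(cohort, AnalysisConfig())
```

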