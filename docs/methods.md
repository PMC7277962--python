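# Methods

This note documents the models, numerical choices and limitations behind
`erpmarkers`. It complements the README, which defines the biomarkers and
statistics themselves.

## Signal processing

Filters are zero-phase (scipy `sosfiltfilt`) so component latencies are
preserved. The band-pass is a cascade of a 4th-order Butterworth high-pass
and low-pass (a single band-pass design spanning 0.1–100 Hz at fs = 1000 Hz
is numerically ill-conditioned; the cascade keeps passband ripple < 0.1%
and > 97% attenuation one octave into the stopband). The notch is a
quality-factor-30 IIR design. The forward–backward pass doubles the
effective order; applied filters are recorded in the recording's metadata.
The 0.1 Hz high-pass has multi-second edge transients — unavoidable for any
realization — which is why resting feature extraction discards nothing but
relies on 70 s recordings, and event epochs sit far from recording edges.

Epochs are half-open `[start, end)` in samples, so 2.048 s at 1000 Hz is
exactly 2048 samples. Resting epochs are consecutive and non-overlapping;
the first 30 epochs whose absolute amplitude stays within 100 μV on every
EEG channel are retained, a deterministic selection rule. The 100 μV
resting threshold is interpreted as absolute amplitude (|x| > 100), not
peak-to-peak. Event epochs are baseline-corrected by subtracting the
pre-stimulus mean per channel, and the ±75 μV rejection is applied *after*
baseline correction (the threshold is about residual signal, and a large
DC offset with small residual activity should not discard a usable epoch).

## Spectral estimation

Band power is a Hann-tapered per-epoch periodogram with density scaling,
integrated over the bins whose center frequency lies in the half-open band
[8, 10) Hz, then averaged over the 30 epochs. With density scaling the
estimate is consistent for both narrowband inputs (a sinusoid of amplitude
a yields a²/2) and broadband inputs (white noise of variance σ² yields
σ²·bandwidth/Nyquist), which the tests verify against both oracles. No log
transform is applied to powers before the asymmetry index. Bin assignment
by center-frequency inclusion makes results bit-reproducible.

## ERP measures

Peak searches use closed latency windows; the N1 (50–200 ms) and P2
(150–300 ms) windows deliberately overlap in 150–200 ms and the searches
run independently. Ties between equal extrema go to the earliest latency.
The LDAEP regression uses intensity/10 as the regressor so the slope's
units are μV per 10 dB directly. The MMN window is fixed at 130–280 ms (no
data-driven re-selection) and the composite is the unweighted mean of the
nine frontocentral sites.

## Synthetic data

The generator produces the statistical structure each extractor assumes,
with the simplest identifiable signal model:

* **Background**: 1/f-shaped ("pink") Gaussian noise per channel, default
  SD 5 μV — the spectral shape of resting EEG without any physiological
  source model.
* **Resting alpha**: a sinusoid at 9 Hz (center of the low-alpha band)
  with per-channel amplitude. For a target asymmetry A the left/right
  amplitudes of a pair realize the power ratio (100+A)/(100−A), keeping
  the mean pair power at (10 μV)²/2. Broadband noise leaks a small equal
  power into both channels of a pair, biasing the recovered index toward 0
  by ≈ 1–2% at the default SNR — well inside the ±5-unit recovery band.
* **Evoked components**: Gaussian bumps (N1 at 100 ms, σ = 20 ms,
  negative; P2 at 200 ms, σ = 30 ms, positive) whose peak-to-peak distance
  equals the configured intensity series; the nominal peak-to-peak is
  floored at 0.25 μV because an N1/P2 morphology cannot have a negative
  peak-to-peak — extreme cohort draws therefore saturate, compressing the
  recovered slope for those subjects.
* **Oddball**: standards and deviants share a common N1/P2-like response;
  deviants add a Hann-windowed negative deflection spanning exactly
  130–280 ms whose window mean equals the configured MMN amplitude (peak =
  2 × amplitude, since a Hann window's mean over its support is half its
  peak).
* **Event designs**: 5 × 60 tones with ISI uniform in 500–900 ms for the
  intensity series; 750 tones (exactly 10% deviants, shuffled) for the
  oddball. The oddball ISI is configurable and defaults to 500 ms (the
  reference protocol's description is internally inconsistent about this
  interval; the default follows the stimulus count and common MMN
  practice).
* **Clinical trajectories**: HAM-D(w) = baseline × (1 − r·f(w)) + noise,
  rounded and truncated at 0, with f(0, 2, 4, 8) = 0, 0.45, 0.75, 1 — a
  decelerating recovery curve. The per-subject recovery fraction r is
  Gaussian (mean 0.675, SD 0.22, clipped to [−0.2, 1]) shifted by ± half
  the group effect (default 0.27) according to the subject's true F5/F6
  asymmetry group (median split of the drawn true values). The CORE score
  is a rounded truncated Gaussian correlated with the true F7/F8 asymmetry
  (default r = 0.34). Age, sex (92% female), medication (50/50
  vortioxetine/escitalopram) and HAM-A are drawn independently.

Cohort distribution defaults (FAA 0.03 ± 14.13 and −1.73 ± 15.81, LDAEP
1.55 ± 2.85 μV/10 dB, MMN −2.97 ± 1.34 μV, baseline HAM-D 26.13 ± 6.80,
age 45.87 ± 11.69, CORE 4.35 ± 5.98) mirror a published MDD cohort of
n = 52 and are realistic settings, not a claim to reproduce that cohort.
The default recovery means were chosen so that week-8 group means land near
that cohort's reported low/high values (≈ 5 and 12 on a baseline of 26).

What the generator does **not** emulate: volume conduction, ocular/muscle
artifacts (rejection is exercised with synthetic amplitude spikes),
latency jitter or amplitude variability of single trials, non-Gaussian
score distributions, dropout. Passing recovery tests therefore show the
pipeline is correct and calibrated under the assumed structure — not that
it is robust to every property of real clinical EEG.

Determinism: every generator draws from a stream keyed by
(seed, paradigm, subject index) via `numpy` `SeedSequence`, so any subset
of subjects or paradigms can be regenerated byte-identically.

## Repeated-measures ANCOVA

No installed package fits a repeated-measures ANOVA with between-subject
covariates, so the univariate GLM approach is implemented directly: the
k = 4 repeated measures are transformed by orthonormal polynomial
contrasts M; the between-subject design X (intercept, group, covariates;
two-level covariates coded 0/1, constant columns dropped) is fit to YM;
the week × group interaction F averages the hypothesis and error SSCP
traces, df1 = k−1, df2 = (k−1)(n−p). Greenhouse–Geisser ε and Mauchly's W
are computed from the error covariance of the transformed measures
(E/(n−p)), with Box's two-term chi-square approximation for Mauchly's p.
GG adjustment (df × ε) is applied only when Mauchly's p < 0.05. The
implementation was verified against `pingouin.mixed_anova` (interaction F,
no-covariate case, agreement to 1e-9) and against R `car::Anova`
univariate output with covariates (F, ε, W and adjusted p to ≥ 6
decimals). Baseline HAM-D deliberately appears both as a repeated-measures
level and as a covariate, mirroring the reference design; a
`drop_baseline_covariate` flag removes the double use for sensitivity
analysis.

Per-week ANCOVA uses statsmodels OLS + ANOVA (type 2; with no interactions
in the model the group test equals type 3). Partial correlation
residualizes both variables on the covariates by least squares and applies
the t transform with df = n−2−m; it reduces exactly to the Pearson
correlation with no covariates. The chi-square is scipy's Pearson test
without continuity correction — the uncorrected statistic reproduces the
reference tables' printed values exactly, and an exhaustive test checks it
against the n(ad−bc)²/(row·column margins) closed form on every 2×2 table
with n ≤ 30.

Missing data are handled by complete-case analysis per statistic; no
imputation, and no multiple-testing correction across the four biomarkers
(the report notes this).

## Problem sizes and calibration

The null-calibration experiments use 200 cohorts of n = 52 (the reference
cohort size) with the group effect set to zero; chi-square and
rm-ANCOVA-interaction rejection rates at α = 0.05 are required to fall in
[0.02, 0.10]. Measured rates are ≈ 0.03–0.07 — the chi-square runs
slightly conservative because the median split conditions on the observed
biomarker and the outcome is discrete. Parameter-recovery experiments use
20 replicates per setting in the test suite (10 in the acceptance script)
at the default noise level; recovered means fall within ±5 index units
(FAA), ±0.2 μV/10 dB (LDAEP) and ±0.3 μV (MMN) of the injected values.

## File formats

Recordings round-trip through the npz container (lossless; JSON sidecar
with labels, events, provenance) or EDF. EDF files are read with mne; the
writer produces plain 16-bit EDF with 1-s records, physical range padded
±1 μV around the data, and a JSON sidecar for events (EDF+ annotation
encoding is not written). Quantization error is bounded by the physical
range / 65535 per sample. The EDF round trip is tested with mne as the
independent reader, including unit conversion when a file declares mV.

## Known limitations

* The rm-ANCOVA reports only the week × group interaction (the study's
  target effect), not the full ANOVA table.
* The EDF writer targets interchange of synthetic/processed data, not
  archival clinical use (no patient metadata fields beyond the id, no
  EDF+ annotations).
* Median splits with many ties can produce unbalanced groups; ties go to
  the low group deterministically.
* Subject-level results of any real cohort (correlations, F statistics,
  adjusted means) depend on patient data and are not reproduced by the
  synthetic defaults; the simulation is calibrated to the same *settings*,
  not the same realizations.
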