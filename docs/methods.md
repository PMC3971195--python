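# Methods

`eegad` benchmarks automated EEG artifact removal (AAR) for resting-EEG
Alzheimer's-disease (AD) classification.  Because the clinical recordings
that motivate this line of work are not publicly deposited, the package is
driven end-to-end by a synthetic cohort generator that retains ground-truth
clean signals, so every stage — epoch screening, spatial artifact removal,
feature extraction, classification — can be validated against a known truth.
This note documents the models, the defaults and why, the numerical choices,
and what the synthetic conditions do and do not show about real data.

## Synthetic EEG model

Each subject's clean 20-channel recording (10–20 montage, bi-auricular
reference, 200 Hz, μV) is a sum of five band-limited noise processes per
channel, one per classical band (delta 0.1–4, theta 4–8, alpha 8–12, beta
12–30, gamma 30–90 Hz at fs = 200; the nominal "30–100+" gamma ceiling
exceeds Nyquist, so the upper edge is capped at 0.45·fs).  Each band source
is Gaussian noise band-pass filtered (4th-order zero-phase Butterworth, with
several low-cutoff time constants of padding generated and trimmed so filter
settling transients never enter the retained stretch), multiplied by a
positive envelope `1 + depth·Σ √w·g_m(t)` built from band-limited noise in
the permitted modulation bands (depth 0.5, weights halving with modulation-
band rank: resting EEG envelopes are slow), then re-confined to the band and
scaled so the *relative* band powers hit the group profile's targets.

**Group profiles.**  Controls (N) are alpha-dominant (delta/theta/alpha/
beta/gamma = 0.22/0.20/0.33/0.20/0.05, interhemispheric coupling 0.60).
Disease is a one-parameter contrast ("effect scale"): each unit shifts
+0.06/+0.03 into delta/theta and −0.06/−0.03 out of alpha/beta (then
renormalized) and lowers coupling by 0.12 — the classic EEG "slowing" and
interhemispheric disconnection.  AD1 (mild) sits at effect 1, AD2
(moderate-to-severe) at effect 2.

**Coupling.**  Each interhemispheric pair's band component mixes a shared
and an independent unit-variance source, `√a·s + √(1−a)·n` with `a = √c`;
the expected magnitude-squared coherence of such a mixture is `a² = c`, so
the measured per-band MSC recovers the coupling target (verified within
±0.03 at 2-minute durations; the package invariant allows ±0.1).

**Artifacts** are generated separately and added, so `mixed = clean +
artifact` holds exactly.  Blink: squared-cosine unipolar bump, 0.2–0.5 s,
frontal topography (Fp1/Fp2 = 1, F7/F8 = 0.7, F3/F4 = 0.35, Fz = 0.3).
Muscle: Hann-windowed 20–90 Hz noise burst, 0.3–2 s, temporal topography.
Line noise: continuous 60 Hz sinusoid on all channels.  Saturation:
constant-level segment exceeding ±100 μV on frontal channels.  Blink and
muscle events vary per event (amplitude ±30%, channel gains ±15%): real
ocular and muscular events are not identical repeats of one topography, and
an exactly rank-1 artifact would make whole-component spatial removal
trivially optimal.  Defaults model eyes-closed rest: 3 blinks/min at 150 μV,
3 muscle bursts/min at 30 μV, 5 μV line noise, 0.3 saturation events/min at
150 μV.  No public quantitative artifact statistics exist for the original
clinical recordings, so these are conventions, chosen once.  Heartbeat
artifacts are not simulated (no removal stage targets them).

## Preprocessing

Power-line suppression is a 6th-order elliptic low-pass (passband edge
45 Hz, 0.4 dB ripple) whose stopband depth is root-found so that a
transmission zero lands exactly at 60 Hz; it is applied forward–backward
(zero-phase) to protect the phase-coherence features, which doubles ripple
and attenuation in dB.  Steady-state 60 Hz attenuation is effectively total;
brief ringing remains at the record edges, as with any zero-phase IIR
filter.  Eight virtual interhemispheric bipolar channels (Fp1-Fp2, F7-F8,
F3-F4, T3-T4, C3-C4, T5-T6, P3-P4, O1-O2; left minus right) are derived
after filtering — the order is immaterial by linearity.  Recordings are cut
into consecutive non-overlapping 8-s epochs; a trailing partial epoch is
dropped.  Legacy temporal labels (T3/T4/T5/T6) are canonical; T7/T8/P7/P8
are accepted as synonyms on input.

## Artifact removal

**SAR** (statistical artifact rejection) screens whole epochs and never
modifies survivors.  An epoch is rejected if any channel exceeds ±100 μV; if
any channel's kurtosis deviates more than 5 across-epoch SDs from that
channel's mean kurtosis; or if the epoch's summed channel log-probability
(per-channel Gaussian fits across all epochs) deviates more than 5 SDs.
Degenerate across-epoch SDs (identical epochs) reject nothing.  Statistics
are computed per channel with any-channel rejection.

**BSS** = SOBI ocular removal followed by CCA muscular removal, on the 20
unipolar channels only (bipolar channels are re-derived afterwards — they
are linear in the unipolars).  SOBI whitens (eigenvalues below the largest
divided by `eigenratio` = 10⁶ are truncated) and jointly diagonalizes the
symmetrized lagged covariances at lags 1..50 with Jacobi rotations.
Components are ranked by waveform fractal dimension (Katz-type, averaged
over 1-s windows): ocular activity is smooth and low-complexity, so the
*lowest*-fd components are removed, between 2 and 4 of them (the plugin-
style forced range).  The Katz estimator uses the curve length `L = Σ|Δy|`
and maximal excursion `d = max|y−y₀|`: `FD = log n / (log n + log(d/L))`,
clipped to [1, 2]; it is exactly 1 for a line and scale-free because only
d/L enters.  On artifact-free data fd saturates near 2 for every component,
so the forced removals are chosen greedily to minimize the worst per-channel
cumulative variance share; genuine fd outliers are always removed first.
Even so, removing ≥2 of 20 components from clean data unavoidably costs
15–30% of some channel's variance — a structural cost of the forced range
that the over-removal tests acknowledge (per-channel correlation ≥ 0.75,
channel mean ≥ 0.88 on clean input; wICA, which has no such floor, holds
≥ 0.95).

CCA decomposes the signal against its one-sample delay via a whitened
generalized eigenproblem, giving components ordered by non-increasing
autocorrelation.  A component is muscular when it lies in the lowest-
autocorrelation quartile *and* its mean spectral power above femg = 15 Hz
exceeds 1/10 of its mean power below (the psd-ratio test); flagged
components are subtracted.  Rank-deficient input (e.g. a common sinusoid)
is handled by the whitening truncation and passes through untouched.

**wICA** decomposes with FastICA (deterministically seeded, whitened,
tol 10⁻³; the tolerance is deliberately loose — artifact components separate
long before the last decimals converge).  A component is flagged artifactual
when its maximum amplitude exceeds 4 robust SDs (median/MAD).  Flagged
components are wavelet-corrected and everything is re-projected through the
mixing matrix.  The correction uses the *stationary* (translation-invariant)
db8 transform at depth 5: decimated thresholding leaves pseudo-Gibbs tails
around removed excursions, and depth was capped because a db8 atom at level
8 spans ~19 s of signal, letting event energy hide in "distant" coarse
coefficients.  Each level is thresholded against its own robust scale
(`tolerance`·σ_j·√(2 ln n), tolerance 1.25, σ_j from the median absolute
coefficient outside detected events) — a single finest-level scale, the
textbook denoising choice, underestimates background in narrowband
components and guts them.  Transient events are additionally located in
time (smoothed rectified amplitude > 2.5× its median) and their slow-scale
coefficients are removed wholesale within the event support, dilated per
level by the filter span.  Sub-threshold coefficients — the ongoing neural
background — are retained everywhere.

Cascades (SAR-BSS, SAR-wICA) screen epochs first and run the spatial method
on the concatenated survivors.

## Features

All spectral estimates use Welch averaging with 1-s Hamming windows and 50%
overlap within each 8-s epoch (1 Hz resolution; 15 segments).  Per epoch:

* **Spectral (140)** — relative band power for all 28 signals (20 unipolar +
  8 bipolar) × 5 bands, normalized by the union of the five bands so the
  fractions sum to 1.  The 1 Hz resolution biases delta slightly low (the
  sub-1 Hz mass falls into the excluded DC bin); tests allow ±0.05.
* **Modulation (392)** — per signal and band: band-pass (4th-order
  zero-phase Butterworth) → Hilbert envelope → demean (so the envelope's DC
  offset cannot leak into m-delta) → Welch → energy in each permitted
  modulation band.  Only 14 (band, m-band) combinations are meaningful
  (an envelope cannot oscillate faster than its band is wide); the 14
  energies are normalized jointly per signal — per-band normalization would
  pin E(delta; m-delta) at 1 and destroy its information.
* **Coherence (40)** — magnitude-squared coherence |⟨XY*⟩|²⁄(⟨|X|²⟩⟨|Y|²⟩)
  averaged over in-band bins, for the 8 interhemispheric pairs × 5 bands.
* **Phase (45)** — band-aggregated cross-spectral phase arg Σ⟨XY*⟩ (a
  magnitude-weighted circular mean; positive = left leads right) for the 8
  pairs × 5 bands, plus 5 global-field-synchrony values: per bin, the
  difference of the two normalized eigenvalues of the 2×2 uncentered
  scatter of the channels' real and imaginary Fourier coefficient vectors,
  averaged over bins and segments (1 = common phase, ~0.2 = the 20-channel
  random-phase floor).

Feature names follow `SIGNAL_BAND_FEATURE` (`Pz_alpha_pwr`,
`P3-P4_delta_m-delta`, `O1-O2_theta_cohe_pha`, `GFS_beta_gfs`); 617 columns
total.  Feature-domain averaging over 5 consecutive epochs (non-overlapping
blocks within subject, remainder dropped) raises feature SNR without
smearing the signals.

## Evaluation

Three tasks: N vs AD1 vs AD2, N vs AD1 (early detection), AD1 vs AD2
(progression).  Per task and feature set, a stratified random 25% of rows is
set aside for feature selection — recursive feature elimination with a
linear SVM, dropping 10% of features per step down to 24 — and the disjoint
75% is classified by an SVM under stratified 10-fold CV with per-fold
min-max scaling fit on training rows only.  The kernel is the plain dot
product (degree-1 polynomial, C = 1): at degree 1 a kernel-scaling γ is
mathematically a pure rescaling of C, and small γ drives every sample to
the dual bound, leaving the intercept numerically ill-determined; γ (default
0.01) therefore shapes the kernel only at degree ≥ 2.  Multi-class uses
one-vs-one voting.  Rows are epoch blocks pooled across subjects — faithful
to the benchmarked design, but note this leaks subject identity across CV
folds; a grouped CV would be the conservative alternative and the
chance-level calibration below is done under the same leakage.

Relative gain is (Perf_AAR − Perf_base)/Perf_base × 100.  The distribution
overlap of a feature before/after cleaning is Σ min(p_i, q_i)·100 over 50
equal-width bins spanning the pooled range (100 = unchanged; > 80 is
conventionally an irrelevant change; identical constants define 100).

## Problem sizes

Desk-scale defaults, chosen once: cohorts of 12 subjects per group, 2-minute
recordings (15 epochs → 3 averaged feature rows per subject).  Efficacy and
over-removal suites use 30 subjects; chance-level and gain checks use
reduced cohorts (6–12 per group) with the chance band Monte-Carlo-calibrated
at exactly those sizes.  The full default experiment (6 AAR variants × 6
feature sets × 3 tasks) runs in well under 15 minutes on one CPU.

## What the synthetic conditions do not show

The generator produces stationary, Gaussian-ish band mixtures with linear
instantaneous mixing: no 1/f broadband floor, no nonstationary vigilance
drifts, no volume-conduction forward model, no heartbeat/ECG artifacts, and
disease is a single smooth contrast rather than heterogeneous pathology.
Passing tests therefore demonstrate that each algorithm does what its
mechanism claims under controlled conditions with known truth — not that
clinical accuracy figures transfer.  The absolute accuracies obtained on
synthetic cohorts are not comparable to accuracies on clinical recordings.
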