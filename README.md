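# eegad — automated EEG artifact removal for Alzheimer's-disease classification

Resting EEG is a cheap, non-invasive window on cortical dysfunction in
Alzheimer's disease (AD): the disease shifts spectral power from alpha/beta
into delta/theta ("slowing"), weakens interhemispheric coherence, and alters
the slow amplitude-modulation dynamics of the classical bands.  Diagnostic
pipelines built on these features traditionally depend on clinicians
hand-picking artifact-free epochs.  `eegad` implements and benchmarks the
fully automated alternative: statistical epoch rejection (SAR), blind source
separation (SOBI for ocular, CCA for muscular artifacts), wavelet-enhanced
ICA (wICA), and their cascades, evaluated by how much they help or hurt an
SVM diagnostic classifier built on four EEG feature families.

Because the clinical recordings behind this design are not publicly
available, the package ships a first-class synthetic cohort generator with
controllable disease effect sizes and injected ocular/muscular/power-line/
saturation artifacts that retains the ground-truth clean signal for every
subject — so removal efficacy is measured against a known truth rather than
eyeballed.

The quantities at the core, per 8-s epoch over 28 signals (20 scalp
channels + 8 interhemispheric bipolar derivations):

* relative band power  P_b / Σ_b' P_b'  for delta…gamma (140 features);
* amplitude-modulation energies  E(band; m-band)  of the Hilbert envelope's
  second spectral decomposition, 14 valid combinations per signal (392);
* magnitude-squared coherence  |⟨XY*⟩|² / (⟨|X|²⟩⟨|Y|²⟩)  and cross-spectral
  phase  arg⟨XY*⟩  per interhemispheric pair and band (40 + 40);
* global field synchrony  λ₁−λ₂  of the normalized 2×2 real/imaginary
  scatter of the multichannel Fourier coefficients (5).

Features are averaged over 5 consecutive epochs, the 24 most relevant are
chosen by SVM recursive feature elimination on a disjoint 25% split, and a
polynomial-kernel SVM is scored by stratified 10-fold cross-validation on
three tasks: controls vs mild vs moderate AD, controls vs mild (early
detection), and mild vs moderate (progression).  Artifact-removal benefit is
reported as the relative gain (Perf_AAR − Perf_base)/Perf_base × 100 against
the raw-data baseline.

## Worked example

```python
from eegad import (ArtifactSpec, ClassifierConfig, benchmark_matrix,
                   default_profiles, make_cohort)
from eegad.experiment import build_method_tables

heavy = [ArtifactSpec("blink", rate=10.0, amplitude=250.0),
         ArtifactSpec("muscle", rate=10.0, amplitude=80.0),
         ArtifactSpec("line_noise", amplitude=10.0),
         ArtifactSpec("saturation", rate=1.0, amplitude=150.0)]
cohort = make_cohort({"N": 6, "AD1": 6}, profiles=default_profiles(0.35),
                     artifacts=heavy, duration=120.0, master_seed=900)
tables = build_method_tables(cohort, ("none", "wICA"), average_k=5)
report = benchmark_matrix(tables, tasks=["task2"], feature_sets=["All"],
                          cfg=ClassifierConfig(seed=900))
base = report.baseline[("task2", "All")].accuracy
wica = report.results[("task2", "All", "wICA")].accuracy
gain = report.gains[("task2", "All", "wICA")]
print(f"baseline {base:.1f}%  wICA {wica:.1f}%  gain {gain:+.1f}%")
```

prints

```
baseline 85.2%  wICA 92.6%  gain +8.7%
```

— this cohort carries a subtle disease contrast (effect scale 0.35) under a
heavy artifact load; the raw-data classifier reaches 85.2% on the
controls-vs-mild task, wICA cleaning lifts it to 92.6%, a relative gain of
+8.7%.  (Numbers are exactly reproducible from the seeds shown; different
seeds give different cohorts.)

The same pipeline is available from the shell:

```bash
eegad run --n-per-group 12 --seed 0 --out results/experiment
eegad simulate --n-per-group 3 --seed 1 --out cohort/
eegad clean --input cohort/N01_mixed.edf --method sar-wica --out cleaned.edf
```

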