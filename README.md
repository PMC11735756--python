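# localglobal

Simulation and single-trial EEG decoding of the auditory **local–global
paradigm**, with the cohort-level statistics used to relate decoding of
auditory regularities to consciousness level and outcome in comatose patients
after cardiac arrest.

The package is aimed at clinical-neurophysiology researchers who want to (a)
generate the paradigm's stimulus schedules, (b) prototype and validate the
full pre-registered decoding pipeline on synthetic EEG before any patient
data exist, and (c) run the cohort statistics (power analysis, outcome tests,
sedation models) on real or simulated cohort tables.

## The paradigm and the analysis

Series of five pure tones (A = 100 ms, B = 150 ms; 490 ms onset asynchrony)
establish two independent regularities:

- **local**: the fifth tone matches (AAAAA) or violates (AAAAB) the
  within-series repetition;
- **global**: one series type is frequent within a block (100/120, the global
  standard) and one is rare (20/120, the global deviant).

Four block types cross the two dimensions (block 1: standard AAAAB / deviant
AAAAA; block 2 reversed; blocks 3–4 the same with A and B swapped); a session
presents each block type twice in semi-randomised order, with inter-series
intervals uniform on [1450, 1800] ms. Violations of the global rule evoke a
late (≳300 ms) differential response; the local violation response is earlier.

Per recording, epochs from −100 to 500 ms around the fifth-tone onset are
decoded single-trial, separately for the global and local contrast, with an
80/20 cross-validation/test split:

- **STTA** (single-trial topographical analysis): each condition's
  GFP-normalised voltage topographies, pooled over trials and latencies, are
  modelled by a mixture of Gaussians whose means act as template maps. A
  trial's decision score is the cumulative log-likelihood ratio
  `Σ_t [log p(x_t | deviant) − log p(x_t | standard)]` over a discriminative
  time window; the component counts and the window are selected by stratified
  cross-validation to maximise the AUC.
- **SVM**: support-vector classification of the concatenated channels × time
  voltage vector (and a time-resolved variant per sample), with kernel
  (linear/RBF), C and γ selected on the CV partition.

Significance per recording is assessed against ≥100 full pipeline re-runs on
label-permuted data: an add-one empirical permutation p and a one-sided
Wilcoxon signed-rank test of the null AUCs against the observed AUC, combined
conjunctively at α = 0.05.

At the cohort level: a binomial success-count power simulation
(`Power(N) = Σ_i 1[P_H0,i < α]/n`, closed form `1 − (1−p)^N`), Pearson
correlations of AUC with the FOUR score and CPC, two-sided Fisher exact tests
of significant decoding × dichotomised outcome (CPC 1–2 vs 3–5),
Kruskal–Wallis comparisons of clinical features, and forward selection
(adjusted R² ordering, AIC stopping) of sedative infusion-rate terms
(propofol, fentanyl, midazolam) explaining the AUC.

Because no patient recordings exist at this stage, the package ships a
synthetic-EEG generator (spatially correlated, AR(1)-smoothed Gaussian noise
plus configurable effect topographies and windows) and a cohort generator
with explicit links between effect amplitude, FOUR score, outcome and
sedation, so every stage of the pipeline is testable end to end.

## Worked example

```python
import dataclasses
from localglobal.pipeline import RunConfig, simulate_session_epochs, run_recording

config = dataclasses.replace(RunConfig.reduced(seed=7), contrasts=("global",))
epochs = simulate_session_epochs(config, global_amplitude_uv=12.0)
result = run_recording(epochs, config, recording_id="demo")["global"]
print(f"test AUC        : {result.test_auc:.3f}")
print(f"selected window : {result.selected['window_ms']} ms")
print(f"empirical p     : {result.empirical_p:.4f}")
print(f"significant     : {result.significant}")
```

prints

```
test AUC        : 0.975
selected window : [350.0, 450.0] ms
empirical p     : 0.0196
significant     : True
```

i.e. a strong simulated global effect (12 µV on a fixed topography in
[300, 500) ms, 16 channels, 144 trials) is decoded at AUC 0.975 on the
held-out test trials, the selected STTA window falls inside the planted
interval, and the observed AUC beats all 50 label-permutation re-runs
(empirical p = 1/51).

The same stages are available from the shell:

```sh
localglobal simulate-schedule --seed 1 --out events.tsv
localglobal simulate-cohort --seed 2 --out cohort/
localglobal decode --epochs cohort/rec000_epochs.h5 --seed 3 --out results/
localglobal cohort-stats --table cohort/cohort_table.csv --out results/
localglobal power --p 0.21 --nsims 50000 --seed 4 --out power.csv
```

## Layout

| module | contents |
| --- | --- |
| `localglobal.paradigm` | tone/series/block types, schedule construction, BIDS-style events export |
| `localglobal.synthetic` | head model, epoch simulation, cohort simulation |
| `localglobal.preprocessing` | band-pass (0.1–40 Hz zero-phase FIR), epoching, artifact rejection/interpolation, GFP normalisation, CV/test split |
| `localglobal.stta` | mixture-of-Gaussians template-map decoder |
| `localglobal.svm` | SVM decoding (concatenated and time-resolved), sub-averaging |
| `localglobal.inference` | AUC, permutation null, significance rule |
| `localglobal.cohort` | power simulation, Fisher/Pearson/Kruskal–Wallis, sedation model selection |
| `localglobal.pipeline`, `localglobal.cli` | configuration, seed fan-out, end-to-end runs, CLI |

See `docs/methods.md` for the modelling choices, parameter defaults and known
limitations.
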