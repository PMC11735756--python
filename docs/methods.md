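# Methods notes

This note records the modelling assumptions, parameter defaults and numerical
choices behind `localglobal`, and what the synthetic-data validation does and
does not establish.

## Stimulus scheduling

The protocol fixes the counts and timing (120 series per block = 100 global
standards + 20 global deviants; 490 ms tone onset asynchrony; inter-series
intervals in [1450, 1800] ms; two repetitions of each of the four block types)
but leaves three details open, resolved here as:

- **Deviant placement** within a block: uniform over all placements with no
  deviant in the first 10 series (the regularity must be establishable first)
  and no two consecutive deviants. Sampling is exact (a stars-and-bars
  bijection onto unconstrained subsets), not rejection based.
- **Block order**: uniform over permutations of the eight blocks in which the
  two repetitions of a block type are never adjacent — a minimal reading of
  "semi-randomised".
- **Inter-series interval**: uniform on [1450, 1800] ms, measured from the
  fifth-tone onset to the next series' first-tone onset.

Block-type assignments: block 1 standard AAAAB / deviant AAAAA; block 2 the
reverse (standard AAAAA / deviant AAAAB); blocks 3 and 4 repeat the structure
with the roles of the 100 ms and 150 ms tones swapped. The protocol text
describing block 2 contains an internal inconsistency (the prose says the
assignment is *reversed* while its parenthetical repeats block 1's order);
the reversal is implemented, since otherwise block types 1 and 2 would be
identical and the four (global, local) label combinations would not all
occur.

Tone rendering is out of scope: schedules carry identities, onsets and labels
only. The carrier frequency stored on `ToneSpec` (1000 Hz) is a placeholder
default; A and B differ only in duration.

## Synthetic EEG

`simulate_recording` produces one epoch per scheduled series on a
[−100, 500) ms window:

- **Noise**: iid Gaussian per channel and sample (default `noise_sd` = 5 µV,
  a typical single-trial background EEG scale), smoothed along time by a
  variance-preserving AR(1) filter (default coefficient 0.3) and mixed across
  channels by a fixed random full-rank matrix with unit-norm rows, so
  channels are correlated but keep their marginal variance. There is no 1/f
  spectrum and there are no blink/ECG artifacts — this is the simplest noise
  structure that makes spatial decoding and GFP normalisation non-trivial.
- **Effects**: each effect adds `amplitude × topography(channel) ×
  envelope(time)` to the trials that are deviant on its label dimension
  (global effect keyed to the global label, local to the local label).
  Default windows: global [300, 500) ms (the late, P3b-like differential
  response), local [100, 250) ms (the earlier mismatch-like response). The
  envelope is a raised-cosine (Hann) bump rather than a rectangle, to avoid
  spectral splatter in filter-based tests. Topographies are smooth
  linear-gradient maps over a Fibonacci electrode layout, average-referenced
  and unit L2 norm, so `amplitude` is the instantaneous peak strength of the
  whole map in microvolts.

The default recording geometry mirrors the acquisition (63 channels,
1200 Hz); the reduced profile used throughout the simulation studies is 16
channels, 120 + 24 trials of a single block, 120 Hz.

### Cohorts

`simulate_cohort` draws per-patient covariates and links them linearly to the
global effect amplitude:

    amplitude_i = base + slope·FOUR_i + Σ_a coef_a·rate_ai + ε_i,  clipped at 0

with FOUR uniform on 0–16, infusion rates gamma-distributed on realistic
scales (propofol ~mg/kg/h, fentanyl ~µg/kg/h, midazolam ~mg/kg/h), and CPC
drawn from a logistic outcome rule in amplitude (favourable = CPC 1–2). None
of these links is part of the protocol — they are exactly the hypotheses the
cohort statistics are meant to recover, so all of them are explicit,
configurable parameters.

Defaults (base 1 µV, slope 0.5 µV per FOUR point) place the simulated
amplitudes at 1–9 µV. This range was chosen so that a parameter-recovery
study at the reduced geometry actually spans the decoder's operating range:
at 16 channels × 144 trials the test AUC is flat near 0.5 below ~2–3 µV and
saturates above ~10 µV, so links planted entirely below that floor would be
unrecoverable by *any* statistic — a property of the measurement, not of the
cohort tests under study.

## Preprocessing

- **Filtering**: zero-phase FIR band-pass 0.1–40 Hz (Hamming window,
  `firwin` design) with fixed transition bandwidths of 0.1 Hz at the low edge
  and 10 Hz at the high edge, via MNE. The filter is therefore ~33 s long and
  applies to continuous data only; the protocol names the band but not the
  realisation, and this fully documented choice favours reproducibility.
- **Epoching** is index-exact: sample `round(t_event·fs) + round(−0.1·fs)`
  onward, `round(0.6·fs)` samples (720 at 1200 Hz). Events too close to a
  recording edge are dropped and counted.
- **Artifact handling** is threshold based: channels exceeding the amplitude
  threshold (default 100 µV) in more than 20% of epochs are interpolated by
  inverse-distance weighting of the remaining channels; epochs with any
  remaining excursion are dropped; `retained + dropped = input` always.
  ICA-based cleaning is intentionally outside the package (the synthetic data
  contain no blink/ECG components); externally ICA-cleaned continuous data
  enter through the same epoching entry point.
- **Baseline**: per-epoch, per-channel mean of [−100, 0) ms subtracted by
  default (ERP convention; can be disabled).
- **GFP normalisation**: topographies are average-referenced, then divided by
  their global field power, defined as the standard deviation across channels
  (Lehmann–Skrandies). Time-points with GFP below 1e−8 µV are masked rather
  than divided and are excluded from mixture fitting and scoring.
- **Split**: stratified 80/20 CV/test, class proportions preserved within one
  trial, refused when a class has fewer than 5 trials.

## STTA decoder

One diagonal-covariance Gaussian mixture per condition is fitted by EM to the
pooled unmasked post-onset topographies of the CV-partition trials.
Numerical choices:

- diagonal covariances (channels ≫ trials regime at 63 channels; full
  covariance would need ~2000 points per component to be stable);
- variance floor 1e−6; a restart whose component responsibilities collapse is
  discarded; best of `n_restarts` (default 3) random initialisations (means
  drawn from data points, shared data variances, uniform weights);
- convergence when the total log-likelihood improves by < `em_tol` (1e−5,
  relative); the full log-likelihood trace is stored and is non-decreasing
  (EM guarantee, asserted in tests);
- fits subsample at most `max_fit_points` (20 000) pooled topographies,
  deterministically per seed — at full scale the pool is ~370 000 points and
  the extra points add nothing but runtime.

The decision score of a trial is the summed per-time-point log-likelihood
ratio (deviant vs standard mixture) over the selected window; masked
time-points contribute zero. Component counts are selected per condition
(a (k_deviant, k_standard) pair over candidates {1…6}) jointly with a
contiguous window from a millisecond grid (default: starts every 10 ms in
[0, 500), lengths ≥ 20 ms), maximising the mean held-out AUC over stratified
folds (default 5). Windows are restricted to post-onset latencies. Ties break
to the earliest window start, then the shortest window, then the smallest
total component count — a determinism/parsimony rule. Whether the original
method fits one mixture per condition or a shared mixture with
condition-specific posteriors is not specified in the protocol text; the
per-condition reading is implemented as the most direct one.

The inner selection loop computes, per fold and component pair, the
per-time-point log-likelihood ratio of every held-out trial once and obtains
every candidate window's scores from a cumulative sum, so the window grid
adds negligible cost.

## SVM decoder

Features are the concatenated channels × samples voltages (channel-major;
63 × 720 = 45 360 features at full scale), z-scored per feature with
statistics computed on the CV partition only. Kernel (linear/RBF), C
(default grid 0.01…100) and γ (default grid: sklearn's "scale" heuristic
1/(d·var), 0.01, 0.1, 1; ignored for linear) maximise mean held-out AUC of
signed decision margins; inverse-frequency class weights counter the 5:1
imbalance (configurable off). The time-resolved variant fits an independent
classifier on the instantaneous channel vector at every sample.

Sub-averaging replaces each class by the means of random non-overlapping
groups of 2 or 3 same-class trials (leftovers discarded; labels of the
*other* dimension become "mixed" since groups may straddle it); when it is
used, hyperparameter selection is re-run on the pseudo-trials. Under this
package's Gaussian noise model at desk scale, sub-averaging does *not*
reliably raise the test AUC: the √g noise reduction is offset by the g-fold
loss of samples (measured paired differences of −0.02…+0.04 across seeds and
SNRs). The often-reported benefit on real EEG plausibly rests on heavy-tailed
noise that the generator deliberately omits; tests therefore assert the
mechanism (pseudo-trial noise variance ≈ 1/g of the original, signal
preserved) rather than an AUC gain.

## Significance

The protocol's criterion — the observed AUC "outperforms" the label-permuted
ones "as assessed by a Wilcoxon signed rank test" — is statistically unusual:
a one-sample signed-rank test of ~100 null AUCs against a fixed observed
value is significant for almost any positive offset, regardless of where the
observed value sits in the null distribution. Both quantities are therefore
reported: the Wilcoxon p (one-sided, observed greater; exact where scipy's
exact path applies, otherwise normal approximation with continuity
correction) and the standard add-one empirical permutation p,
`(1 + #{perm ≥ obs}) / (n_perm + 1)`, which is never zero. The `significant`
flag defaults to the conjunction of both at α = 0.05 (faithful to the text
*and* calibrated; either criterion alone is configurable). Labels are
permuted *before* the CV/test split and the entire pipeline is re-run per
permutation, so selection bias is inside the null. With the conjunction rule
the empirical p dominates in practice and the realised false-positive rate is
slightly conservative (≈ 2/(n_perm+1) per recording).

## Cohort statistics

- **Power simulation**: K′ ~ Binomial(N, p) per draw; under H₀ (success
  probability zero) the probability of observing *at least* K′ successes is 0
  for K′ ≥ 1 and 1 for K′ = 0, so a draw is significant iff K′ ≥ 1 and the
  power estimate converges to `1 − (1−p)^N`, which doubles as the closed-form
  oracle (agreement within 3 Monte-Carlo SE is asserted). The protocol's
  phrase "up to K′ successes" would make P_H0 ≡ 1 and power ≡ 0; the
  at-least reading is the only one that reproduces the published N = 13 (and
  mean success count 2.7) at p = 0.21. Note the analogous healthy-control
  closed form gives 1 − 0.8¹³ ≈ 0.945, marginally short of 0.95 — consistent
  with rounding in the source.
- **Outcome/consciousness tests**: exact two-sided Fisher (significant
  decoding × favourable outcome), Pearson r with t-distributed p (n−2 df) for
  AUC vs FOUR and vs CPC, Kruskal–Wallis with tie correction for clinical
  features between decodable and non-decodable recordings — all computed per
  recording day, via scipy. Degenerate Kruskal–Wallis input (all values tied)
  returns H = 0, p = 1.
- **Sedation models**: OLS with identity link on AUC (a logit-transformed
  response is available); forward selection adds, at each step, the eligible
  term with the largest adjusted-R² gain *provided the AIC decreases*, and
  stops otherwise — the protocol names both criteria without arbitration, so
  adjusted R² orders and AIC gates. Pairwise interactions become eligible
  only once both main effects are included. Every evaluated candidate model
  is returned in a ledger. Raw p-values are reported throughout (the protocol
  specifies no multiplicity correction); Benjamini–Hochberg can be applied
  downstream. Under a null data-generating process, forward AIC selection
  still admits a spurious term in roughly a third of cohorts of 30 — an
  inherent property of the rule, which is why recovery claims are evaluated
  as majorities over seeded replicate cohorts.

## Validation scale and what it shows

The simulation studies run at a reduced profile chosen for desk-scale
iteration: 16 channels, 120 + 24 trials, 120 Hz, STTA candidates k ∈ {1, 2}
on a 50 ms window grid (minimum length 100 ms), 3 folds, 50 permutations,
cohorts of 30 recordings. At this scale the suite establishes: exact paradigm
construction; a calibrated false-positive rate of the full
permutation-significance pipeline over 50 null recordings; detection of a
strongly planted global effect (test AUC > 0.9) with window recovery;
AUC correctness against an exhaustive pair-counting oracle; and recovery of
planted cohort-level links (FOUR–AUC correlation sign, propofol as the
selected sedation term, intercept-only under null sedation, as majorities
over 20 seeds).

Passing these tests shows the pipeline is correctly implemented and
statistically calibrated under the stated noise model. It does **not** show
that real coma EEG is decodable: the generator has Gaussian noise, fixed
known topographies, no artifacts, no non-stationarity, and its effect
amplitudes are set, not estimated. Real-data properties (prevalence of global
encoding in coma, day-1 vs day-2 differences) are outside what synthetic
validation can establish.

## Other limitations

- The European Data Format reader and BIDS events import are thin optional
  wrappers (MNE/pandas) and are not exercised by the test suite, which is
  fully synthetic.
- Average reference is the only supported montage transform; source
  localisation, time-generalisation and cluster-based corrections are out of
  scope.
- `significant` flags feed the Fisher/Kruskal–Wallis tests; when significance
  is not computed (e.g. cohort screening without permutations) those tests
  are skipped and the reason is recorded in the statistics output.
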