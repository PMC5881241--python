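# Methods

This note documents the models, algorithms, defaults, and design choices in
`oddballerp`, and what the synthetic study can and cannot show.

## The synthetic oddball study

The generator emulates a visual-motor oddball experiment with two task
conditions per subject: a *simple* condition (oddball only) and a *dual*
condition (oddball while performing a demanding continuous sensorimotor
task). Defaults:

| Parameter | Default | Why |
| --- | --- | --- |
| subjects | 13 | study size |
| stimuli per condition | 60 targets, 60 deviants, 720 standards | 1:12:1 oddball ratio |
| ISI | drawn uniformly from {900, 1100} ms | two-point jitter; a continuous-uniform option exists behind `isi_continuous` |
| montage | 62-channel extended 10-20, FCz reference | standard active-cap recording |
| native rate | 250 Hz | desk scale; divisible by the 25 Hz analysis rate; 2500 Hz configurable |
| response latency | log-normal, median 0.79 s (simple) / 0.77 s (dual), log-SD 0.25 | oddball reaction times are right-skewed; medians match the behavioural calibration |
| omissions | p = 50/780 (simple), 67/780 (dual) per target | calibrated to the behavioural totals |
| commissions | 0 (simple), 2/10140 (dual) per non-target | near-zero slips |
| blinks | 2/min, 300 µV peak, frontal-dominant blob | large enough to trip the ±100 µV rejector |
| background noise | 1/f pink noise, 9 µV RMS per channel, plus a 10 Hz occipital rhythm (2 µV) and 50 Hz hum (0.5 µV) | broadband EEG-like floor; the exact background model is a package choice, not an empirical fit |

### Evoked structure

Each ERP component is a **Gaussian bump in time** (peak latency, width as
SD, peak amplitude in µV) times a **spatial blob** on the 2-D montage
projection (gain 1 at a center electrode, Gaussian decay with head
distance). Gaussian bumps were chosen because they are smooth, integrable,
and fully described by two parameters; no particular component shape is
implied by the literature the scenario draws on.

* All stimuli: small occipital visual response (180 ms, 2 µV at Oz).
* Targets: parietal **P3b** (peak 450 ms, temporal SD 150 ms, 8 µV at Pz).
  The wide SD makes the complex broad and sustained — it still carries
  signal in the late (600–800 ms) feature window, as the parietal target
  complex being emulated does.
* Deviants: frontocentral **P3a** (380 ms, 5 µV at FCz) plus an
  *attenuated* parietal positivity (430 ms, SD 150 ms, 1 µV at Pz) — small
  enough that deviant detection from the two parietal electrodes alone
  stays at chance, the reported property the generator is calibrated to.
* Dual-task targets additionally carry a late parietal **prospective
  positivity** (700 ms, 60 % of the P3b amplitude at CPz) and have a
  slightly stronger (×1.12), much more variable P3b (latency jitter SD
  75 ms vs 35 ms, amplitude jitter SD 2.5 µV vs 1.5 µV).

The 60 % relative amplitude of the late component is a free generator
parameter (the literature does not quantify it). The dual-vs-simple
contrast is deliberately encoded as (a) the extra late component and (b)
higher trial-to-trial variability; (b) is what makes classifiers trained on
dual-task data more robust under transfer.

Per-subject variability is a multiplicative log-normal(0, 0.2) amplitude
factor; trial-to-trial variability is per-template latency/amplitude
jitter. Everything is driven by one seed through per-(subject, condition,
stream) seed sequences, so outputs are bit-reproducible.

### What the generator does **not** emulate

Spatially correlated background noise, realistic volume conduction,
non-stationarity and drift, ocular/muscle artifacts beyond stereotyped
blinks, latency shifts correlated with response time, and realistic
artifact rates (the synthetic rejector removes a few percent of trials, not
the ~25–40 % typical of real recordings). Passing the pipeline tests on
this data shows the *algorithms* behave as specified under the configured
statistical structure; it does not certify performance numbers on real EEG.

## Preprocessing

Two branches process the same continuous data:

* **ERP branch**: common-average re-reference (the implicit FCz reference is
  re-instated as a zero channel before averaging), 0.1–30 Hz band-pass,
  −100…1000 ms segments, baseline correction on the prestimulus mean
  (toggleable, default on), rejection of trials with any |sample| > 100 µV
  or any adjacent-sample step > 75 µV.
* **Classification branch**: 0–1 s segments at the acquisition reference
  (no re-reference), per-channel zero-mean, decimation to 25 Hz
  (zero-phase 8th-order Butterworth anti-alias at 0.4 × target rate, then
  every k-th sample), 0.1–4 Hz band-pass. Artifact decisions are reused
  from the ERP branch so both analyses see the same trials; targets
  additionally require a response 200–2000 ms after onset, non-targets the
  absence of one.

All filters are 4th-order Butterworth (8th for anti-aliasing) applied
forward–backward (zero phase). The gradient criterion is interpreted as µV
per sampling step at the branch's current rate; µV-per-millisecond is the
alternative reading and would simply rescale the threshold.

## Average-ERP analysis

Subject averages are arithmetic means over kept trials (successful targets
only for the target class); the grand average is the *unweighted* mean of
subject averages. Peak amplitude is the signed maximum in an inclusive
window (early 350–600 ms, late 600–850 ms), ties resolved toward the
earlier latency. "Normalized amplitudes" are implemented as vector scaling
(each subject/condition/class electrode profile divided by its Euclidean
norm) — one defensible reading of a methodological literature that mostly
critiques such normalisations; it is labelled as an interpretation. Group
statistics (ANOVA families, corrections) are intentionally not
re-implemented: the module exports tidy TSV tables for external statistical
software.

## xDAWN

Model `X = D·A + N` with a 0/1 Toeplitz design `D` marking evoked-class
onsets. Evoked estimate `Â = (DᵀD + εI)⁻¹DᵀXᵀ` with trace-scaled ridge
ε (default 10⁻⁶ × trace(DᵀD)/L; the same relative ridge stabilises the
total covariance, which guarantees solvability even for the 2-channel
configuration and the zero-noise limit). Filters solve the symmetric
generalized eigenproblem maximising evoked-to-total energy; eigenvalues are
therefore ratios in [0, 1]. Signs are fixed so each component's evoked peak
is positive. Forward patterns are `ΣW(WᵀΣW)⁻¹`, column-normalised so maps
are invariant to filter rescaling.

Choices where the original processing chain is underdetermined:

* **Fitting input**: training epochs are concatenated into a continuous
  block with onsets at trial starts — this keeps the Toeplitz least-squares
  formulation while respecting fold boundaries.
* **Evoked class per pair**: the infrequent/positive class (target for
  t/st and t/d, deviant for d/st); for the three-class problem, target.
* **Leakage**: the filter (and feature normalisation) is refit inside every
  outer training split and for every transfer training set; per-fold
  refitting is the leakage-safe reading.
* Component counts: 8 pseudo-channels from 62 electrodes, 1 from 6 or 2.

## Classification

Features are the six 25 Hz samples per pseudo-channel whose times fall in
the inclusive window (early 400–600 ms, late 600–800 ms), flattened
channel-major (62-channel configuration: 8 × 6 = 48 features; single
pseudo-channel: 6). Features are standardised with training-split
statistics (constant features get scale 1).

The classifier is a soft-margin linear SVM (scikit-learn `LinearSVC`,
primal, squared hinge — deterministic for fixed inputs) with per-class
penalty C × weight; the under-represented class of the 1:12 pairs gets
weight 2, the near-balanced targets-vs-deviants pair weights 1:1. C is
chosen from {10⁰ … 10⁻⁶} by an inner stratified 5-fold grid search on the
outer training split, maximising balanced accuracy (the headline metric;
the model-selection metric is otherwise unspecified), ties resolved toward
the larger C. The outer scheme is repeated stratified 10-fold; predictions
are pooled per repetition, metrics computed per repetition and averaged,
with the SEM across repetitions reported. All fold shuffles derive from one
run seed recorded in the result.

Multiclass uses one-vs-one voting over the three pairwise models; ties are
broken by the summed signed decision values, then lexicographic class
order. Transfer fits everything (filter, normalisation, C via inner 5-fold,
model) on the full source condition and evaluates on the full target
condition.

Metrics: per-class TPR; binary bACC = (TPR + TNR)/2 with the infrequent
class positive; multiclass bACC = mean per-class TPR; ACC = total correct /
total. bACC is invariant to resampling class sizes at fixed rates; ACC is
not.

## Desk-scale settings

The package's default problem sizes are chosen to make the full pooled
study (13 subjects × 2 conditions, ~10,400 trials per condition after
rejection) run on a single CPU in minutes: native rate 250 Hz and 2
repetitions of the outer 10-fold for the pooled evaluations (the inner
5-fold and the full seven-value C grid are never reduced). The amplitude
recovery sweep generates on the parietal montage only — channel noise is
independent, so the parietal statistics are identical to the full cap at a
tenth of the cost. 2500 Hz and 10 × 10 cross-validation remain plain
configuration changes.

## Known limitations

* The BrainVision writer covers the multiplexed/vectorized, float32/int16
  core of the format, not vendor extensions (segmented files, µV-scaled
  markers, coordinates sections).
* The rejection rule is fully automatic; no semi-automatic review stage.
* No ocular regression/ICA; blink-contaminated trials are simply rejected.
* Pattern maps use a schematic 2-D montage projection, not digitised
  positions.
* With 2 CV repetitions the SEM over repetitions is a coarse spread
  estimate; raise `n_repetitions` to 10 for publication-style tables.
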