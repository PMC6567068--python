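# Methods

## The problem

Cyclic square-wave voltammetry (CSWV) records the current response of a
sample as the applied potential is swept cathodically (toward reduction) and
then anodically (toward oxidation).  The two sweeps are concatenated into a
single current trace per scan; peak potentials in that trace act as a
chemical fingerprint — e.g. anodic stripping peaks at +0.06 V (Hg), −0.20 V
(Cu), −0.58 V (Pb) and −0.78 V (Cd) vs. Ag/AgCl identify heavy metals in
seawater, and aerated blanks show a broad oxygen-reduction feature near
−0.9 V on the cathodic branch.  `voltclass` reconstructs the full
identification pipeline around such traces: simulation of labeled scan
libraries, seven classifiers, a repeated stratified evaluation protocol,
class-activation-map (CAM) interpretation, and a CAM-guided truncation
experiment.

## Potential grid

The seawater instrument sweeps between +1.0 V and −1.0 V with a 4 mV
increment.  The package's grid convention is 1002 samples: a 502-point
cathodic branch from +1.000 V down to −1.004 V followed by a 500-point
anodic branch from −1.000 V up to +0.996 V.  This convention reproduces the
three published index↔potential anchor pairs (560 → −0.768 V, 770 →
+0.072 V, 1000 → +0.992 V) exactly.  A fourth published pair (~610 ↔
−0.584 V) is inconsistent with the other three by about five samples under
any uniform-step convention; we treat it as an approximation in the source
material and keep the convention that satisfies the other three exactly.

## Synthetic scan libraries

The experimental library is not public, so the package generates scans with
the same statistical structure:

- **Class signatures.** Each class contributes Gaussian peaks in potential
  space at its published peak potentials.  Default peak width sigma is
  30 mV (square-wave peak half-widths are typically ~90 mV); "small broad"
  herbicide anodic features use 50 mV sigma at 0.4 relative amplitude.
  Cathodic (reduction) peaks point down, anodic (oxidation) peaks up.
- **Background.** All seawater classes carry the oxygen-reduction feature:
  a cathodic Gaussian at −0.9 V, sigma 80 mV, amplitude 1.0 jittered ±20%
  per scan.  A per-scan linear baseline drift (slope ~ N(0, 0.1) over the
  trace) and additive white Gaussian noise (sigma 0.05) complete the trace.
- **Concentration.** Each scan draws a concentration proxy log-uniformly
  from 50–2000 ppb and maps it linearly to peak amplitude
  (`amplitude_per_ppb` = 1/200, i.e. amplitudes 0.25–10 in
  pre-standardization units).  Larger proxy ⇒ larger expected peak, and the
  40× amplitude spread is a deliberate difficulty: identity must be read
  from peak *position*, not height.
- **Standardization.** The finished current table is z-scored globally
  (one mean, one sd), emulating raw data that already sits near mean 0 /
  sd 1; classifiers apply no further preprocessing.
- **Class inventory.** The 11-class seawater scheme uses the published
  per-class scan counts (DQ 14, MeP 50, PQ 8, Cd 36, Cu 23, Hg 22, Pb 38,
  heavy-metal mixture 68, BPA 4, NP 34, blank 80; 377 total).  The 4-class
  scheme is a pure relabeling of the same scans (HM 187 / Ind 38 /
  HandP 72 / SW 80): with the same seed the current matrices are
  identical, only labels merge.  Generic explosives-like layouts (3 classes
  with 36/24/6 scans; 11 classes with 6 scans each) are available for
  small-sample experiments.
- **Seeding.** One master seed; each scan gets a counter-derived substream,
  so datasets are reproducible and independent of generation order.

What the generator does *not* emulate: electrode kinetics, the square-wave
staircase waveform, frequency/amplitude dependence, electrode-to-electrode
fouling beyond the per-peak ±10% height jitter, and the unexplained
high-potential activation reported for Pb scans in the source data.
Passing tests on this data therefore demonstrate that the pipeline works on
data with the *described* structure — peak-position fingerprints over a
shared background with class imbalance — not that it would reach identical
scores on any particular experimental library.  A fidelity anchor: on the
synthetic 11-class library the LDA baseline's micro ROC-AUC lands in the
same low-0.9s regime reported for it on the experimental library
(`analysis/02_classical_baselines.py` computes it), so the
classical-baseline difficulty of the emulation is in the right range while
the deep models reach the near-perfect regime — the ordering the study
observed.

## Classifiers

**Classical.**  PCA-SVM projects to 3 principal components and fits an RBF
SVM (probabilities by pairwise coupling).  LDA reduces to a 3-discriminant
subspace for embeddings but classifies with its native Bayes rule (an
11-class LDA restricted to 3 components would otherwise be ill-defined).
1NN-DTW is implemented from scratch: banded dynamic programming with a
Sakoe–Chiba window of 10 samples, absolute-difference local cost (squared
available), k = 1, ties to the earliest training index.  The window is
interpreted in samples, not percent of length, following the stated
computational constraints of the original protocol.

**Deep.**  Four architectures in pure NumPy (float32, im2col convolutions):

- *FCN*: three stride-1 "same" blocks (conv → batch norm → ReLU) with
  128/256/128 filters and kernels 8/5/3, global average pooling, softmax.
  Kernel sizes follow the convention of the FCN family this architecture
  derives from; the filter counts are fixed by the study.
- *LSTM*: the dimension-shuffled recurrent model — the length-L trace is
  presented as one time step with L features, collapsing the recurrence to
  a single cell update; 80% dropout after the recurrent block (disabled for
  the isolated LSTM in the original description, kept configurable here;
  default 0.8 as in the hybrids).
- *LSTM-FCN / ALSTM-FCN*: both branches concatenated before the softmax
  head.  The attention variant gates the dimension-shuffled input with a
  softmax attention vector (nonnegative, sums to 1 per scan) and feeds the
  reweighted presentation `L · a ⊙ x` to the LSTM; the factor L keeps a
  uniformly-attended input unchanged.  Published descriptions of this
  attention cell differ in detail; any variant satisfying the
  normalization contract is acceptable for the analyses here, and the
  implemented one keeps the attention weights exportable per scan.

Training: class-weighted softmax cross-entropy (weights `N/(K·n_c)` — the
rare-event correction, so each class carries equal effective mass), Adam at
initial learning rate 1e-3, plateau decay by 2^(1/3) after every 100 epochs
without validation-accuracy improvement, floored at 1e-4; He initialization
for convolutions, Glorot for dense/recurrent kernels.  Validation for
plateau detection is the test split of the repeat, matching the
optimistic-monitoring convention of the works the protocol follows.

## Evaluation protocol

Randomized, stratified, shuffled train/test splits: 70:30 for the seawater
and 3-class explosives schemes, 50:50 for the 11-class explosives scheme.
Per-split metrics: macro-F1 (argmax labels; the 0.5 threshold is kept only
for optional per-class binary reports), one-vs-rest ROC-AUC per class plus
micro (pooled) and macro (unweighted mean) averages, and the confusion
matrix.  Splits are repeated (25 at study scale) and metrics aggregated as
median and IQR.  Classes with no positives in a test split have undefined
AUC and are excluded from the macro average with a warning — reachable in
the 6-scans-per-class layouts.  Paired per-split scores of two models are
compared with the two-sided Wilcoxon signed-rank test; identical score
vectors return p = 1 by convention.  AUC is cross-checked against a
brute-force pairwise-comparison oracle in the tests, and DTW against
exhaustive warping-path enumeration.

## Class activation maps

For any model with a convolutional branch, the CAM of class c is
`CAM(t) = Σ_k w_kc · A_k(t)` over the 128 final-block feature maps, using
only the softmax weights attached to the GAP features (the recurrent
branch's weights are ignored in hybrids).  Maps are linearly resampled to
the input length (a no-op for the stride-1 stack) and min-max normalized;
constant maps normalize to all zeros.  On synthetic single-analyte scans
the CAM maximum falls on the analyte's programmed stripping peak, and on
blank scans the activation is diffuse.  The truncation experiment trims
traces to the 400-point anodic stripping window (drop 502 head / 100 tail
samples), retrains, and compares paired confusion matrices and accuracies
against full-length training on the same split.

## Problem sizes and compute presets

The deep models run on plain NumPy, so one training epoch on the 263-scan
seawater training split (1002-point traces) costs roughly half a TFLOP of
convolution arithmetic.  Three presets encode the scales used:

- `full` — 2000-epoch cap, 25 repeats: the study-scale protocol.
- `desk` — 300-epoch cap, 5 repeats: the CPU desk scale.  The
  dimension-shuffled LSTM costs one matmul per scan and runs this preset
  in under a minute per split, so it is evaluated at full desk scale
  (3 repeats in the shipped runs).
- `acceptance scale` — the sizes the test suite and the acceptance script
  use for the *convolutional* models so they complete on one CPU: batch
  size 4 (the smallest value of the batch-size refinement grid, which
  maximizes optimizer updates per epoch), epoch caps of 30 (deep-model
  survey), 40–80 (CAM analyses), and one split per convolutional model.
  Training also stops early once validation accuracy has saturated at 1.0
  for a stretch of epochs, after which the plateau schedule has nothing
  left to monitor.

At these scales the hybrids already reach micro ROC-AUC ≥ 0.999 on the
synthetic seawater libraries (their recurrent branch converges quickly and
the head combines it with the slower convolutional features), while the
pure FCN is still mid-optimization — its scores at the survey scale are
lower bounds, not converged values.  A reported median over repeats
summarizes fewer splits than the study-scale protocol; the repeat-to-repeat
IQR observed at desk scale is small, and every quantity is recomputed,
never cached.

## Numerical choices and degenerate inputs

- Batch-norm epsilon 1e-3, running-stat momentum 0.9; evaluation uses the
  running statistics.
- Softmax and cross-entropy computed in float64 with max-subtraction;
  probabilities clipped at 1e-12 inside the log only.
- Non-finite training loss raises a divergence error carrying the history.
- DTW of an empty trace, splitting a class with fewer than 2 scans,
  truncating to fewer than 2 points, and peaks placed outside the grid's
  potential range are all rejected with explicit errors.
- Constant raw CAMs normalize to zeros; min-max otherwise.
- Wilcoxon on all-zero differences returns p = 1 rather than erroring.

A structural caveat on the truncation experiment: in the emulated library,
methyl parathion's only programmed feature is its cathodic peak (−0.71 V)
and blank seawater's only feature is the cathodic oxygen background, so
truncating to the anodic window leaves both classes featureless and
mutually indistinguishable — the truncated 4-class problem has an accuracy
ceiling of roughly 0.87 on a typical test split, and the measured drop
versus full-length training is correspondingly larger than on the
experimental library this emulates (whose anodic branches evidently retain
more class information than the published peak table describes).  The
truncation machinery itself is exercised end-to-end regardless.

## Known limitations

- The generator's amplitude model is linear in concentration with no
  saturation; real stripping responses flatten at high load and clip at
  the instrument's current range, so the synthetic dynamic range is, if
  anything, harsher than the real one.
- The 40× amplitude spread makes 1NN-DTW and PCA-SVM weak here (neither is
  amplitude-invariant) — the same ordering the study observed.
- Deep-model scores at acceptance scale are lower bounds on what longer
  training achieves; the epoch caps are compute choices, not convergence
  claims.
- No GPU path, no mixed precision, no k-fold machinery (the protocol uses
  repeated shuffle splits throughout).
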