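# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `nirstreat`. Everything quantitative stated here is
computed by the test suite or the acceptance script; nothing is quoted from
external data.

## Probe model and montage

The packaged montage is a 3×11 grid of optodes (33 total, alternating
sources and detectors in a checkerboard), every horizontally or vertically
adjacent source–detector pair at 3 cm separation forming one of 52
channels. Channels on the two lowest channel rows sit on the T3–Fz–T4 line
and are heavily noise-contaminated in practice, so the default in-use mask
retains 32 channels over the prefrontal cortex (the top two channel rows,
the full upper vertical band, and one midline vertical). Two channels are
*neighbours* iff they share an optode; the packaged numbering makes the
neighbours of C14 exactly {C7, C8, C20, C21}, and neighbourhood is
symmetric by construction. The montage is YAML configuration, not code:
laboratories with a different layout supply their own file with the same
schema. Channel reconstruction (used before connectivity analysis) imputes
a QC-discarded channel as the arithmetic mean of its *kept* neighbours;
reconstructed channels never donate to another reconstruction, and a
discarded channel with no kept neighbour fails the subject by default
(configurable to plain exclusion).

## Task paradigm and baselines

The verbal-fluency session lasts 170 s at 10 Hz: 10 s pre-scan, 30 s
pre-task, 60 s task, 70 s post-task. Two baseline windows anchor the
hemodynamic baseline: b₁, the 10 s immediately before task onset, and b₂,
55 s in the post-task block. The text anchor for b₂ does not fix its
position inside the 70 s block; we place it at the *end* of the session
(the final 55 s), skipping the first 15 s of post-task so the hemodynamic
recovery does not leak into the baseline. Baseline correction subtracts,
per channel, the straight line through (centre of b₁, mean over b₁) and
(centre of b₂, mean over b₂) — a two-point linear baseline rather than a
single mean, because two separated markers define a trend, not an offset.

## Preprocessing chain

Order of operations: optical density → motion detection → spline
correction → wavelet despiking → linear detrend → band-pass → Beer–Lambert
conversion → baseline correction → channel QC.

- **Optical density.** ΔOD = −log₁₀(I/I₀) with I₀ the mean of the whole
  recording, making ΔOD invariant to global intensity scaling.
- **Motion detection.** A sample is flagged when the max–min excursion in
  any 0.5 s window exceeds 20 channel standard deviations or 5 OD units;
  flags dilate by 1 s on both sides. These are conventional defaults for
  block-task recordings and are exposed as parameters; the standard
  deviation is that of the recorded (artefact-containing) signal, so a
  *sustained* step inflates its own threshold — the detector is built for
  transient spikes, which is what the generator produces.
- **Spline correction.** Within each flagged segment a cubic smoothing
  spline (csaps-style parameter p = 0.99, roughness weight λ = (1−p)/p) is
  subtracted and the segment re-levelled to the preceding clean segment's
  mean (following clean segment when the artefact opens the recording).
- **Wavelet despiking.** Per channel, a depth-4 periodised db4 DWT;
  detail coefficients outside the Tukey fences (quartiles ± 1.5 IQR of
  their level) are zeroed. Depth 4 at 10 Hz leaves the ≤ 0.3 Hz band — all
  of the hemodynamic range — untouched. Quantile fences need a noise
  floor: on *exactly* noise-free signals the IQR collapses and the fences
  become degenerate; in practice any physiological noise sets the scale.
- **Band-pass.** 5th-order Butterworth high-pass at 0.01 Hz cascaded with
  a 3rd-order low-pass at 0.1 Hz, each applied forward–backward
  (zero-phase, so task timing is not shifted). Note the passband edge
  effect on block designs: the fundamental of a 60 s boxcar response lies
  near the high-pass edge, so the recovered response peak is attenuated by
  roughly a third relative to the planted amplitude. Tests therefore
  compare the pipeline output against the *identically filtered* ground
  truth; under that oracle the intensity → OD → hemoglobin round trip is
  transparent to ~10⁻⁵ relative.
- **DPF.** DPF(age, λ) = α + β·age^γ + δλ³ + ελ² + ζλ with α = 223.3,
  β = 0.05624, γ = 0.8493, ε = 0.001245, ζ = −0.9025 and δ = −5.723×10⁻⁷.
  The δ scale matters: at 10⁻³ the cubic term alone is ≈ −3×10⁶ and the
  DPF is astronomically negative, so `compute_dpf` rejects non-positive
  results; any δ can still be supplied explicitly via `DPFCoefficients`.
  Defaults give DPF(30, 830 nm) ≈ 5.68 and DPF(30, 695 nm) ≈ 6.32,
  increasing with age.
- **Extinction coefficients.** Standard compiled in-vitro values at
  695/830 nm, shipped as editable YAML; the absolute molar scale of
  ΔHbO/ΔHbR is configuration-sensitive and all downstream analysis is
  invariant to it except the QC amplitude threshold.
- **Channel QC.** SNR = band power below 0.1 Hz over band power above
  4.5 Hz (Welch), computed on the motion-corrected ΔOD *before* the
  band-pass (after it the > 4.5 Hz band would be numerically empty),
  worst case across wavelengths. Default mode discards channels with
  SNR < 10 or ΔHbO min–max range > 1.5 mM; a literal mode discarding
  SNR > 10 exists behind a flag for comparison. Amplitude is assessed on
  ΔHbO only, since all downstream features use ΔHbO. QC never mutates
  data; it marks channels.

## Features

**Time domain (13).** From the task-period ΔHbO averaged over the kept
in-use channels: mean, SD, variance, coefficient of variation, min–max
range, peak, time-to-peak (s from task onset), power-weighted centroid
time, area under the curve, onset slope (least squares over the first 10 s
of task), recovery slope (first 10 s post-task), skewness, kurtosis.
Channel-averaging before feature computation keeps the count at 13 total
(one PFC trace) rather than per-channel maps. Moments of a zero-variance
trace are defined as 0. The set is a module constant and deliberately
pluggable — any 13-statistic definition table can be substituted.

**Connectivity (7).** The task segment (with its own two-point baseline
against 1 s margins) over the 32 in-use channels, discarded channels
reconstructed from neighbours, yields a Pearson matrix with negatives and
the diagonal zeroed. Orthogonal-MST binarization: extract the MST of the
residual graph under distance 1/weight (Kruskal, lexicographic channel-pair
tie-breaks), remove its edges, repeat; after each aggregation compute
global cost efficiency = weighted global efficiency of the union − (sum of
selected weights / sum of all positive weights); keep the union at the
maximum. A disconnected positive graph is a subject-level error (the
subject is excluded upstream, with the exclusion logged). Metrics of the
binary graph: degree assortativity (0 for degree-regular graphs, where the
correlation is undefined), mean clustering, characteristic path length,
global efficiency, mean local efficiency, greedy modularity, and
small-worldness σ against 10 degree-preserving rewired references (20
swaps per edge, seeded; graphs too constrained to rewire fall back to
σ = 1).

## Reference-group projection

Features are z-scored with the NR group's mean and SD (ddof = 1) — the
whole transform is anchored to the reference group, consistent with
fitting the components on NR only. PCs come from the SVD of the z-scored
reference matrix (covariance divisor m−1; sign convention:
largest-magnitude loading positive). The discard count is
k = min{j : Σᵢ≤ⱼ EVᵢ ≥ θ} with θ = 0.99 by default; exclude-leading mode
retains PCs k+1…n, include-leading mode (ablation) retains PCs 1…k, and
θ = 0 degenerates to keeping everything. Note that after z-scoring every
feature has unit reference variance, so "low-variance directions" means
near-linear *dependencies* among features — contrasts that are almost
constant across reference subjects — not features with small raw scale.

Two fitting disciplines are provided. The replication discipline fits the
basis on all NR subjects before cross-validation and is the default (with
a logged warning): it mirrors the original experimental design but lets
reference statistics of held-out NR subjects leak into training folds. The
`fold_safe` discipline refits the basis inside every training fold. The
default is a faithfulness choice, not an endorsement.

## Classification

RBF SVM, one-vs-one for three classes. Hyperparameters (C, γ) are chosen
by a seeded random search: `iters` candidates log-uniform over
[10⁻³, 10³]², each scored by stratified 5-fold CV error, selecting the
lowest mean + 1 standard error ("best point" rule, guarding against
optimistically noisy minima); the budget, the seed and the selection rule
are the contract — the search strategy is pluggable. Folds are stratified
(with 13 subjects in the smallest class, unstratified folds could lack a
class entirely) and shuffled with the run seed; out-of-fold predictions
are pooled into one confusion matrix, from which per-class TP/FN/FP/TN and
the macro-averaged sensitivity, precision and specificity are computed
(zero-denominator metrics defined as 0 with a warning). miRNA columns are
never rescaled by default; an RBF kernel is scale-sensitive, so a
standardization flag exists, off by default for fidelity to the original
design. Binary mode merges PR into R before training; balanced mode
down-samples every class to the smallest class size with seeded sampling.

## Synthetic cohort: what it emulates, and what it does not

The generator is the package's study population: 24 NR / 15 PR / 13 R,
ages uniform 21–49, one 170 s session per subject, raw intensity
I = I₀·10^(−ΔOD) with per-channel I₀ and the forward Beer–Lambert model
(age-matched DPF) linking planted ΔHbO/ΔHbR (ΔHbR = −⅓ ΔHbO, a typical
anticorrelation; configurable) to the optics.

Planted structure, with defaults in parentheses:

- **Task response.** Canonical double-gamma HRF convolved with the 60 s
  boxcar, peak-normalized; group amplitude 0.3/0.45/0.6 µM (NR/PR/R).
- **Habituation (the group's time-domain signature).** The boxcar decays
  within the task with time constant τ = 20/45/∞ s: non-responders'
  activation fades, responders sustain it. This is a *shape* contrast
  among the amplitude-scaled features, exactly the kind of near-constant
  feature contrast the projection retains. Subject jitter: lognormal
  σ = 0.15 on τ.
- **Connectivity.** Two channel communities (the in-use list split in
  half) driven by band-limited (0.02–0.09 Hz) latent sources; the shared
  component grows with group (cross-community coupling 0.35/0.45/0.55).
  The contrast is deliberately modest relative to the sampling noise of a
  60 s correlation estimate, so connectivity alone classifies near chance
  — matching how weak task-FC group effects are at this recording length.
- **Dominant nuisance.** Lognormal response gain (σ = 0.6) scaling every
  amplitude feature; lognormal connectivity-SNR gain (σ = 0.8) shifting
  all network metrics; response latency jitter (SD 1 s) that, through the
  band-pass, scrambles the argmax-based timing features. An optional
  per-subject physiological-noise gain (`phys_gain_sigma`) defaults to 0.
- **Noise.** Linear drift (±2 nM/s), Mayer waves (0.1 Hz, 40 nM),
  respiration (0.25 Hz, 30 nM), cardiac (1.1 Hz, 20 nM) — subject-common
  phases with per-channel amplitude jitter — white noise (10 nM), and
  Poisson motion spikes (0.3/min, 5 µM, 0.6 s decay).
- **miRNA.** Log-normal expression on a normalized fold-change scale
  (log-means per group around 0–1, σ = 0.45, group-shifted with
  non-monotone patterns so all three classes are separable); on its own it
  classifies in the 60–80% range.
- **Labels.** HAM-D baselines 18–30 with group-consistent percentage
  reductions; every generated pair re-annotates to its planted label.

What passing tests on this cohort demonstrate: the pipeline's stages are
numerically correct, the projection removes exactly the kind of low-rank
multiplicative nuisance it was designed for, and under such nuisance the
projection is worth ≥ 10 accuracy points to multimodal fusion with the
explained-variance ablation ordering (exclude-99 ≥ exclude-95 ≥ include).
What they do not demonstrate: performance on real cortical hemodynamics —
real inter-subject variability is not purely low-rank, real group effects
are not planted contrasts, and scalp/systemic physiology is not modelled
(no short-separation channels, no photon-transport simulation).

## Numerical choices and degenerate inputs

- Zero/negative intensity, zero-variance channels, singular extinction
  matrices, disconnected graphs, zero-variance reference features and
  empty kept-channel sets all raise typed errors naming the offender.
- MST ties break lexicographically by channel pair; PC signs follow the
  largest-loading-positive convention; both make results backend-stable.
- All randomness (simulation, folds, candidate search, down-sampling,
  rewired references) flows from explicit integer seeds; a repeated run
  reproduces reports bit-for-bit, and each report embeds its config hash.
- Problem sizes in the test suite: five 52-subject cohorts for the
  mechanism checks with the 100-candidate search budget; oracle
  equivalences run on ≤ 6-node graphs (exhaustive enumeration) and
  5-node OMST brute force over all spanning trees.

## Known limitations

- The exact identity of the 32 in-use channels and the original 13/7
  feature definition tables are not recoverable from text; both are
  packaged as configuration reproducing the published counts and the one
  worked neighbour example, and can be replaced wholesale.
- The replication fitting discipline leaks reference statistics across CV
  folds by design (see above); use `fold_safe` for honest generalization
  estimates.
- The headline clinical accuracies of the original study are not
  reproducible without its (undeposited) cohort; this package demonstrates
  the *mechanism* on synthetic data instead.
- Absolute hemoglobin concentrations depend on the extinction-coefficient
  configuration; only the QC amplitude threshold consumes the absolute
  scale.
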