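# Methods

This note documents the models, algorithms and numerical choices behind
`sparpaf`, what the synthetic cohort generator does and does not emulate,
and the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic ECG cohort

The generator produces the study conditions the analysis assumes: a
single-lead sinus-rhythm ECG cohort with a large control group and a small
PAF-history group.

**Beat template.** One cardiac cycle is a Gaussian-bump mixture on a unit
phase grid (512 samples): P wave (amplitude 0.12, centre 0.16, width 0.035
of the cycle), QRS (Q/R/S at phases 0.285/0.30/0.315; R amplitude 1.0 and
width 0.008, multiplied by a per-subject polarity ±1 to emulate the
base-apex lead convention in which the R deflection may point either way),
and T wave (amplitude 0.25, centre 0.55, width 0.06). Per-subject
morphology variation is drawn deterministically from the subject seed;
amplitude coefficients of variation are 8% (P, T) to 20% (Q, S) and the
P/T centres vary by ±0.005 of the cycle. The diastolic (P/T) geometry is
deliberately kept tight: the sign-flip diagnostic (§5) presupposes a
within-class theta-core phase convention, which only exists when the
diastolic sequence is consistent across subjects.

**PAF substrate.** The PAF effect of size δ ∈ [0, 1] is

    amplitude(φ) = base(φ) + δ · (A₁(φ) − A₀(φ)) · W(φ)

where A₀ is the subject's own P bump, A₁ a shifted (+0.08 cycle), widened
(×2.5) and amplified (×8) version of it, and W a smooth taper that is
identically zero in and around the QRS window. Consequences: the QRS is
untouched for every δ (exactly, not just to tolerance); the L2 distance
from the δ = 0 template is exactly linear — hence monotone — in δ; and
δ = 0 gives byte-identical control and PAF generative distributions under
matched seeds (an exact null). The endpoint δ = 1 is scaled to exceed the
between-subject morphology spread by a wide margin, so the δ scale spans
chance-level to essentially perfect separability; δ ≈ 0.05–0.1 produces
the "subtle but detectable" regime, and 0.1 is the cohort default. In the
attractor domain the perturbation presents as a rotation/reshaping of the
central core region. No electrophysiological realism is claimed for the
mechanism; it is a controlled stand-in whose true physical correlate is
unknown.

**Record synthesis.** R-R intervals are lognormal with mean 60/heart-rate
and coefficient of variation 0.05, truncated to [0.3 s, 4 s] (positive,
right-skewed, physiological); the template is resampled to each drawn
interval and the beats concatenated. Corruptions: sinusoidal wander
(amplitude 0.25 of the R height at 0.15 Hz) plus a random-walk drift
low-passed at 0.2 Hz — both deliberately band-limited below the analysis
high-pass cutoff so that they are genuine *baseline* wander; band-limited
(30–100 Hz) noise at 25 dB SNR; Poisson artefact bursts (2/hour, 5–15 s,
4× R amplitude) emulating motion artefacts; and an optional sign-flip
(whole-trace negation) emulating an acquisition-convention mismatch between
devices. Subject heart rates are N(36, 4) bpm clipped to [20, 80]; half the
subjects have negative R polarity.

**Scale defaults.** The default cohort mirrors the emulated study
population — 120 control + 19 PAF at 500 Hz — with 180-s records, the
minimal analysis window admitting the three 60-s strips; this keeps a full
cohort tractable on a laptop. `CohortSpec.study_scale()` gives 3-hour
records; `CohortSpec.flipped_paf_preset()` gives the 19-PAF cohort with 6
sign-flipped records (δ pinned at 0.3 so the preset's phase convention does
not drift with the cohort default).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: AF episodes and f-waves (all generated rhythm is
sinus, as in the strips the analysis targets), autonomic heart-rate
dynamics (R-R jitter is i.i.d. lognormal, no respiratory sinus arrhythmia
or long-range correlation), beat-to-beat morphology variability within a
subject (the template is fixed per subject; only noise varies),
pathologies other than the PAF substrate, electrode-motion artefact
structure, and any true electrophysiological mechanism linking PAF history
to P-wave changes. Results on this cohort validate the *pipeline* —
bookkeeping, invariances, calibration under a known null, effect recovery
under a known effect — not clinical performance.

## 2. Preprocessing

From each record, three non-overlapping 60-s strips are selected inside an
analysis window of at most 3 h from the start, preferring the best-quality
strip per third of the window; if any third lacks a strip above the quality
floor, an exact weighted-interval-scheduling dynamic program picks the
best-scoring non-overlapping triple globally. Each strip splits into three
contiguous 20-s sub-strips (9 per subject; a 139-subject cohort gives 1251).

**Quality score** (automating a manual clinical review step): on the
5–40 Hz band-passed candidate,

    score = min(median prominence / IQR prominence, 50)/10
            − (power fraction below 0.5 Hz)
            − 2 · CV(3-s band-energy windows)

The first term rewards regular R-peak prominences, the second penalizes
baseline wander, the third penalizes artefact bursts (which make beat-band
energy strongly non-stationary — prominence regularity alone cannot catch
them, because a burst's few huge peaks are mutually "regular"). Clean
synthetic strips score ≈ 2, wander- or burst-dominated strips score below
0; the selection floor is 1.0. Flat signals get a finite minimum score.

**Filtering**, zero-phase throughout (forward-backward application, peak
timing shifts < 1 sample): an 8th-order Butterworth high-pass at 0.25 Hz —
chosen because at resting equine rates (~25–30 bpm) the ECG fundamental
lies at 0.42–0.5 Hz, and a 0.5 Hz cutoff measurably distorts the diastolic
waveform and rotates the attractor core for low-rate subjects; a zero-order
(moving-average) Savitzky–Golay smoother, window 7 samples at 500 Hz scaled
with the rate; and an equiripple Parks–McClellan FIR low-pass with 40/60 Hz
band edges, 1 dB ripple and 40 dB attenuation (tap count by the Harris
estimate). All cutoffs are package defaults, configurable in `FilterSpec`.

**Normalization** divides by the 99.9th percentile of *absolute* amplitude
(linear interpolation between order statistics), removing between-device
amplitude disparity; it is scale-invariant and odd, so the whole
preprocessing chain commutes with gain changes and sign flips.

**R peaks** are detected on the absolute signal — handling either R
polarity identically — with a 0.3 s refractory period (below the shortest
plausible equine sinus R-R at the simulated rates) and an adaptive
prominence threshold (40% of the 90th-percentile candidate prominence).
Sub-strips with fewer than two detected beats are excluded and logged, so
record counts are conserved: subjects × 9 = sub-strips + exclusions.

## 3. SPAR embedding and density profiles

Delay τ = mean R-R / 3, rounded to the nearest sample. Triples
(x(t), x(t−τ), x(t−2τ)) are projected as v = (x+y−2z)/√6, w = (x−y)/√2 —
a fixed orthonormal basis of the plane orthogonal to (1,1,1); any such
basis preserves all invariants, this one is recorded for reproducibility.
The projection is computed from pairwise differences so that a constant
offset cancels to rounding error. Invariants maintained by construction
and verified by tests: translation invariance (machine precision), negation
equivariance (rotation by π, exact), 3-fold symmetry for a strictly
periodic signal at τ = period/3, and heart-rate invariance under joint
time-rescaling of signal and delay.

The density image is a plain 2-D histogram (101 × 101 bins over the
symmetric extent max|coordinate| padded 5%, normalized to sum 1); a
histogram rather than a smoothed estimator is the package's choice, made
for exact mass bookkeeping. The core radius r_c is the radius enclosing a
configured fraction (default 0.5) of the points — a parameter-light,
robust quantile definition of the core/arm boundary. Polar profiles: the
radial density over 100 bins, and angular densities over 120 bins computed
separately for core (r ≤ r_c) and arm (r > r_c) points, normalized so the
two integrate to their point-mass fractions (jointly 1). Empty partitions
give all-zero profiles, not errors. Class-level profile figures show the
pointwise mean, mean + SD and 5th–95th percentile envelopes.

## 4. Features (the frozen 74-entry manifest)

73 attractor features + mean R-R, in frozen order (a golden test guards
names and count):

* **5 global:** maximum bin density; occupied-area fraction (bins above 1%
  of the maximum); core radius; core mass fraction; outer radius (99th
  percentile of r).
* **9 families × 7 statistics (mean, median, min, max, SD, 25th, 75th
  percentile) = 63:** radial distances of all points; per-arm lengths
  (95th percentile of r in the sector); per-arm peak angular densities;
  per-arm point-mass fractions; per-arm angular deviations of the density
  peak from the expected sector centre (sector centres at
  arm_phase + k·π/3, where arm_phase aligns the first sector to the
  largest arm-density peak — the "expected position" convention); theta-core
  density values; theta-arm density values; 3-fold symmetry residuals
  (per-bin |image − image of the point set rotated by 2π/3|, restricted to
  occupied bins — the rotated image is re-binned from rotated points on the
  identical grid rather than interpolated); per-sector core radial extents
  (95th percentile of core-point r per sector).
* **5 core/shape:** core peak density; core total density (mass of bins
  whose centre lies within r_c); centroid distance from the origin;
  principal-axis orientation of the point cloud; Shannon entropy of the
  density image.

Empty arms contribute zeros and are flagged in a per-vector quality mask.
All features are finite for every sub-strip the preprocessing admits, and
are invariant to input amplitude scaling via the normalization step.

## 5. Sign-flip diagnostic

Negation rotates the attractor by π, so records acquired with the opposite
sign convention have theta-core densities out of phase with the cohort.
`detect_sign_flip` computes the circular cross-correlation of a subject's
(sub-strip-averaged) theta-core density against a reference and flags the
record when the argmax phase lies nearer π than 0. The cohort-level
procedure uses two passes: a provisional pass against the grand-mean
profile establishes the majority convention, then the reference is
recomputed from the majority group only and all subjects are re-tested.
The remedy is multiplying the affected signals by −1; because the filter
chain and normalization are odd, this is applied directly to the
preprocessed sub-strips.

Limitation: the diagnostic presupposes a cohort-wide theta-core phase
convention. A rare morphology draw can produce a near-phase-symmetric core
profile that no reference can classify (observed in roughly one subject in
several hundred generated); real cohorts with heterogeneous diastolic
geometry would need a per-device or per-lead reference instead.

## 6. Classification

**ASUWO oversampling.** The minority training class is clustered by
average-linkage agglomerative clustering (default 3 clusters, capped at
half the minority size); clusters into which the majority intrudes
(nearest-majority distance below the intra-cluster median pairwise spread)
are trimmed from synthesis (all retained if every cluster is trimmed);
remaining clusters receive synthesis budget proportional to
size / (nearest-majority distance) — boundary-difficulty weighting — and
synthetic rows are uniform convex combinations of random same-cluster
minority pairs until the classes balance (target ratio 1.0). Original rows
are never modified, synthetic rows are marked, and only real rows are ever
scored.

**Ensemble.** k-NN with k = 9 and standardized Euclidean distance
(features divided by the training SD; zero-variance features get scale 1
with a warning); linear-kernel SVM on standardized features; RBF-kernel
SVM on raw features (standardization can amplify feature noise under a
nonlinear kernel), with the kernel width set by the median heuristic
(γ = 1/median squared pairwise distance, on up to 256 training rows) and
C = 1. SVM posteriors are Platt-style sigmoid calibrations fitted on
training data via internal 5-fold CV. Standardization, γ and calibration
all derive from training data only — no leakage by construction.

**Votes.** The two-level vote is read minimally: the sub-strip
*hard label* is the majority of the three member labels (each member
thresholded at 0.5), while the *continuous score* — used only for ROC —
is the mean member posterior. A subject's score is the fraction of its 9
sub-strips voted PAF; with 9 sub-strips the 0.5 threshold can never tie.
Sub-strip-level ROC uses the mean posterior; subject-level ROC uses the
vote fraction (the subject score as defined).

**SRRS.** Each run samples the configured stratified counts (full scale:
108/15 train, 12/4 test, 1000 runs; desk-scale presets use 25–100 runs),
enforcing unique training-subject combinations across runs (infeasible
requests fail naming the combinatorial bound). Aggregates are the mean and
the 2.5th–97.5th percentile interval per metric and level. Rates are
reported in percent; AUC (rank/trapezoid, PAF positive) in [0, 1]; AUC is
reported as missing for single-class truth.

**Forward feature selection** greedily maximizes
J = w·sensitivity + (1−w)·specificity at the subject level (SRRS-averaged),
with w = 2/3 and stopping threshold ε = 0.001 — the sensitivity emphasis
reflects that missing a PAF case costs more than a false alarm. The same
split sequence (same seed) is used for every candidate evaluation, making
comparisons paired and the procedure deterministic.

## 7. Orchestration and determinism

A single global seed is fanned out to every stage and subject through
`numpy.random.SeedSequence` with stable string-derived keys, so re-running
one stage never perturbs another and an identical configuration reproduces
all tables bit-for-bit. Every exclusion is logged; every record is
accounted for in outputs or the exclusion log. The pipeline writes the
cohort manifest, sub-strip and feature tables, selected features, per-run
and aggregate cross-validation tables, per-subject mean scores, sign-flip
flags, a JSON run summary, and the standard figures (attractor image,
class density-profile bands, theta-core flip diagnostic). Signals are
exchanged as two-column plain text (time_s, amplitude; comma/tab/space
dialects auto-detected, sampling rate inferred from the median time step).

## 8. Problem sizes used in the test suite

The suite validates the analysis at desk scale, chosen as the smallest
sizes at which each property is meaningfully testable: full-cohort
bookkeeping at the emulated study size (139 subjects, 1251 sub-strips,
180-s records); null calibration and effect recovery on 30 control / 10
PAF cohorts with 24/8–6/2 splits at 40–100 SRRS runs; the effect-size
ladder at δ ∈ {0, 0.05, 0.3, 1.0}, spanning chance to saturation on the
frozen effect scale; and the sign-flip preset at its default seed. The
full-scale protocol (1000 runs, 108/15–12/4) is the library default for
real use.
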