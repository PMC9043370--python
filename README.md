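# sparpaf

Detecting a **paroxysmal atrial fibrillation (PAF) history from
normal-sinus-rhythm single-lead ECG** with Symmetric Projection Attractor
Reconstruction (SPAR) and an ensemble machine-learning classifier.

PAF presents as intermittent, self-terminating AF episodes and is hard to
diagnose once sinus rhythm has resumed. In equine athletes (and humans), a
PAF history is thought to leave subtle morphological traces in the sinus
ECG. `sparpaf` implements a complete, tested analysis pipeline for this
problem — strip selection, filtering, SPAR embedding, attractor feature
extraction, imbalance-aware ensemble classification and repeated-subsampling
cross-validation — driven by a synthetic single-lead ECG cohort generator,
so that every stage of the analysis can be exercised, calibrated and
validated without access to any clinical recordings. It is aimed at
physiological-signal researchers who want a self-contained, reproducible
reference implementation of the SPAR-plus-ML workflow.

## The method

**SPAR embedding.** A roughly periodic signal x(t) is represented by delay
triples (x(t), x(t−τ), x(t−2τ)) with τ = mean R-R interval / 3, projected
onto the plane orthogonal to the (1,1,1) diagonal:

    v = (x + y − 2z)/√6,    w = (x − y)/√2

This 2-D "attractor" is invariant to vertical offsets, independent of heart
rate, and 3-fold rotationally symmetric for a strictly periodic signal with
τ = period/3. Negating the signal rotates the attractor by π — the
signature used to diagnose sign-flip acquisition artefacts. The attractor
splits into a high-density central **core** (driven by the non-QRS part of
the cycle) and six lower-density **arms** (driven by the R deflections).

**Features.** Each 20-s sub-strip's attractor is quantified by a frozen
manifest of 73 features (size, shape, 3-fold-symmetry residuals and density
distribution over the core + 6 arm regions) plus the mean R-R interval —
74 features in total.

**Classification.** Sub-strips are classified by a majority vote of three
classifiers — k-NN (k = 9, standardized Euclidean distance), a linear-kernel
SVM on standardized features, and an RBF-kernel SVM on raw features — with
the PAF training minority oversampled to class parity by cluster-based
adaptive weighted interpolation (ASUWO); synthetic points are used for
training only. A subject is classified by majority vote of its 9 sub-strips
(score = PAF votes / 9, threshold 0.5). Performance is assessed by
stratified repeated random sampling (SRRS): repeated stratified
subject-level train/test splits with unique training combinations, reported
as the mean and 95% coverage interval (2.5th–97.5th percentile) of
accuracy, sensitivity, specificity, ROC AUC and per-class F1, with PAF as
the positive class.

**Synthetic cohort.** The generator emulates the study population the
analysis assumes: 120 control + 19 PAF subjects, single 500 Hz lead (256 Hz
dialect supported), resting equine heart rates, R deflections of either
polarity, baseline wander, band-limited noise, artefact bursts and an
optional sign-flip artefact. The PAF substrate is a tunable, purely atrial
morphology perturbation of effect size δ ∈ [0, 1] with an exact null at
δ = 0. See `docs/methods.md` for what the generator does and does not
emulate.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_attractor_and_profiles.py` prints

```
sub-strip: 10000 samples, mean R-R 1.453 s, tau = 0.484 s (9516 attractor points)
core radius r_c = 0.134 (encloses 50% of the points)
peak bin density 0.0554; theta-core density peak 0.167 at 175 deg
attractor image saved to scratch_attractor.png
```

— a 20-s sub-strip at a resting equine rate (R-R 1.45 s) embedded at
τ = R-R/3, whose densest attractor bin holds 5.5% of the points and whose
core (half the point mass) sits within radius 0.134 of the origin in
normalized amplitude units. `examples/04_crossvalidation.py` runs the full
ensemble on a 16 control / 6 PAF cohort with a moderate effect (δ = 0.3)
and prints the SRRS metric table, e.g. subject-level accuracy 94.7%
(80–100%), sensitivity 86.7%, specificity 100%, ROC AUC 0.94 over 30 runs;
`examples/05_sign_flip_diagnostic.py` recovers exactly the 6 of 19 subjects
whose traces carry the sign-flip artefact, each with a theta-core phase
within a few degrees of 180°.

The whole pipeline can also be driven from the shell:

```
sparpaf run-all --seed 1 --outdir runs/demo
sparpaf report runs/demo
```

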