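# Methods

`tracenet` predicts the binary nascent-transcription state of single cells
from their chromatin-trace pairwise-distance matrices and then interrogates
the trained classifier to identify which structural features carried the
prediction. All analyses run on synthetic ensembles with known regulatory
ground truth, so every interpretability claim the package makes can be
checked against the rule that generated the labels.

## Data model

A trace is the ordered 3D path of B = 52 genomic barcodes (~6 kb steps over
~312 kb) in one cell, in nanometres. Absolute coordinates depend on the
viewing angle, so the working representation is the 52×52 matrix of all
pairwise Euclidean distances — invariant to rotation and translation while
retaining all internal structure. Missing barcodes (undetected spots) are
imputed by linear interpolation along the chain at the missing barcode's
fractional position between its nearest observed neighbors; missing runs at
either chain end copy the nearest observed barcode (constant extrapolation;
a `reject` policy is available). Traces with fewer than two observed
barcodes are rejected and counted in a QC report; no other completeness
filter is applied by default, though a fraction-missing cutoff can be
configured.

Datasets are split 60/20/20 into train/validation/test, stratified by
label. Matrices are z-standardized entrywise against the training split's
per-entry mean and standard deviation (std floored at ε = 1e-6 to protect
the degenerate diagonal). An alternative normalization — dividing each
entry by the training mean — is available via `NormStats(mode="mean_ratio")`
for users who prefer relative-distance accentuation; the z-score is the
default because it is the variant stated precisely enough to implement
unambiguously, and the package treats the choice as a configuration flag
rather than a scientific commitment.

Barcode indices are 1-based in files, configuration and reports ("monomer
20", "monomer 40") and 0-based in in-memory arrays.

## Polymer ensemble generator

The generator produces heterogeneous, physically plausible conformations of
a confined 52-monomer bead-spring chain; it is a deliberately simplified
Brownian-dynamics engine, not a molecular-dynamics reproduction. Forces:

* harmonic bonds, rest length 1 (≈60 nm), stiffness 40 kT — bond
  fluctuations of a few percent, verified against the Boltzmann average by
  1-D quadrature;
* Kratky–Porod bending stiffness 8 kT, giving a persistence length of
  roughly five barcode steps. This is the term that makes adjacent barcodes
  redundant witnesses of each other's position, the property that real
  chromatin traces show and that the occlusion analyses depend on: with a
  freely jointed chain, no classifier — however trained — can recover a
  blanked barcode's distances from its neighbors (we measured an
  information ceiling near 69% predictability under 5-barcode blanking by
  retraining a logistic regression on blanked inputs), whereas the locally
  smooth chain raises that ceiling above 90%;
* capped soft-core repulsion (no self-attraction): force
  k(1 − r/r_rep) below r_rep = 0.8, zero beyond — excluded volume without
  hard-sphere stiffness;
* harmonic radial confinement beyond radius 4 (≈240 nm), standing in for
  nuclear density. The wall is soft; excursions scale as √(kT/k_conf).

Integration is overdamped Langevin (Euler–Maruyama, dt = 0.005, kT = 1)
with a numba-compiled kernel. Chains initialize as random walks folded into
the confinement sphere and burn in for 20× the frame interval so the
bending term can relax the initial walk. Each chain is recorded for 100
frames separated by `steps_per_frame` integration steps, and every frame is
one example, as in single-cell imaging where each cell is one observation;
consecutive frames of a chain are autocorrelated, which is documented
behavior, and `ConformationEnsemble.thin()` subsamples frames when
independence matters more than sample count.

The simulation-unit-to-nanometre scale (60 nm per unit) anchors the
physical 150 nm enhancer–promoter contact call used by the baseline
predictor. Under the defaults the enhancer–promoter distance (monomers
20–40) has a coefficient of variation above 0.3 — the heterogeneity that
makes contact labeling non-degenerate.

What the generator does *not* emulate: loop extrusion, epigenetic-state
block copolymers, chromatin-fiber torsion, locus-specific compaction
differences, or measurement noise (localization error is added separately
by `add_coordinate_jitter`, and missing-barcode dropout by the trace
reader's MISSING pathway). Conclusions from passing tests therefore concern
the analysis machinery — that the classifier and its interpretation
recover planted regulatory rules from polymer-realistic distance maps — not
any particular biological locus.

## Labeling rules

Four ground-truth rules assign ON/OFF labels; all operate on the raw
(nanometre) geometry:

* **binary contact** — rank all examples by d(20, 40); the closest 30% are
  ON. The 30% matches the nascent-transcription class balance of typical
  locus imaging.
* **compaction** — rank by the median of all B(B−1)/2 pairwise distances;
  the most-decompacted 30% are ON (decompaction ↔ activity).
* **hierarchical**, independent or cooperative — promoter at 20, enhancers
  at 5 and 35, dominant silencer at 45. Per example, contact indicators are
  distances ≤ a threshold; silencer–promoter contact silences with
  probability 0.8 regardless of enhancers; otherwise the independent
  variant draws one 0.8-probability activation per contacting enhancer (ON
  if any succeeds — "either enhancer activates with equal probability"
  read as independent events; a single-draw variant is available), and the
  cooperative variant activates at 0.8 when both enhancers touch but only
  0.1 for a single contact. The contact threshold is calibrated by
  bisection on the closed-form expected ON fraction so the class balance
  matches a target (default 0.30, the same balance as the rank rules); the
  expected-ON curve is not monotone in the threshold (the silencer
  eventually dominates), so calibration brackets the first crossing on the
  rising branch and errors with the achievable range if the target is
  unreachable.

**Label noise** models non-structural determinants of transcription: each
example first has probability f (default 0.50; 0.25/0.75 variants) of
receiving a fair-coin label and never consulting the rule. Noise is applied
before the rule, and ranking always happens over the full ensemble. The
expected ON fraction is f/2 + (1−f)q.

Under the rank rules the only label-relevant information is the binary
rule indicator, so the achievable AUC has a closed form
(`bayes_optimal_auc`): with f = 0.5, q = 0.3 the conditional probabilities
are P(R=1|ON) = 0.5625 and P(R=1|OFF) = 0.125, giving AUC ≈ 0.719 with the
standard tie correction. Every trained classifier is checked against this
ceiling — a test AUC significantly above it indicates leakage, not skill.

The **shuffle control** permutes labels uniformly, preserving class counts
while destroying all structure–label correspondence; trained on shuffled
labels, any classifier must score AUC ≈ 0.5.

## Classifiers

The central model is a small 2D CNN on standardized matrices: two
convolution blocks (8 then 16 filters, 3×3 kernels, batch normalization,
ReLU, 2×2 max-pool), a 16-unit dense ReLU layer and a sigmoid output,
trained with binary cross-entropy under AdamW (lr 2e-3 with a 100-step
linear warmup, decoupled weight decay 2e-3, batch 128, 14 epochs, no early
stopping — training sits well inside the loss plateau, which the recorded
per-epoch history lets callers verify). The engine is a compact numpy
implementation with manual backpropagation; every backward pass is pinned
by finite-difference gradient checks, and gradients flow to the input,
which the attribution code requires.

Two training details matter and are deliberate:

* **Occlusion augmentation.** Every training example has three random
  windows of 3–7 barcodes' rows and columns zeroed (the dataset average in
  standardized space). This mirrors the missing-barcode dropout that real
  traces exhibit and forces the network to learn the redundant,
  neighborhood-distributed representation that locally smooth polymers
  support. Without it the CNN reads single matrix entries and occlusion
  analysis degenerates (blanking a 5-barcode window over the enhancer
  collapses predictability toward ~30 and varies wildly across training
  seeds); with several small windows the learned floor is high and stable.
  The window sizes stay well below the 20-barcode knockouts used in
  evaluation so that large-window blanking remains essentially
  out-of-distribution, though a confined polymer does carry weak global
  information about any pairwise distance, and an occlusion-robust model
  retains a correspondingly small residual score under 20-wide blanking.
  The augmentation can be restricted to the first k epochs
  (``occlusion_epochs``) or disabled (``occlusion_max_window=0``).
* **Warmup, dense-bias init and restarts.** Without countermeasures, a
  minority of initializations drive every hidden ReLU dead in the first few
  batches, leaving a constant predictor. Three guards are in place: a
  100-step linear learning-rate ramp, a small positive (0.01) dense-bias
  initialization, and a deterministic restart — if the validation logits
  have collapsed to a point after the third epoch, training reinitializes
  from a shifted seed (at most three restarts, recorded in the training
  history).

The comparison models share the evaluation protocol: a dense network on the
flattened matrix (no spatial prior), a random forest
(scikit-learn, flattened input, probability = vote fraction), the classic
enhancer–promoter call (ON iff d(20,40) ≤ 150 nm, inclusive, raw
nanometres only), and a nearest-class-mean "average similarity" classifier
under the Frobenius metric with ties resolved to OFF (the majority class).

Evaluation reports ROC/AUC (rank statistic), precision/recall/F1 and the
confusion matrix at probability 0.5, and the odds ratio
(TP·TN)/(FP·FN) with the Haldane–Anscombe +0.5 correction on zero cells
and a percentile bootstrap CI (3000 resamples by default). Stratified
k-fold cross-validation (default 10), training-set downsampling and
coordinate jitter reproduce the robustness protocol; hyperparameters are
selected by validation AUC over an explicit configuration grid.

## Interpretation

**Window blanking.** A window of barcodes is occluded in the standardized
test matrices by zeroing its rows and columns (zero = dataset average in
z-score space; the matrix-space reading of the procedure). The blanked AUC
maps linearly to *normalized predictability* — 100 at the unblanked AUC,
0 at chance (the two anchor points are fixed by the score's definition;
the linear interpolation between them is this package's choice) — and the window slides with step 1 at
widths 1–30. Error bounds come from stratified subsampling of the held-out
set (default 10 trials at 80%) under the single trained model; the
alternative of re-training on resampled train/test splits captures
training variability too but is substantially more expensive — callers
wanting that can train multiple models and scan each.

**Expected-gradients attribution.** Per-example signed maps in the SHAP
family: the Monte-Carlo estimate of E[(x − r) ⊙ ∇f(r + α(x − r))] over
background references r (100 training examples) and α ~ U(0,1), with 32
path samples by default, attributing the pre-sigmoid logit (the sigmoid's
saturation makes probability-space gradients vanish exactly where the
model is most confident). Positive values push toward ON. Maps are
symmetrized ((M + Mᵀ)/2) since the input is symmetric and the convolution
stack need not be.

**Population aggregation.** Per entry, the mean of the top decile of that
entry's attributions across ON cells (bottom decile across OFF cells) —
emphasizing rare-but-strong features that plain averaging cancels; the
companion map gives the median raw distance over the same cell subsets
(contact vs separation), and a per-entry one-sample Wilcoxon signed-rank
test against zero (normal approximation; all-zero entries get p = 1)
provides the −log10 p significance maps. The signed-rank choice is this
package's: there is no standard test for such maps, and a
location-free, symmetric-null nonparametric test is the natural default
for signed per-cell attributions. No multiplicity correction is applied by
default (the maps are exploratory); Benjamini–Hochberg is a flag.

**Cooperativity.** An entry is "extreme" in a cell when its attribution
exceeds its own population percentile (99th by default for ON; mirrored
for OFF). For entry (a,b), over the cells where it is extreme, the
co-occurrence with each other entry (c,d) is the fraction of those cells
in which (c,d) is also extreme; the map averages over all (c,d) ≠ (a,b),
and `pairwise_cooccurrence` exposes the anchored "punctum" view. For
independent entries the expected co-occurrence equals the extreme rate r,
so hub-like structure shows as exceedances over r; p-values come from a
permutation null that shuffles each entry's extreme-cell assignment
independently across cells (destroying within-cell co-occurrence,
preserving per-entry rates; 200 permutations by default). Entries never
extreme are NaN-masked and logged.

## Numerical and procedural choices

* Rank-rule ties break by example index (stable sort) — relevant only for
  degenerate ensembles.
* Blanking refuses all-nonnegative input as likely raw distances (the
  procedure is defined in standardized space); `assume_standardized`
  overrides.
* The blanked-window fill is exactly 0 under z-score normalization; under
  `mean_ratio` normalization pass `fill=1.0`.
* AUC requires both classes; single-class test sets raise.
* All randomness flows through explicit integer seeds; the pipeline derives
  named per-stage substreams from one global seed by hashing, so adding a
  stage never shifts another stage's stream.
* Attribution decile counts use round(n/10) with a floor of one cell;
  classes with fewer than 10 cells are rejected.

## Problem sizes

Defaults are 500 chains × 100 frames = 50,000 examples with 100
integration steps per frame. The shipped analyses
choose desk-scale sizes: the enhancer–promoter blanking analyses use
20,000 examples (the learned neighborhood redundancy that sets the
5-barcode blanking floor is data-hungry; at 10,000 examples the same
training protocol learns a more entry-local solution and the floor drops),
compaction and shuffle controls use 10,000, and the hierarchical,
cooperativity and jitter analyses use 6,000 with an 8-epoch schedule,
since they assert localizations and orderings rather than calibrated
scores. The test suite states these sizes in its module docstring;
`scripts/acceptance.py` prints its sizes alongside each result.

## Known limitations

* The polymer is a single homogeneous chain; its force constants were
  chosen to reproduce qualitative ensemble properties (heterogeneous E–P
  distances, near-neighbor redundancy decaying over ~10 monomers), not
  fitted to any measured locus.
* Blanking-error bars from test-set resampling understate the variability
  that re-training would add.
* The cooperativity permutation null preserves per-entry rates but not the
  spatial smoothness of attribution maps, so its p-values are liberal for
  entries adjacent to genuinely extreme ones.
* Expected gradients assume a differentiable model; the random forest is
  excluded from attribution analyses by design.
* Training determinism holds for fixed seeds on a given platform; across
  BLAS builds bit-level identity is not guaranteed, though all reported
  quantities are far above that noise floor.
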