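# tracenet

Deep-learning analysis of single-cell chromatin traces: predict whether a
gene is transcribing from the 3D fold of its regulatory domain, then unpack
*which* structural features the classifier used.

Chromosome-tracing microscopy (ORCA, Hi-M, MINA) reports, per cell, the
ordered 3D coordinates of B sequential genomic barcodes — here B = 52 steps
of ~6 kb — together with a binary nascent-transcription readout (ON/OFF)
for genes in the traced locus. `tracenet` is for researchers who have such
paired structure/expression data (or want to benchmark methods for it on
simulations with known ground truth) and who want to go beyond
single-threshold enhancer–promoter contact analyses.

## What it computes

Each cell's trace becomes the rotation-invariant pairwise-distance matrix
D ∈ ℝ^{52×52}, D_ij = ‖x_i − x_j‖. A convolutional network f(D) ∈ [0,1]
is trained on z-standardized matrices to estimate P(ON | structure),
evaluated by ROC AUC and by the odds ratio (TP·TN)/(FP·FN) against
baselines: the classic contact call 1{d(E,P) ≤ 150 nm}, a nearest
class-mean classifier, a dense network and a random forest.

Interpretation then proceeds three ways:

* **window blanking** — occlude a sliding window of barcodes (rows and
  columns set to the dataset average) and rescale the blanked AUC to a
  *normalized predictability* (100 = unblanked, 0 = chance), localizing
  the informative genomic windows;
* **expected-gradients attribution** (SHAP family) — per-cell signed maps
  φ_ij aggregated population-wide by the mean of each entry's top decile
  over ON cells (bottom decile over OFF cells), with median-distance and
  signed-rank significance companion maps;
* **cooperativity** — for each entry, the average frequency with which
  other entries are simultaneously attribution-extreme in the same cells,
  a signature of hub-like, more-than-pairwise regulation.

A bundled Brownian-dynamics generator produces confined 52-monomer
bead-spring ensembles, and labeling rules with known ground truth
(enhancer–promoter contact, compaction, hierarchical enhancer/silencer
logic with or without cooperativity, plus stochastic label noise and a
label-shuffle control) make every interpretability claim checkable.
See `docs/methods.md` for the full model description.

## Worked example

```bash
python examples/01_simulate_and_label.py
```

prints

```
2000 conformations
mean bond length: 62.5 nm (one barcode step along the fiber)
mean radius of gyration: 176 nm (overall domain size inside the confinement sphere)
binary contact, no noise: ON fraction 0.300
binary contact, 50% noise: ON fraction 0.401
compaction, 50% noise: ON fraction 0.410
hierarchical rule: calibrated contact threshold 198 nm, ON fraction 0.294
```

The polymer steps ~60 nm per barcode and folds into a ~176 nm-radius
domain inside the confinement sphere. At zero noise the contact rule marks
exactly the closest 30% of enhancer–promoter distances ON; at 50% label
noise half the cells get coin-flip labels, so the ON fraction moves to
0.5·0.5 + 0.5·0.3 = 0.40. The hierarchical rule's contact threshold is
calibrated (198 nm here) so its expected ON fraction matches the same 0.30
class balance.

The remaining examples each demonstrate one capability end-to-end and
print what the numbers mean: `02_train_and_evaluate.py` (CNN vs baselines,
AUC against the 0.719 noise ceiling, odds ratios),
`03_blanking_analysis.py` (predictability profile dipping at monomers 20
and 40), `04_shap_aggregation.py` (top-decile attribution maps peaking at
the planted enhancer–promoter and silencer–promoter entries) and
`05_cooperativity.py` (cooperative vs independent enhancer wiring).

A thin CLI wraps the same pipeline for shell use:

```bash
tracenet run-all --config experiment.yaml
tracenet blank --config experiment.yaml --window-size 5
tracenet report runs/experiment
```

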