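# Methods

`lncpi` predicts lncRNA–protein interactions (LPIs) from sequence alone.
The pipeline has five stages: descriptor encoding, AdaBoost-based forward
feature selection, min–max scaling, three base classifiers, and a fixed
weighted blend. This note records the model, its tunables, the synthetic
world used for validation, and the numerical choices.

## Data model

An LPI dataset is a triple: nucleotide sequences for lncRNAs, amino-acid
sequences for proteins, and a binary bipartite matrix `Y` with
`y_ij = 1` for a known interaction. Zero entries are unlabeled;
presumed negatives are drawn uniformly from them at a 1:1 ratio to
positives, freshly per experiment repeat. Sequence text is canonicalized
on input: uppercase, `U→T` for nucleotides, characters outside the
declared alphabet dropped with a logged count.

## Descriptor encoding

Each lncRNA maps to a 14,891-dimensional vector from 13 families:

| family | dimension | definition |
|---|---|---|
| zCurve | 3 | (A+G)−(C+T), (A+C)−(G+T), (A+T)−(G+C) on letter totals |
| gcContent | 1 | (G+C)/len |
| atgcRatio | 1 | (A+T)/(G+C) |
| cumulativeSkew | 2 | (G−C)/(G+C), (A−T)/(A+T) |
| pseudoKNC | 84 | counts of all t-mers, t = 1..3 |
| {mono,di,tri}×{Mono,Di,Tri}KGap (7 families) | 80–5120 each | counts of head a-mer + g wildcards + tail b-mer, g = 1..5 |

Each protein maps to 10,420 dimensions: pseudoKNC over the 20 amino
acids (8,420) plus monoMonoKGap (400 × 5 = 2,000). A pair is the
concatenation, 25,311 columns (`lnc:` block then `prot:` block). All
k-mer/k-gap features are raw counts; scaling happens only after
selection, so the selection stumps see untouched counts. Any 0/0 ratio
is defined as 0 to avoid NaN propagation. Column order is canonical
(families in fixed alphabetical order; within a family gap ascending,
then head, then tail lexicographic), which makes selection tie-breaks
reproducible.

## Feature selection

Forward selection runs `k` rounds of AdaBoost with depth-1 threshold
stumps as weak learners. Round t fits, for every remaining feature, the
stump minimizing the weighted error ε under current sample weights `D`
(candidate thresholds are midpoints between consecutive distinct sorted
values plus ±∞ sentinels), moves the minimum-ε feature into the
selected list, assigns it β = ½·ln((1−ε)/ε), and reweights samples
(correct ×e^−β, wrong ×e^+β, renormalized to Σ D = 1). Weights persist
across rounds, so later features are chosen to repair earlier mistakes.

Numerics: ε is clamped to [1e−10, 1−1e−10] before the log-odds so a
perfect stump gets a large finite β. The vectorized round kernel uses
the identity err₊(k) = W(+1) − Σ_{i≤k} (D·y) over the sorted order and
picks the split maximizing |err₊ − ½| (covers both polarities in one
pass); the winning column is then re-fit exactly. Ties are broken
deterministically: smaller threshold, then polarity +1, then lower
canonical column index; equivalent predictors whose errors differ only
by rounding are merged with a 1e−12 tolerance.

`k` defaults to 500 and is always logged; the desk-scale experiments in
this repository use k = 50 (the selection budget matters and is
reported with every run). Selection runs on training folds only.

## Classifiers

* **DNN** — fully connected ReLU network (default hidden sizes 256, 64),
  single sigmoid output, binary cross-entropy, Adam (lr 1e−4, batch 128,
  ≤100 epochs), inverted dropout 0.25 on hidden activations, early stop
  once full-pass training accuracy ≥ 0.99. Implemented in numpy;
  deterministic given its seed.
* **GBT** — gradient-boosted trees under logistic loss
  (scikit-learn engine): learning rate 0.1, 100 trees, depth 6, 80%
  feature subsampling, seeded 10% validation split for early stopping
  (patience 10). The defining second-order formulas — leaf weight
  w* = −Σg/(Σh+λ) and split gain
  ½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ)] − γ — are
  exposed as `gbt_leaf_weight` / `gbt_split_gain` and verified against
  direct evaluation.
* **C-SVM** — soft-margin RBF SVM (C = 1, gamma = 1/k) on features
  standardized with training statistics (zero-variance columns map
  to 0); probability outputs via the solver's Platt-style calibration.

Scores from all three live in [0, 1]. The final score is the fixed
convex blend 0.4·p_DNN + 0.3·p_GBT + 0.3·p_SVM; no meta-learner is
fitted. Hard labels use a strict 0.5 threshold (stated for the DNN,
extended to the ensemble as a configurable decision rule).

## Evaluation

Four 5-fold cross-validation schemes: CV_lp hides random pairs; CV_l /
CV_p hide whole lncRNAs / proteins (cold start on one side); CV_ind
draws 20% of lncRNAs *and* 20% of proteins as a node test set per fold,
trains only on train-node×train-node pairs, tests only on
test-node×test-node pairs, and discards cross pairs entirely (its folds
are deliberately not a partition). Metrics: precision, recall,
accuracy, F1, AUC, AUPR. AUC is the tie-aware rank probability; AUPR
integrates the precision–recall curve by the trapezoid rule on recall —
a fixed, documented convention (slightly different from step-wise
average precision). Precision/F1 are 0 when nothing is predicted
positive. The driver averages over repeats × folds (default 20 repeats)
and also reports per-repeat means; folds that end up single-class on
either side (possible for cold-start schemes on small data) are skipped
with a log message. All randomness derives from one master seed via
`SeedSequence` spawning.

## Synthetic world

The generator plants ground truth: each of R = 2 rules is a
(nucleotide motif, peptide motif) pair; 75% of each entity set carries
the motif of one randomly assigned rule, embedded by overwriting at a
random position (lengths fixed). A pair interacts iff some rule's two
motifs both occur in the respective sequences — decided by scanning, so
chance motif hits in background sequence count too. Each matrix entry
is then flipped independently with probability 0.05. Defaults: 60
lncRNAs × 200 nt, 30 proteins × 120 aa, motifs of length 8 (nt) and 5
(aa), uniform background composition (a GC-bias knob exists).

Why carrier fraction 0.75: symmetric entry flips at rate q on a matrix
of clean density d produce spurious positives at rate q(1−d) against
true positives d(1−q), so sparse worlds drown in label noise. At
d ≈ 0.28 (carrier fraction 0.75, two rules: density ≈ 2·(0.75/2)² plus
chance hits) the best achievable ranking — score = the clean rule
indicator — has AUC ≈ 0.93, leaving headroom for the pipeline's ≥ 0.9
end-to-end check; at carrier fraction 0.4 the same ceiling is ≈ 0.82
and no classifier could pass. The resulting density is comparable to
the smaller curated LPI networks in the literature. This choice was
made once, on this analysis, and is not tuned per run.

What a green synthetic run does establish: the encoders expose
motif-derived signal, selection finds it among 25k columns, the
classifiers and blend convert it into ranking performance, and the CV
schemes do not leak. What it does not establish: performance on real
lncRNA/protein data, whose composition, length distributions,
homology structure and network topology the generator deliberately
does not mimic.

## Known limitations

* The DNN is trained with Adam at lr 1e−4 for at most 100 epochs; on
  desk-scale folds (a few hundred rows, 2–7 minibatches per epoch) it
  is the weakest of the three base classifiers, and the blend leans on
  the tree and kernel models. On larger datasets the same settings take
  many more optimizer steps per epoch.
* `SVC(probability=True)` calibration is unreliable below a few dozen
  samples per class (a libsvm quirk); with `probability=False` the
  package falls back to a sigmoid of the decision function.
* The AUPR convention (trapezoid on recall) can differ from step-wise
  average precision by a few points on small test sets; comparisons
  across tools should use one convention consistently.
* Negative sampling treats all zero entries as candidate negatives,
  including any true-but-unobserved interactions.
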