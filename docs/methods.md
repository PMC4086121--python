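# Methods

## The problem and the model

Neuropeptides (NPs) are short secreted peptides (typically 5–30 aa)
excised from longer neuropeptide precursors (NPPs) by proteolysis at
basic-residue motifs. An NPP has a recognisable architecture: an
N-terminal signal peptide (SP, ~25 aa hydrophobic core) directing it
into the secretory pathway, followed by several peptide units flanked
by dibasic (KK, KR, RK, RR) or tribasic cleavage sites recognised by
prohormone convertases. Individual NPs within and across families
share little sequence similarity, so homology search alone recovers
few precursors; `neuropid` instead learns the statistical signature of
the architecture from sequence-derived features.

A sequence is mapped to a fixed 560-dimensional descriptor vector and
scored by four supervised models. A sequence is called a candidate
precursor when **at least one** model's probability strictly exceeds
that model's threshold; positive calls are then ranked and filtered by
the Internal Score, a cleavage-motif density statistic.

## Feature catalog (560 = 20 + 400 + 140)

* **Composition (20)** — residue frequencies, alphabetical order; sums
  to 1.
* **Bigrams (400)** — overlapping ordered-pair frequencies over the
  20×20 alphabet, normalised by L−1 so the group sums to 1 (all zeros
  for L = 1). Normalising rather than using raw counts removes the
  length confound inside the group; length is its own descriptor.
* **Physicochemical/statistical (140)** — a versioned catalog
  (`npid-560-v1`): global scalars (length, molecular weight,
  isoelectric point, GRAVY, instability index, aromaticity, net charge
  at pH 7, reduced molar extinction, Shannon entropy of composition,
  maximal basic and hydrophobic run lengths, Chou–Fasman-style
  secondary-structure fractions); seven statistics of a Kyte–Doolittle
  hydropathy profile (window 9, or the full sequence when shorter);
  eight residue-class fractions (charged, polar, hydrophobic, aromatic,
  tiny, small, basic, acidic); sixteen basic-site statistics — K/R
  counts and per-100-residue densities, single/dibasic/tribasic counts
  with full-length and post-SP-trim densities, the Internal Score,
  mean motif spacing, motif count in the first 25 residues; N- and
  C-terminal 25-residue window compositions (20 + 20) and six terminal
  scalars; and 49 reduced-alphabet bigram frequencies over a 7-class
  partition (small AGST / aliphatic ILMV / aromatic FWY / basic KRH /
  acidic DE / polar-amide NQC / proline).

No published enumeration of an exact 140-descriptor set exists for
this problem, so the catalog is this package's own reconstruction of
the described categories, completed to exactly 140 and frozen under a
version string. Trained bundles record the version and refuse vectors
built under any other, so train/predict feature order cannot drift.
Degenerate inputs are handled, not rejected: terminal windows shorter
than 25 aa use the available prefix/suffix; bigram groups are zero for
single residues; the instability index is reported as 0 for L = 1
(it is defined over dipeptides).

## Motif scanning and the Internal Score

Maximal runs of {K,R} are classified by length: 1 → single basic site,
2 → one dibasic motif, ≥3 → one tribasic motif. A run is reported once
at its start and never decomposed into overlapping sub-motifs, so
reported sites are disjoint and each counts one cleavage opportunity;
a run of four or more still counts as one tribasic motif (the
alternative ⌊run/2⌋ was rejected for simplicity and testability).

The Internal Score is

    IS = 100 × (n_dibasic + n_tribasic) / max(L − 25, 1)

where 25 aa is the typical SP length trimmed from the denominator.
Defaults, both exposed as switches on `motif_scan.annotate`: motifs in
the first 25 residues **are** counted in the numerator (only the
denominator is trimmed), and the numerator counts motif events, not
basic residues. The floor of 1 prevents division by zero for
sequences ≤ 25 aa; such records carry a `below_sp_length` flag.

## Classifier stack

Four scikit-learn models trained on identical feature order:

| slot | estimator | threshold |
|---|---|---|
| random_forest | RandomForestClassifier, 200 trees, balanced class weights | 0.8 |
| gradient_boosting | GradientBoostingClassifier, 150 trees, depth 3, `max_features="sqrt"` | 0.99 |
| linear_svm | StandardScaler → LinearSVC, sigmoid-calibrated (3-fold Platt) | 0.8 |
| minimal_tree | ExtraTreesClassifier on the top-20 features | 0.8 |

Thresholds are strict inequalities (probability > cutoff); the overall
call is the OR of the four per-model calls. The linear SVM is
calibrated because the thresholding contract needs probabilities, not
margins. The minimal-tree feature subset is the top k = 20 features by
extra-trees impurity importance (k exposed); during cross-validation
the subset is re-selected inside each training fold so held-out
metrics are leakage-free, and the shipped subset is selected on all
data. Gradient boosting subsamples features per split
(`max_features="sqrt"`) — with 560 partially redundant descriptors
this loses essentially nothing and keeps 6-fold CV on ~400×560
matrices to seconds. All hyperparameters are overridable through
`train(model_params=...)`.

Training runs stratified 6-fold cross-validation (shuffled, seeded),
computes held-out confusion counts at a 0.5 probability cut plus the
Mann–Whitney AUC per fold, averages metrics across folds (counts are
summed), then refits each model on all data. Class imbalance is
handled by class weighting, not resampling. Every source of
randomness flows from the single integer training seed stored in the
bundle; the bundle persists as a directory of joblib models plus a
plain-text JSON manifest so thresholds, seed and the minimal feature
subset are auditable without deserialising anything.

`confusion_metrics` implements the standard formulas — accuracy,
precision, recall, and MCC with the convention MCC = 0 when any
denominator factor is 0; undefined precision (TP+FP = 0) is reported
as 0 with an explicit flag. `auc` is the Mann–Whitney pair-ranking
formulation with mid-ranks for ties.

## Pipeline

`pipeline.run` validates records (removing and counting those with
non-canonical residues such as B, X, U, Z), optionally filters by
signal-peptide presence, scores survivors with all four models,
annotates motifs, and sorts by IS descending with ties broken by
maximum model probability then input order. `high_quality` means a
positive overall call with IS ≥ the threshold (default 2.0%, always
echoed in output; there is no canonical published value, so the
default is explicitly this package's own). Raising the threshold can
only shrink the high-quality set. Exit code 0 is returned even when
zero positives are found; nonzero is reserved for errors.

The built-in SP heuristic flags a sequence when some 7-residue window,
starting after the initiator Met and lying within the first 25
residues, has mean Kyte–Doolittle hydropathy ≥ 1.0. It is a
hydrophobic-core screen only — no cleavage-site model, no evolutionary
information — and is documented as NOT equivalent to a dedicated SP
predictor. A dedicated external predictor can be plugged in via a
command template (`{fasta}` placeholder) whose short-format output
(`id Y|N` per line) is parsed strictly: a missing executable, nonzero
exit, unparseable line or missing id aborts the run rather than
silently proceeding unfiltered. By default SP-filtered sequences are
excluded from scoring entirely; `score_filtered=True` scores them with
the SP call recorded.

## Synthetic data

The generator emits the architecture the classifier assumes, so
training, evaluation and the full pipeline are testable without any
download. Positives: an SP-like segment (Met, one or two basics, a
hydrophobic core, polar fill; 25 aa) — spacer — n repeat units (3–8 by
default, each 5–30 aa of background composition) each followed by a
flank motif drawn from {KK 0.30, KR 0.30, RK 0.15, RR 0.15, tribasic
0.10} — tail. Segment boundary residues are forced non-basic so every
planted flank is a maximal run of exactly its own length, making the
planted ground truth a subset of the scanner's output (spontaneous
background motifs may add sites; a `sanitized` mode suppresses them
for oracle tests). Every planted flank is emitted to a BED-like TSV.

Negatives come in three flavours: `uniform-background` (1/20 per
residue), `globular-like` (average well-characterised-protein
composition, hard-coded constants), and `nuclear-like` — K/R doubled
overall but basic runs of ≥2 rejection-sampled away: basic-rich yet
motif-poor, the deliberately hard negative class. The default
training negative set pools nuclear-like and globular-like halves,
reflecting training against several independent negative classes.

What the generator does **not** emulate: real NP family composition
biases, homology between precursors, amidation signals, non-canonical
(monobasic or absent) cleavage, and annotation noise. Passing tests
therefore demonstrate that the machinery recovers a planted
architecture signal under realistic composition, not that the stated
accuracies transfer to real proteomes; published headline accuracies
for this problem were obtained on curated database sequences that are
not redistributable here, and are out of scope.

## Problem sizes and numerical choices

The default study conditions used by the test suite and the
reproduction script are 200 positives vs 200 pooled negatives for
training (6-fold CV) and a fresh-seed 200+200 held-out set — sizes at
which the synthetic classes are cleanly separable and a full run
completes in well under a minute on one CPU. Group-sum invariants are
asserted to 1e−9. Sorting is stable and total, so reruns of the same
input and bundle are byte-identical. Feature histograms rescale each
set by its own standard deviation about the pooled mean (the query
marker uses the positive set's scale); a zero-variance set is an
error naming the set. Histogram bin count defaults to Sturges' rule.

## Known limitations

* The physchem catalog is a faithful reconstruction of described
  categories, not a bit-match of any historical tool; trained bundles
  are tied to the catalog version.
* The SP heuristic is a coarse stand-alone screen; for real proteome
  filtering plug in a dedicated predictor via the external adapter.
* The IS rewards canonical dibasic/tribasic processing only;
  precursors cleaved at non-canonical sites rank low by design, so
  browsing all positive predictions (not only high-quality ones)
  is advisable on real data.
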