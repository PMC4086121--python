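# neuropid

Machine-learning identification of **neuropeptide precursors (NPPs)**
from protein sequence.

Neuropeptides are short secreted peptides (typically 5–30 aa) cut out
of longer precursor proteins by proteolysis at basic-residue motifs.
Mature peptides share almost no sequence similarity within or across
families, so homology search recovers few precursors from unannotated
genomes, transcriptomes or mass-spectrometry data. What *is* conserved
is the precursor architecture: an N-terminal signal peptide (~25 aa
hydrophobic core) and multiple peptide units flanked by dibasic
(KK/KR/RK/RR) or tribasic cleavage sites. `neuropid` learns that
statistical signature. It is for anyone screening protein sets —
predicted proteomes, ORF sets, peptidomics hit lists — for candidate
precursors and secreted peptide modulators.

## Method in brief

Each validated sequence (20-letter alphabet; records with B, X, U, Z
or other non-canonical residues are removed and reported) is mapped to
a fixed vector of **560 features**: 20 amino-acid composition
frequencies, 400 overlapping bigram frequencies, and 140
physicochemical/statistical descriptors (GRAVY, instability index,
isoelectric point, net charge, hydropathy-profile statistics,
basic-motif densities, terminal-window compositions, reduced-alphabet
bigrams, ...). Four supervised models score the vector — a random
forest, gradient boosting, a Platt-calibrated linear SVM, and a
"minimal tree" restricted to the 20 most discriminative features — and
a sequence is called positive when at least one model's probability
strictly exceeds its threshold (0.8 for three models, 0.99 for
gradient boosting). Standard evaluation applies:

    Accuracy = (TP+TN)/(TP+FP+TN+FN)   Precision = TP/(TP+FP)
    Recall   = TP/(TP+FN)              MCC, AUC (Mann–Whitney)

Positive calls are ranked by the **Internal Score**

    IS = 100 × (n_dibasic + n_tribasic) / max(L − 25, 1)

the density of cleavage motifs per effective length (length minus a
typical signal-peptide length of 25 aa). Calls with IS above a
threshold (default 2.0%) form the high-quality list. An optional
signal-peptide filter (built-in hydrophobic-core heuristic, or any
external predictor via a command template) removes non-secreted
sequences first.

A built-in generator emits synthetic precursors with the full
architecture (SP, repeat units, planted flank motifs with ground
truth) and matched negative classes, so the whole pipeline is
trainable and testable without any external download. See
`docs/methods.md` for the model, parameter and generator details.

## Worked example

Generate labeled synthetic sets, train, and predict:

```bash
neuropid synth --n-pos 100 --n-neg 100 --seed 7 --out data
neuropid train --pos data/positive.fasta --neg data/negative.fasta --seed 7 --out model
neuropid predict --fasta data/positive.fasta --model model --sp heuristic --out predictions
```

which prints:

```
100 positives, 100 negatives -> data
model bundle written to model
random_forest: CV accuracy=1.000 precision=1.000 recall=1.000 MCC=1.000 AUC=1.000
gradient_boosting: CV accuracy=1.000 precision=1.000 recall=1.000 MCC=1.000 AUC=1.000
linear_svm: CV accuracy=1.000 precision=1.000 recall=1.000 MCC=1.000 AUC=1.000
minimal_tree: CV accuracy=1.000 precision=1.000 recall=1.000 MCC=1.000 AUC=1.000
input=100 removed=0 sp_filtered=0 positive=100 negative=0 high_quality=100 (IS >= 2.0%)
```

The training lines are 6-fold cross-validation metrics per model —
the synthetic classes are cleanly separable by construction, so all
four reach perfect scores. The prediction line is the run summary:
of 100 input sequences none were removed as invalid, none lacked a
predicted signal peptide, all 100 were called positive, and all 100
cleared the Internal Score threshold of 2.0%. `predictions/` then
holds the ranked `detailed.tsv` (per-model probabilities and calls,
overall call, IS, high-quality flag; sorted by IS descending), the
`high_quality.tsv` subset, a `summary.tsv` including the agreement
histogram (how many models agree per sequence), and
`positive.fasta` for forwarding to downstream cleavage-prediction
tools. The top row of `detailed.tsv`, e.g.

```
pos_7_0074  0.995  1.000  0.997  1.000  True True True True  True  4  8.43  True  True
```

is a sequence all four models agree on, with 8.43 di/tribasic motifs
per 100 effective residues. `neuropid features` exports the 560-column
feature matrix, and `neuropid report` writes per-sequence SVG graphics
with dibasic/tribasic motifs in red and single basic residues in green.

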