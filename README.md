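# proteus

Per-residue prediction of **protean segments** — the parts of an
intrinsically disordered protein region (IDPR) that undergo a
disorder-to-order transition when they bind a partner — from sequence-derived
features alone.

Intrinsically disordered proteins lack a stable tertiary structure in
isolation, yet many of their binding regions (also catalogued as MoRFs,
molecular recognition features) fold upon binding. Identifying those
segments per residue is a heavily imbalanced classification problem: in a
typical curated corpus only ~2% of residues are protean, so a random
classifier has ~1.9% precision and any useful predictor must be measured
against that baseline.

## Method

Each residue is described by **342 features in seven groups**, most averaged
over a 15-residue window centred on the residue:

| group | name | features | count |
|---|---|---|---|
| 1 | amino-acid mutability (scaled PSSM window) | 1–300 | 20 × 15 |
| 2 | conservation (window-mean PSSM information) | 301 | 1 |
| 3 | amino-acid concentration in the window | 302–321 | 20 |
| 4 | physicochemical properties (polarity 4, charge 3, Kyte–Doolittle hydropathy, residue mass) | 322–330 | 9 |
| 5 | predicted secondary-structure probabilities (H, E, C) | 331–333 | 3 |
| 6 | predicted disorder: window mean + disordered/ordered segment length and relative boundaries | 334–340 | 7 |
| 7 | disorder topography: peak/valley/neither class and topographic run length | 341–342 | 2 |

Raw PSSM scores are min–max scaled to [0, 1] per amino acid on the training
corpus. The disorder topography classifies a residue as part of a *peak* if
residues scoring at least 10% lower exist on both sides (a *valley* with the
inequalities reversed) and records the length of the contiguous same-class
run.

A random forest (500 trees, depth 13) votes per residue; the score is the
fraction of trees voting protean and a residue is called protean when the
score reaches `p_cut = 0.5` (ties positive). Evaluation uses precision
(PPV), recall (TPR), F1 and the Matthews correlation coefficient (MCC),
micro-averaged over residues pooled across **cluster-grouped 5-fold
cross-validation** — all members of a sequence-similarity cluster (30%
identity over 50% coverage) share a fold, so homologs never straddle
train/test.

The package also implements the accompanying sequence-consensus analyses:
amino-acid propensities per residue class, secondary-structure content
fractions, and the **Altscore** (secondary-structure transitions per residue
of a segment — a measure of "indecisiveness" in adopting any single
secondary structure).

External predictors (PSI-BLAST, PSIPRED, DISOPRED-class disorder
predictors, BLASTclust) are *not* run by this package: their output files
are parsed as inputs, and a self-contained synthetic-corpus generator
(`proteus.synthetic_fixtures`) emulates their statistical structure so the
whole pipeline runs and is testable offline.

## Worked example

```bash
proteus make-fixtures --n 200 --seed 1 --out-dir corpus/
proteus cv --corpus-dir corpus/ --out-dir cv_out/ --trees 100 --seed 1
```

The generator reports `wrote 200 proteins (2.32% protean residues)`; the
`cv` command prints (to stderr) and writes `cv_out/metrics.json`:

```
INFO cross-validated MCC 0.2133 F1 0.0889 PR-AUC 0.7584
```

with `metrics.json` containing the pooled out-of-fold confusion counts and

```json
"tp": 43, "fp": 0, "fn": 881,
"ppv": 1.0, "tpr": 0.0465, "f1": 0.0889, "mcc": 0.2133,
"pr_auc": 0.7584, "baseline_precision": 0.0232
```

Read: 2.3% of residues are protean, so 0.023 is the random-precision
floor and the out-of-fold recall–precision AUC of ~0.76 sits far above it.
The hard majority-vote cutoff of 0.5 is conservative on so imbalanced a
corpus — only 43 residues clear it (all correctly, hence PPV 1.0 and low
recall); lowering `--pcut` trades precision for recall along the PR curve.
(Numbers vary with the corpus seed and forest size; real proteins are far
harder than this generator.)

The prediction track (`oof_scores.tsv`) is a TSV with columns
`protein_id  position  residue  proteus_score  call` — the score is the
fraction of trees voting protean, the call applies the 0.5 cutoff.

File formats: FASTA; PSI-BLAST ASCII PSSM; PSIPRED VFORMAT `.ss2`;
DISOPRED-style `.diso` (4-column or 2-column); labels as
`protein_id  start  end` TSV (1-based inclusive); clusters as
one-cluster-per-line member lists; fold assignments as `protein_id  fold`.

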