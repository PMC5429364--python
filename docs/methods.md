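# Methods

## Problem and model

A protean segment is a stretch of an intrinsically disordered region that
folds upon binding a partner. The predictor treats this as per-residue
binary classification: residue `i` of a protein is positive iff it lies in
an annotated protean interval. Inputs per protein are the amino-acid
sequence plus three externally produced tracks — a PSI-BLAST ASCII PSSM
(L×20 log-odds + per-position information), PSIPRED-style three-state
secondary-structure probabilities, and a per-residue disorder probability
in [0, 1]. This package never runs those external tools; it parses their
files and, for self-contained operation, generates statistically analogous
tracks synthetically.

The classifier is a random forest (scikit-learn backend) with the operating
point fixed at depth 13, 500 trees (50 for the exhaustive feature-group
search, scaled further to 10 in this package's test/acceptance runs), and
probability cutoff `p_cut = 0.5`. The per-residue score is the fraction of
trees whose individual (hard) vote is positive — not the forest's averaged
class probability — and a tie at the cutoff is called positive. All other
forest hyperparameters are the library defaults, pinned into the trained
model's metadata (`criterion`, `max_features`, `bootstrap`). No class
re-weighting is applied despite the ~2% positive rate; a `class_weight`
hook exists but is off by default.

## Features (342 per residue)

Groups and column ranges (1-based): mutability 1–300, conservation 301,
concentration 302–321, properties 322–330, secondary structure 331–333,
predicted disorder 334–340, disorder topography 341–342.

Window policy: all averaged groups (2–6 window mean) use a **truncated**
window at the termini — the divisor is the number of in-sequence positions
— so terminal residues are not biased toward zero. Group 1, which
concatenates the 20 scaled PSSM values at each of the 15 window offsets,
needs fixed dimensionality and **zero-pads** offsets that fall outside the
sequence. The window size is configurable (odd, 9–21, default 15; the
default matches the centre of the protean segment-length distribution).
With a narrower window the matrix keeps its 342-column layout and the
absent outer offsets of group 1 become structurally zero columns.

PSSM scaling: per amino-acid column min–max over the *training* corpus,
`(v − min)/(max − min)`, clamped to [0, 1] at prediction time; a degenerate
column (min = max) maps to 0.5, the uninformative midpoint. The log-odds
block of the PSSM (not the weighted-percentage block) feeds group 1; this
is the standard choice and is configurable in the parser.

Composition and property fractions use the count of standard residues in
the window as denominator; ambiguity codes (X/B/Z/U/J/O) contribute zero
counts and are excluded from denominators, while their PSSM/SS/disorder
rows are used as-is. Property classes: non-polar {A,V,L,I,M,F,W,P,G}, polar
{S,T,C,Y,N,Q}, acidic-polar {D,E}, basic-polar {K,R,H}; charge positive
{K,R,H}, negative {D,E}, neutral otherwise. Histidine's placement in the
basic/positive classes follows the common textbook partition; sources
differ, and the tables live in one module (`_aa_tables`) should a user want
the alternative. Hydropathy is the Kyte–Doolittle index and mass the
average residue mass in Da, both left on their natural scales — tree
ensembles are scale-invariant.

Group 6: the windowed disorder mean, then the (length, start, stop) of the
maximal contiguous disordered run (score ≥ 0.5) containing the residue if
the residue is disordered, else of the ordered run (< 0.5); the triplet for
the other state is zero, so exactly one triplet is nonzero per residue.
Boundaries are reported as 1-based positions divided by L
(`segment_position_mode="position"`); the alternative reading — distance
from the current residue to each boundary over L — is implemented and
switchable (`"distance"`), since the two readings are both defensible and
differ only in parameterisation, not information content. The ≥ 0.5
disordered convention is likewise switchable.

Group 7: a residue is part of a peak (class +1) if on both sides some
residue scores at least 10% lower, a valley (−1) if both sides hold a
residue at least 10% higher, else 0. "10%" is interpreted
**multiplicatively** (≤ 0.9·s, ≥ 1.1·s); an absolute-offset mode
(`delta_mode="absolute"`) is provided. The search extends to the termini; a
terminus with no residues on one side fails that side's condition, so
terminal residues are class 0, and a residue satisfying both definitions
(possible only at score 0 in relative mode) is classed as peak. The second
feature is the length of the maximal contiguous run sharing the residue's
class, 0 for class 0. The implementation is O(L) via prefix extrema and is
tested against a literal O(L²) double-loop oracle.

## Cross-validation

Sequences are clustered (30% identity over 50% of the shorter sequence is
the reference convention); clusters — not proteins — are dealt to 5 folds,
largest cluster first, each to the currently smallest fold by protein
count, with deterministic ties by cluster id. Cluster files from an
external clustering tool are first-class input; the built-in
`greedy_cluster` fallback links sequences by gapless k-mer-seeded diagonal
identity under single linkage and is an approximation, not a re-creation of
the reference tool. Per rotation, the PSSM scaler is refitted on the
training split only, so test-protein extremes clamp rather than stretch the
scale. Metrics are micro-averaged over residues pooled across the five
rotations.

## Consensus analyses

Propensity of amino acid X in class c:
`Pr(X) = (N_c(X)/N_c) / (N_full(X)/N_full)`. The package treats the class
frequency as count-over-class-total; an alternative normalisation dividing
the class count by the full-corpus total is selectable
(`denominator="printed"`) but makes a near-total class's baseline collapse
to its corpus share instead of ~1, which contradicts the baseline-≈1
behaviour expected of a propensity, so the proper ratio is the default.
The identity `Σ_X f_full(X)·Pr(X) = 1` is enforced by a property test.

Altscore of a segment = (number of adjacent unequal secondary-structure
call pairs) / segment length; a `length−1` denominator is switchable. The
distribution comparison drops zero-Altscore and pure-coil segments and
histograms the rest on a fixed [0, 1] grid with bin width 0.025 — fine
enough to resolve peaks separated by 0.05, which is the scale of interest.

## Synthetic corpus generator

The generator's defaults are the study conditions for every test and for
`scripts/acceptance.py`: 200 proteins of 100–300 residues, ~40% of each
protein disordered, protean segments only inside disordered regions with a
log-normal length (mode ≈ 15, clipped to 5–60) carried by ~25% of proteins
— together giving ~2% positive residues. Ordered regions draw from a
globular amino-acid background; disordered regions are enriched in
P, G, S, D, E, K, R and depleted in large hydrophobics and C; protean
segments re-enrich L, I, F, Y, W (strongly — the rarer the residue, the
larger the multiplier, so that corpus-level propensities recover the
configured direction well above sampling noise at desk-scale corpus sizes)
and D, E, K, R, and deplete P, G, C. The disorder track plateaus at 0.8
over disordered regions and 0.2 elsewhere with a cosine valley of depth
0.25 over each protean segment (so it never crosses 0.5 inside a disordered
region) plus ±0.05 uniform noise. Secondary structure comes from a
three-state switching process; its state distribution is redrawn at region
boundaries so each region sits at its configured composition (disordered:
85% coil), and the switch rate is higher inside protean segments (0.25 vs
0.08), planting the Altscore separation. Pseudo-PSSM rows are integers
peaked on the true residue; information is lower in disordered regions.
15% of proteins are 10%-mutated copies of earlier ones, providing real
sequence families for cluster-grouped CV. Values written to disk are
rounded (PSSM integers, info 2 dp, probabilities 3 dp) and the in-memory
corpus stores the rounded values, so the disk round trip is exact.

A second, purpose-built corpus (`generate_topography_corpus`) isolates
feature group 7: the disorder track stays ≥ 0.5 everywhere (making the
group-6 segment descriptors per-protein constants), all valleys share one
depth and are wider than the 15-residue window (saturating the windowed
mean identically inside them), and only the valley *width* differs between
the protean valley (18–24) and two narrow decoys (15–16). Narrow decoys
make the topography class impure, so the topographic run length is the one
cleanly separating feature — by construction. Inter-valley spacing keeps
peak-class runs well above the protean width range.

What the generator does **not** emulate: realistic PSI-BLAST score
distributions, correlated errors across tracks, annotation noise, or real
protean biology. Passing the recovery tests demonstrates that the feature
arithmetic, fold construction, training loop and analyses do what they
claim on data with known structure — not that the predictor attains any
particular performance on real proteins, which requires the real external
tracks and corpora.

## Problem sizes and numerical choices

Test and acceptance runs scale the study down: cross-validation uses the
200-protein reference corpus with 100 trees; the exhaustive 127-subset
group search runs at 10 trees on a 15-protein corpus (structure check) and
a 40-protein topography corpus (recovery check); consensus analyses use a
400-protein corpus for stable frequency estimates; oracle checks use 1000
random tracks of length ≤ 200. Determinism is exact: a fixed seed fixes the
corpus, fold assignment, forest and therefore every score byte. The
recall–precision AUC is a trapezoid over recall on the attainable upper
envelope (equal-recall points collapsed to their best precision, flat
extension to recall 0); zero-call thresholds contribute points with
precision 0 by the global zero-denominator convention (ppv/tpr/f1 → 0,
MCC → 0 on an empty marginal).

## Known limitations

- The greedy fallback clusterer is gapless and k-mer seeded; distant
  homologs with many indels may escape it. Supply a real cluster file for
  serious use.
- Feature extraction is dense; a full-scale corpus (~1400 proteins, ~870k
  residues × 342 features) fits in a few GB but the per-tree hard-vote
  scoring is O(trees × residues) per prediction pass.
- The segment-boundary features follow one of two defensible readings (see
  above); models trained under one mode are not comparable to the other.
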