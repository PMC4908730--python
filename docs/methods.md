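# Methods

This note documents the models, algorithms, defaults and numerical choices
in `proinflam`, and what the synthetic-data experiments do and do not show.

## Problem and data model

The classifier separates proinflammatory epitopes (peptides assayed positive
for IL1α, IL1β, TNFα, IL12, IL18 or IL23) from non-proinflammatory epitopes,
using only the amino-acid sequence. Peptides are strings over the 20
standard residues; prediction enforces lengths of 4–30 residues (the range
of curated epitope data), while the protein-scan tool windows longer
sequences down to that range. Ambiguity codes (B, J, O, U, X, Z) are
rejected rather than coerced: the composition formulas assume the 20-letter
alphabet. Lowercase input is uppercased silently.

## Feature encodings

* **AAC** (20): per-residue percentages, alphabetical order, summing to 100.
* **DPC** (400): percentages of the `L − 1` overlapping ordered dipeptides,
  lexicographic order, summing to 100 for `L ≥ 2`. The denominator `L − 1`
  is the standard occurrence-count convention.
* **PHYS** (10): the mean over the peptide of a per-residue scale, one value
  per property, in the fixed order amphipathicity, hydrophobicity, pI,
  bulkiness, hydrophilicity, net-hydrogen, steric hindrance, charge,
  hydropathy, molecular weight.

The PHYS scale table is a deliberate, editable default
(`src/proinflam/data/physchem_scales.tsv`, overridable via
`load_scales(path)`): Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity,
Eisenberg consensus hydrophobicity, Zimmerman bulkiness, free-amino-acid pI,
monoisotopic residue masses, unit formal charges with His at +0.1, and
approximate published values for amphipathicity, net side-chain hydrogen
bonding and steric hindrance. The exact scales behind the original
property-based models are not published; these stand-ins are clearly
substitutes, and the property-based model is the weakest of the three
feature sets in any case.

Features enter the SVM on the raw percent scale, un-standardized, so the
published kernel widths (γ of 0.001–0.005) retain their meaning.

## Compositional comparison

`compare_compositions` applies Welch's unequal-variance two-sample t test to
each residue (AAC) or dipeptide (DPC) percentage, two-sided, on per-peptide
values. Features with zero variance in both groups and equal means are
reported as `t = 0, p = 1`; zero variance with unequal means as `p = 0`.
No multiple-testing correction is applied by default (the comparison is
exploratory and the historical analyses report raw `p < 0.05`);
Benjamini–Hochberg is available via `correction="bh"`.

## Exclusive motif mining

A motif is a token sequence over literal residues, residue-class labels and
single-position wildcards; first and last tokens may not be wildcards.
Defaults: maximum length 9 (the MHC I/II binding-core size) and a total
wildcard budget of 1 per motif — "one wildcard total" was chosen over "one
per adjacency" as the tractable reading of a gap budget of 1; the budget is
a parameter (`gap`).

Class alphabets ship as editable defaults taken from the standard
classification literature: Betts–Russell (hydrophobic ACFGHIKLMTVWY, polar
CDEHKNQRSTWY, small ACDGNPSTV, tiny ACGS, aliphatic ILV, aromatic FHWY,
charged DEHKR, positive HKR, negative DE) and Koolman–Röhm (aliphatic AGILV,
sulfur CM, aromatic FWY, neutral NQST, acidic DE, basic HKR, imino P,
basic_ring H; the label uses an underscore because `-` separates motif
tokens). Classes may overlap. Custom schemes load from two-column TSV.

**Search.** Sequences are represented as per-token 64-bit position masks
(bit *p* = token matches residue *p*), so appending a token to a candidate
is a shift-and; mining therefore handles sequences up to 64 residues, which
covers the peptide scale it is meant for. A depth-first search grows
candidates token by token with two exact prunes:

1. positive coverage is anti-monotone under extension — candidates below
   `min_positive_coverage` are abandoned;
2. a candidate that is already exclusive (zero negative matches) and does
   not end in a wildcard is emitted and never extended, because every
   extension covers a subset of its positives and would be removed by the
   redundancy filter below. (An exclusive candidate that *ends* in a
   wildcard is not a legal motif and is extended instead.)

The inner loop is numba-compiled; a full mining run on 300 + 300 peptides
with the Betts–Russell alphabet takes on the order of a second.

**Non-redundancy.** Among the emitted exclusive motifs, a motif is dropped
when a retained motif of shorter or equal length covers a superset of its
positives. Candidates are processed in order of (length, number of
non-literal tokens, token string), so of two motifs with identical coverage
the shorter — then the more literal, then the lexicographically smaller —
is retained. Results are sorted by positive coverage descending, ties by
motif string. A consequence worth knowing: a planted or expected pattern may
be *represented* by a strictly more general retained motif whose exclusive
coverage is larger (e.g. `positive-hydrophobic-L` subsuming
`K-hydrophobic-L`); recovery guarantees are therefore stated as "some
retained motif covers all carriers", which the redundancy filter provably
preserves.

The miner is validated against exhaustive enumeration on hundreds of random
tiny instances (restricted alphabets, short sequences, motif length ≤ 3),
where the two must agree exactly.

**Support floor.** The modeling pipeline mines with
`min_positive_coverage = max(2, 5% of positives)`: reported exclusive-motif
tables in this literature have their useful motifs covering roughly 7–9% of
the positive class, and a 5% floor keeps the hybrid adjustment driven by
recurrent patterns rather than near-singletons. The exploratory `mine` CLI
uses the looser `max(2, 1%)` so users can see the full candidate list.
Negative-exclusive motifs are obtained by swapping the classes and mining
again.

## Classifier and hybrid score

The SVM is scikit-learn's `SVC` (libsvm) with an RBF kernel;
`class_weight={1: j}` multiplies the error penalty of positive training
examples by the cost factor *j*, reproducing the SVM-light `-j` contract.
Training is deterministic given data and configuration.

The hybrid score adds +1 if the peptide matches *any* positive-exclusive
motif and −1 if it matches *any* negative-exclusive motif — indicators, not
counts. A peptide matching both kinds receives both adjustments (net 0);
this cannot occur on training data (exclusivity) and the additive reading is
the natural composition of the two rules. The decision threshold is applied
to the adjusted (hybrid) score: each published model variant carries one
threshold, which only makes sense post-adjustment. Boundary convention:
`score ≥ threshold` is positive.

Published parameter sets for the six model variants (AAC, DPC, PHYS, and
the three hybrid schemes) are available as `REFERENCE_CONFIGS`; the package
default is the deployed variant (DPC + Betts–Russell motifs, g 0.001, c 8,
j 3, threshold 0.3).

Models persist as a JSON envelope (configuration, motif strings, scheme,
metadata, version tag) embedding a base64 pickle of the fitted classifier;
loading a file with a different version tag fails loudly, and a round trip
reproduces scores bitwise.

## Evaluation

* **Split:** per class, `round(fraction · n)` records (half away from zero)
  drawn uniformly without replacement into validation. This rounding exactly
  reproduces the canonical 729/171 → 583/137 training + 146/34 validation
  arithmetic at 20%.
* **Cross-validation:** stratified k-fold (default 10) — stratification is a
  package choice; with ~10⁲ negatives, unstratified folds risk negative-free
  test sets. Predictions are pooled: each record is scored exactly once by a
  model trained without it, and one report is computed from all n pooled
  scores. With a motif scheme, both motif sets are re-mined inside each
  training fold by default (leakage-free); `motif_mining="global"` mines
  once on the full data first, the simpler historical protocol. Both are
  supported and tested.
* **Metrics:** Sen = 100·TP/(TP+FN), Spec = 100·TN/(TN+FP),
  Acc = 100·(TP+TN)/n, MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
  If an MCC denominator factor is zero, MCC is reported as 0 with an
  explicit `mcc_defined=False` flag (a common convention, made visible).
  An absent class makes Sen or Spec undefined and raises.
* **AUC:** Mann–Whitney form (probability a random positive outscores a
  random negative, ties at half credit), computed from the full ROC sweep;
  equal by construction to brute-force concordant-pair counting, which the
  tests verify independently.

## Screening tools

Coordinates are 1-based inclusive throughout. The protein scan slides a
window (step 1, window within 4–30) and hybrid-scores all `L − w + 1`
windows. Virtual screening rescans all 19 single-residue substitutions per
position, with the original peptide as reference row. Epitope mapping
reports every exact substring occurrence, overlaps included. Similarity
search is affine-gap local alignment (Smith–Waterman–Gotoh) against each
database entry — defaults BLOSUM62, gap open 11, extend 1 (standard protein
values; a gap of length g costs open + (g−1)·extend) — returning the top 10
hits by score with traceback strings. Zero-score pairs are reported with an
empty alignment.

## Synthetic data generator

`generate_dataset` emulates the statistical structure the method exploits,
not any particular assay: peptide lengths uniform on 4–30; negatives drawn
i.i.d. from a background residue distribution (uniform by default, natural
abundances optional); positives from the background plus `enrichment_delta`
of probability mass spread equally over the enriched residues (default
A/F/I/L/V — the aliphatic/hydrophobic preference seen in proinflammatory
epitopes) and removed proportionally from the rest. Planted motifs are
written into a stated fraction of positives at random non-overlapping
positions (class tokens instantiated uniformly), and negatives that
accidentally match any planted pattern are resampled — resampling rather
than trimming preserves class size and length distribution. Everything is
reproducible from the seed.

The standard study conditions (`standard_spec`) are 300 positives, 300
negatives, `delta = 0.15`, and `K-hydrophobic-L` planted in 40% of
positives. `alternate_balanced_dataset` reproduces the balanced-dataset
construction in which sampled decoy peptides top the negative class up to
the positive class size.

**What passing tests show — and don't.** The synthetic positives differ
from negatives in exactly two controlled ways (a global compositional shift
and planted exclusive motifs), with i.i.d. residues otherwise. Real epitope
data have positional structure, length/source biases and label noise that
this null does not model, so synthetic performance numbers characterize the
implementation, not expected accuracy on biological data. Two quantitative
consequences, measured by `scripts/acceptance.py` and the test suite:

* The hybrid model beats or matches the DPC-only model consistently
  (5/5 seeds; ≈ +4–5 accuracy points), reproducing the qualitative ordering
  that motivated the hybrid design.
* Absolute accuracy is bounded by the generator itself. With
  `delta = 0.15` over five residues (0.05 → 0.08 per residue) and mean
  length ≈ 17, the per-peptide composition log-likelihood-ratio separation
  is about `d′ ≈ 0.31·√L ≈ 1.3`, a Bayes accuracy near 73% for the
  composition channel; measured DPC pooled tenfold-CV accuracy is 63–68%
  (AUC 0.73–0.79) across seeds, and neither threshold sweeps nor
  kernel-width changes exceed ≈ 71%. High-80s accuracies as reported on
  curated assay data are therefore not reachable under these synthetic
  conditions, and the corresponding accuracy-floor check in the acceptance
  suite documents this gap rather than a model defect.

## Numerical and degenerate-input choices

* Composition features are exact rationals times 100 in float64; sums are
  asserted to 1e-6.
* Welch test: both-variances-zero handled before calling scipy (equal
  means → p = 1; unequal → p = 0).
* Mining requires sequences ≤ 64 residues (bitmask width) and at least one
  sequence per class; `min_positive_coverage ≥ 1`.
* `split_dataset` raises if a class would be emptied on either side.
* Ties: motif output ordering and the redundancy filter are fully
  deterministic (documented sort keys); Smith–Waterman ties sort by subject
  id; the first-listed optimal traceback is reported.
* Model files refuse to load across format versions rather than guessing.

## Known limitations

* The physicochemical scale table is a documented substitute for
  unpublished originals; PHYS-based results are comparative only.
* Mining complexity grows with broad residue classes; the support floor is
  the practical control. Variable-length gaps and motif p-values are out of
  scope.
* The hybrid adjustment is a hard ±1: motifs mined at low support floors
  can accumulate false positive-motif hits on unseen negatives. Raise the
  floor (or inspect `mine` output) when the motif lists look inflated.
* No probability calibration; decision values are SVM margins, comparable
  only within one model.
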