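# proinflam

Sequence-based prediction of **proinflammatory peptide epitopes** — peptides
that, on presentation to T cells, trigger assays positive for the
proinflammatory cytokines IL1α, IL1β, TNFα, IL12, IL18 or IL23. Whether a
therapeutic peptide or a pathogen antigen initiates this inflammatory cascade
is often the difference between a useful vaccine lead and a harmful
immuno-side-effect, and experimental assays are slow and expensive. This
package provides the computational counterpart: a machine-learning classifier
over amino-acid sequence features, plus the screening tools one needs to
apply it to whole proteins and designed variants.

It is aimed at immunoinformaticians and peptide-therapeutics researchers who
want a scriptable, testable implementation of the classical
composition + exclusive-motif + SVM recipe for epitope classification.

## The method

Every peptide (4–30 residues) is encoded by percent-scale composition
features:

* **AAC** — amino-acid composition, `AAC(i) = 100 · count(i) / L`
  (20 features);
* **DPC** — overlapping dipeptide composition,
  `DPC(ij) = 100 · count(ij) / (L − 1)` (400 features);
* **PHYS** — means of 10 per-residue physicochemical scales
  (amphipathicity, hydrophobicity, pI, bulkiness, hydrophilicity,
  net-hydrogen, steric hindrance, charge, hydropathy, molecular weight).

A soft-margin RBF-kernel SVM with parameters *g* (kernel width), *c*
(error cost) and *j* (positive-class cost factor, the SVM-light `-j`
convention) is trained on labeled peptides. Independently, a motif miner
searches for patterns over literal residues, degenerate residue classes
(Betts–Russell or Koolman–Röhm alphabets) and single-position wildcards that
are **exclusively present** in one class: matched by at least
`min_positive_coverage` peptides of that class and by *zero* peptides of the
other. The deployed **hybrid score** is

```
score(p) = SVM_decision(p) + 1·[p matches any positive-exclusive motif]
                           − 1·[p matches any negative-exclusive motif]
```

and a peptide is called positive when `score ≥ threshold`. The default
configuration is the published deployment model: DPC features,
Betts–Russell motifs, `g = 0.001`, `c = 8`, `j = 3`, threshold 0.3.
Performance is reported by pooled stratified tenfold cross-validation
(sensitivity, specificity, accuracy, MCC, Mann–Whitney AUC), with motifs
re-mined inside each training fold so no held-out peptide leaks into the
motif sets.

Because the curated assay dataset behind the original tool is not
redistributable, the package ships a first-class synthetic generator that
reproduces its statistical structure — A/F/I/L/V-enriched positives and
planted class-exclusive motifs — so every component is testable end to end
(see `docs/methods.md` for what this does and does not demonstrate).

## Worked example

Simulate a labeled dataset, train the hybrid model, and predict two
peptides:

```bash
proinflam simulate --n-pos 300 --n-neg 300 --delta 0.15 \
    --motif "K-hydrophobic-L:0.4" --seed 7 --out train.fasta
proinflam train --input train.fasta --features dpc --scheme betts-russell \
    --g 0.001 --c 8 --j 3 --threshold 0.3 --seed 7 --out model.json
printf ">pep1\nKVLAKWIV\n>pep2\nTSNQGGDE\n" > query.fasta
proinflam predict --model model.json --input query.fasta
```

which prints

```
id      sequence        svm_score       motif_adjustment        hybrid_score    call    error
pep1    KVLAKWIV        0.498   1       1.498   positive
pep2    TSNQGGDE        -0.646  -1      -1.646  negative
```

`pep1` carries the `K-hydrophobic-L` motif (window `KVL`), so its SVM
decision value 0.498 gains the +1 positive-motif weight and the hybrid score
1.498 clears the 0.3 threshold; `pep2` matches a negative-exclusive motif
and loses one unit, confirming the negative call. The other subcommands —
`scan` (sliding-window protein scan), `screen` (all 19 substitutions per
position), `map` (exact epitope localization), `search` (Smith–Waterman
against an epitope database), `mine`, `evaluate`, `compare`, `pipeline` —
follow the same pattern; `proinflam --help` lists them.

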