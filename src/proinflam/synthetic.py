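"""Synthetic labeled peptide datasets with the class structure the predictor
exploits: positives enriched in aliphatic/hydrophobic residues (A, F, I, L,
V by default) and carrying planted class-exclusive motifs that never occur
in negatives.

The generator emulates the *statistical shape* of curated epitope data —
peptide lengths 4-30, a compositional shift between classes, recurrent
sequence patterns private to the positive class — not the biology of any
particular assay. Lengths are uniform on the range; negatives are drawn
from a stated background distribution (uniform over the 20 residues by
default, optionally natural protein abundances); positives add
``enrichment_delta`` of probability mass spread equally over the enriched
residues and removed proportionally from the rest. For each planted motif,
the stated fraction of positives receives one concrete instantiation
(class tokens resolved uniformly) written at a random position, and any
negative that accidentally matches a planted motif is resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .motifs import BETTS_RUSSELL, MotifPattern, matches, parse_motif
from .sequence_io import ALPHABET, PeptideRecord

#: Approximate natural amino-acid abundances (percent, UniProt-scale values).
NATURAL_ABUNDANCE = {
    "A": 8.25, "C": 1.37, "D": 5.45, "E": 6.75, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66,
    "M": 2.42, "N": 4.06, "P": 4.70, "Q": 3.93, "R": 5.53,
    "S": 6.56, "T": 5.34, "V": 6.87, "W": 1.08, "Y": 2.92,
}

_RESAMPLE_CAP = 1000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw."""

    n_pos: int = 300
    n_neg: int = 300
    min_len: int = 4
    max_len: int = 30
    enriched_residues: frozenset[str] = frozenset("AFILV")
    enrichment_delta: float = 0.15
    planted_motifs: tuple[tuple[MotifPattern, float], ...] = ()
    background: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("both class sizes must be positive")
        if not (1 <= self.min_len <= self.max_len):
            raise ConfigError("invalid length range")
        if not set(self.enriched_residues) <= set(ALPHABET):
            raise ConfigError("enriched residues must be standard amino acids")
        if self.background not in ("uniform", "natural"):
            raise ConfigError("background must be 'uniform' or 'natural'")
        for motif, frac in self.planted_motifs:
            if not 0 <= frac <= 1:
                raise ConfigError(f"carrier fraction {frac} outside [0, 1]")
            if len(motif) > self.min_len:
                raise ConfigError(
                    f"planted motif {motif} is longer than the minimum peptide "
                    f"length {self.min_len}"
                )
        bg = self._background_probs()
        rest = 1.0 - sum(bg[ALPHABET.index(r)] for r in self.enriched_residues)
        if self.enrichment_delta < 0 or self.enrichment_delta >= rest:
            raise ConfigError(
                f"enrichment_delta must be in [0, {rest:.3f}) for this background"
            )

    def _background_probs(self) -> np.ndarray:
        if self.background == "uniform":
            return np.full(20, 1.0 / 20)
        p = np.array([NATURAL_ABUNDANCE[a] for a in ALPHABET])
        return p / p.sum()

    def class_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """(positive, negative) residue sampling distributions."""
        bg = self._background_probs()
        pos = bg.copy()
        enriched_idx = [ALPHABET.index(r) for r in sorted(self.enriched_residues)]
        if enriched_idx and self.enrichment_delta > 0:
            mass_e = pos[enriched_idx].sum()
            rest_scale = (1.0 - mass_e - self.enrichment_delta) / (1.0 - mass_e)
            pos *= rest_scale
            pos[enriched_idx] = bg[enriched_idx] + self.enrichment_delta / len(enriched_idx)
        return pos, bg


def standard_spec(seed: int = 0) -> SyntheticSpec:
    """The package's standard study conditions: 300 positives and 300
    negatives, +0.15 enrichment of A/F/I/L/V in positives, and a
    ``K-hydrophobic-L`` motif planted in 40% of positives (Betts–Russell
    classes)."""
    return SyntheticSpec(
        planted_motifs=((parse_motif("K-hydrophobic-L", BETTS_RUSSELL), 0.4),),
        seed=seed,
    )


def _sample_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(ALPHABET[i] for i in idx)


def _instantiate(rng: np.random.Generator, motif: MotifPattern) -> str:
    out = []
    for tok in motif.tokens:
        allowed = motif.scheme.token_set(tok)
        if allowed is None:
            out.append(ALPHABET[rng.integers(20)])
        else:
            members = sorted(allowed)
            out.append(members[rng.integers(len(members))])
    return "".join(out)


def _plant(rng: np.random.Generator, seq: str, motif: MotifPattern,
           occupied: list[tuple[int, int]]) -> tuple[str, tuple[int, int]]:
    k = len(motif)
    for _ in range(200):
        start = int(rng.integers(0, len(seq) - k + 1))
        span = (start, start + k)
        if all(span[1] <= a or span[0] >= b for a, b in occupied):
            inst = _instantiate(rng, motif)
            return seq[: span[0]] + inst + seq[span[1]:], span
    raise ValidationError(
        f"could not place motif {motif} without overlapping earlier plants"
    )


def generate_dataset(spec: SyntheticSpec) -> list[PeptideRecord]:
    """Draw one labeled dataset; fully reproducible under ``spec.seed``.

    Positives come first (ids ``pos_0001`` ...), then negatives
    (``neg_0001`` ...).
    """
    rng = np.random.default_rng(spec.seed)
    p_pos, p_neg = spec.class_probs()
    lengths_pos = rng.integers(spec.min_len, spec.max_len + 1, size=spec.n_pos)
    positives = [
        _sample_sequence(rng, int(L), p_pos) for L in lengths_pos
    ]
    # plant motifs into randomly chosen carriers, non-overlapping per peptide
    spans: list[list[tuple[int, int]]] = [[] for _ in range(spec.n_pos)]
    for motif, frac in spec.planted_motifs:
        n_carriers = int(np.floor(frac * spec.n_pos + 0.5))
        carriers = rng.choice(spec.n_pos, size=n_carriers, replace=False)
        for ci in carriers:
            positives[ci], span = _plant(rng, positives[ci], motif, spans[ci])
            spans[ci].append(span)
    patterns = [m for m, _ in spec.planted_motifs]
    negatives = []
    lengths_neg = rng.integers(spec.min_len, spec.max_len + 1, size=spec.n_neg)
    for L in lengths_neg:
        for attempt in range(_RESAMPLE_CAP):
            seq = _sample_sequence(rng, int(L), p_neg)
            if not any(matches(m, seq) for m in patterns):
                break
        else:
            raise ValidationError(
                "could not sample a negative free of planted motifs; "
                "the motifs are too permissive for the background"
            )
        negatives.append(seq)
    width_p = len(str(spec.n_pos))
    width_n = len(str(spec.n_neg))
    records = [
        PeptideRecord(f"pos_{i + 1:0{width_p}d}", seq, label="positive")
        for i, seq in enumerate(positives)
    ]
    records += [
        PeptideRecord(f"neg_{i + 1:0{width_n}d}", seq, label="negative")
        for i, seq in enumerate(negatives)
    ]
    return records


def planted_carriers(spec: SyntheticSpec, records: Sequence[PeptideRecord],
                     motif: MotifPattern) -> frozenset[str]:
    """Ids of positive records matching a planted motif (carriers plus any
    accidental matches)."""
    return frozenset(
        r.id for r in records if r.label == "positive" and matches(motif, r)
    )


def alternate_balanced_dataset(
    positives: Sequence[PeptideRecord],
    negatives: Sequence[PeptideRecord],
    decoys: Sequence[PeptideRecord],
    seed: int = 0,
) -> list[PeptideRecord]:
    """Balance the classes by topping up negatives with sampled decoys.

    Decoys (e.g. non-T-cell epitopes) are relabeled negative and drawn
    uniformly without replacement until the negative class equals the
    positive class in size. All original negatives are kept.
    """
    need = len(positives) - len(negatives)
    if need < 0:
        raise ValidationError("negatives already outnumber positives")
    if need > len(decoys):
        raise ValidationError(
            f"need {need} decoys to balance but only {len(decoys)} provided"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = sorted(rng.choice(len(decoys), size=need, replace=False).tolist())
    chosen = [replace(decoys[i], label="negative") for i in chosen_idx]
    out = list(positives) + list(negatives) + chosen
    ids = [r.id for r in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("record ids must be unique across the merged dataset")
    return out
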