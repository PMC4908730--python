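"""Exclusive-motif discovery over literal and degenerate residue alphabets.

A motif is an ordered list of tokens, each of which is a literal residue
(uppercase letter), a residue-class label (lowercase word such as
``hydrophobic``), or a single-position wildcard (``.``). A motif matches a
sequence when some contiguous window satisfies every token. Mining finds all
motifs that match at least ``min_positive_coverage`` positive sequences and
**zero** negative sequences ("class-exclusive" motifs), up to a maximum
length (default 9, the MHC binding-core size) and a wildcard budget
(default 1), and then removes redundant motifs: a motif is dropped when a
retained motif of shorter or equal length already covers a superset of its
positives (the more specific pattern — fewer class/wildcard tokens, then
lexicographically smaller — wins ties).

Two degenerate alphabets ship as editable defaults, following the standard
amino-acid classification literature:

* ``betts-russell`` — hydrophobic / polar / small / tiny / aliphatic /
  aromatic / charged / positive / negative;
* ``koolman-rohm`` — aliphatic / sulfur / aromatic / neutral / acidic /
  basic / imino / basic_ring.

``none`` uses literal residues only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._mining import enumerate_exclusive
from .errors import ConfigError, ValidationError
from .sequence_io import ALPHABET, ALPHABET_SET, PeptideRecord

WILDCARD = "."

DEFAULT_MAX_LEN = 9
DEFAULT_GAP = 1

#: Mining with the compiled kernel packs positions into 64-bit masks.
MAX_MINEABLE_LEN = 64


@dataclass(frozen=True, eq=False)
class ResidueClassScheme:
    """A named mapping from class labels to (possibly overlapping) residue sets."""

    name: str
    classes: dict[str, frozenset[str]] = field(default_factory=dict)

    def _key(self):
        return (self.name, tuple(sorted(self.classes.items())))

    def __eq__(self, other):
        if not isinstance(other, ResidueClassScheme):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    def __post_init__(self):
        for label, members in self.classes.items():
            if not label or not label.islower() or len(label) < 2 or "-" in label:
                raise ConfigError(
                    f"class label {label!r} must be a lowercase word of length >= 2 "
                    "without '-'"
                )
            if not members or not set(members) <= ALPHABET_SET:
                raise ConfigError(
                    f"class {label!r} must be a non-empty subset of the 20 residues"
                )

    def token_set(self, token: str) -> frozenset[str] | None:
        """Residues a token accepts; ``None`` means any (wildcard)."""
        if token == WILDCARD:
            return None
        if len(token) == 1 and token in ALPHABET_SET:
            return frozenset(token)
        if token in self.classes:
            return self.classes[token]
        raise ConfigError(f"token {token!r} is not a residue, class of scheme "
                          f"{self.name!r}, or wildcard")


NONE_SCHEME = ResidueClassScheme("none", {})

BETTS_RUSSELL = ResidueClassScheme(
    "betts-russell",
    {
        "hydrophobic": frozenset("ACFGHIKLMTVWY"),
        "polar": frozenset("CDEHKNQRSTWY"),
        "small": frozenset("ACDGNPSTV"),
        "tiny": frozenset("ACGS"),
        "aliphatic": frozenset("ILV"),
        "aromatic": frozenset("FHWY"),
        "charged": frozenset("DEHKR"),
        "positive": frozenset("HKR"),
        "negative": frozenset("DE"),
    },
)

KOOLMAN_ROHM = ResidueClassScheme(
    "koolman-rohm",
    {
        "aliphatic": frozenset("AGILV"),
        "sulfur": frozenset("CM"),
        "aromatic": frozenset("FWY"),
        "neutral": frozenset("NQST"),
        "acidic": frozenset("DE"),
        "basic": frozenset("HKR"),
        "imino": frozenset("P"),
        "basic_ring": frozenset("H"),
    },
)

_BUILTIN = {s.name: s for s in (NONE_SCHEME, BETTS_RUSSELL, KOOLMAN_ROHM)}


def get_scheme(name: str) -> ResidueClassScheme:
    """Look up a built-in scheme by name (``none``, ``betts-russell``, ``koolman-rohm``)."""
    try:
        return _BUILTIN[name.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown scheme {name!r}; built-ins are {sorted(_BUILTIN)}"
        ) from None


def load_scheme(path: str | Path, name: str | None = None) -> ResidueClassScheme:
    """Load a scheme from a two-column TSV (class label, residue string)."""
    classes = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigError(f"bad scheme line {line!r}: expected 2 columns")
            classes[parts[0]] = frozenset(parts[1].upper())
    return ResidueClassScheme(name or Path(path).stem, classes)


def save_scheme(scheme: ResidueClassScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in sorted(scheme.classes):
            fh.write(f"{label}\t{''.join(sorted(scheme.classes[label]))}\n")


@dataclass(frozen=True)
class MotifPattern:
    """An ordered token pattern over a residue-class scheme.

    String form joins tokens with ``-`` (e.g. ``K-hydrophobic-L``); the
    wildcard token is ``.``. First and last tokens may not be wildcards.
    """

    tokens: tuple[str, ...]
    scheme: ResidueClassScheme = NONE_SCHEME

    def __post_init__(self):
        if not self.tokens:
            raise ConfigError("motif must have at least one token")
        if self.tokens[0] == WILDCARD or self.tokens[-1] == WILDCARD:
            raise ConfigError("motif may not start or end with a wildcard")
        for tok in self.tokens:
            self.scheme.token_set(tok)  # raises ConfigError on unknown tokens

    def __str__(self) -> str:
        return "-".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_degenerate(self) -> int:
        """Number of non-literal tokens (class labels and wildcards)."""
        return sum(1 for t in self.tokens if len(t) > 1 or t == WILDCARD)


def parse_motif(text: str, scheme: ResidueClassScheme = NONE_SCHEME) -> MotifPattern:
    """Parse the ``-``-joined string form back into a :class:`MotifPattern`."""
    tokens = tuple(tok.strip() for tok in text.split("-"))
    if any(not tok for tok in tokens):
        raise ConfigError(f"empty token in motif string {text!r}")
    return MotifPattern(tokens, scheme)


def matches(motif: MotifPattern, sequence: str | PeptideRecord) -> bool:
    """True iff some contiguous window of the sequence satisfies every token."""
    seq = sequence.sequence if isinstance(sequence, PeptideRecord) else sequence
    k = len(motif.tokens)
    sets = [motif.scheme.token_set(t) for t in motif.tokens]
    for start in range(len(seq) - k + 1):
        ok = True
        for j, allowed in enumerate(sets):
            if allowed is not None and seq[start + j] not in allowed:
                ok = False
                break
        if ok:
            return True
    return False


@dataclass(frozen=True)
class MotifReport:
    """A mined motif with its class coverage on the training data."""

    motif: MotifPattern
    positive_coverage: int
    negative_coverage: int
    covered_ids: frozenset[str]


def _token_list(scheme: ResidueClassScheme) -> list[str]:
    return list(ALPHABET) + sorted(scheme.classes) + [WILDCARD]


def _token_masks(tokens: Sequence[str], scheme: ResidueClassScheme,
                 sequences: Sequence[str]) -> np.ndarray:
    """Bitmask per (token, sequence): bit p set iff token matches position p."""
    masks = np.zeros((len(tokens), len(sequences)), dtype=np.uint64)
    for ti, tok in enumerate(tokens):
        allowed = scheme.token_set(tok)
        for si, seq in enumerate(sequences):
            m = 0
            for p, ch in enumerate(seq):
                if allowed is None or ch in allowed:
                    m |= 1 << p
            masks[ti, si] = m
    return masks


def _coverage_bits(token_ids: tuple[int, ...], tok_masks: np.ndarray) -> int:
    """Covered-sequence set of a motif as a Python int bitmask."""
    cur = tok_masks[token_ids[0]].copy()
    for t in token_ids[1:]:
        cur = (cur << np.uint64(1)) & tok_masks[t]
    bits = 0
    for i in np.flatnonzero(cur):
        bits |= 1 << int(i)
    return bits


def _nonredundant(cands: list[tuple[tuple[int, ...], int]],
                  tokens: list[str]) -> list[tuple[tuple[int, ...], int]]:
    """Drop motifs whose positive cover is a subset of a retained motif's.

    Only a retained motif of shorter or equal length can subsume. Processing
    order (length, degeneracy, lexicographic tokens) makes the more specific
    of two equally-covering motifs the retained one.
    """
    def degeneracy(ids):
        return sum(1 for t in ids if len(tokens[t]) > 1 or tokens[t] == WILDCARD)

    order = sorted(
        cands, key=lambda c: (len(c[0]), degeneracy(c[0]),
                              tuple(tokens[t] for t in c[0]))
    )
    retained: list[tuple[tuple[int, ...], int]] = []
    for ids, cov in order:
        subsumed = any(
            len(r_ids) <= len(ids) and cov | r_cov == r_cov
            for r_ids, r_cov in retained
        )
        if not subsumed:
            retained.append((ids, cov))
    return retained


def mine_exclusive_motifs(
    positives: Sequence[PeptideRecord],
    negatives: Sequence[PeptideRecord],
    scheme: ResidueClassScheme = NONE_SCHEME,
    max_len: int = DEFAULT_MAX_LEN,
    gap: int = DEFAULT_GAP,
    min_positive_coverage: int = 1,
) -> list[MotifReport]:
    """Mine all non-redundant motifs exclusive to the positive class.

    Returns motifs matching at least ``min_positive_coverage`` positives and
    no negative, sorted by positive coverage descending (ties broken by the
    motif string). ``gap`` is the total wildcard budget per motif.
    """
    if not positives or not negatives:
        raise ValidationError("both classes must be non-empty for mining")
    if min_positive_coverage < 1:
        raise ValidationError("min_positive_coverage must be >= 1")
    for r in list(positives) + list(negatives):
        if len(r.sequence) > MAX_MINEABLE_LEN:
            raise ValidationError(
                f"sequence {r.id!r} is longer than {MAX_MINEABLE_LEN} residues; "
                "mining operates on peptide-scale sequences"
            )
    tokens = _token_list(scheme)
    if len(tokens) <= 1:
        raise ConfigError("empty candidate alphabet")
    pos_seqs = [r.sequence for r in positives]
    neg_seqs = [r.sequence for r in negatives]
    pos_tok = _token_masks(tokens, scheme, pos_seqs)
    neg_tok = _token_masks(tokens, scheme, neg_seqs)
    wild = tokens.index(WILDCARD)
    raw = enumerate_exclusive(
        pos_tok, neg_tok, wild, int(min_positive_coverage), int(max_len), int(gap)
    )
    cands = [(ids, _coverage_bits(ids, pos_tok)) for ids in raw]
    kept = _nonredundant(cands, tokens)
    reports = []
    for ids, covbits in kept:
        motif = MotifPattern(tuple(tokens[t] for t in ids), scheme)
        covered = frozenset(
            positives[i].id for i in range(len(positives)) if covbits >> i & 1
        )
        reports.append(MotifReport(motif, len(covered), 0, covered))
    reports.sort(key=lambda r: (-r.positive_coverage, str(r.motif)))
    return reports


def union_coverage(reports: Iterable[MotifReport],
                   sequences: Sequence[PeptideRecord]) -> int:
    """Number of unique sequences matched by at least one motif."""
    covered: set[str] = set()
    for rep in reports:
        for rec in sequences:
            if rec.id not in covered and matches(rep.motif, rec):
                covered.add(rec.id)
    return len(covered)


def write_motif_reports(reports: Sequence[MotifReport], path: str | Path) -> None:
    """Motif reports as TSV (motif string, coverages, covered ids)."""
    from .sequence_io import write_table

    rows = [
        {
            "motif": str(r.motif),
            "positive_coverage": r.positive_coverage,
            "negative_coverage": r.negative_coverage,
            "covered_ids": ",".join(sorted(r.covered_ids)),
        }
        for r in reports
    ]
    write_table(rows, path, format="tsv")
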