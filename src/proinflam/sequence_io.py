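"""FASTA and tabular I/O plus peptide validation.

Peptides are plain strings over the 20 standard amino-acid letters. Class
labels (``positive`` / ``negative``) travel in FASTA headers as a
``|label=...`` suffix so that labeled training sets round-trip through a
single file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, FastaParseError, LengthError, ValidationError

#: The 20 standard amino acids in alphabetical one-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

#: Default peptide length bounds applied at prediction time.
MIN_PEPTIDE_LEN = 4
MAX_PEPTIDE_LEN = 30

_LABELS = ("positive", "negative")
_LABEL_TAG = "label="


@dataclass(frozen=True)
class PeptideRecord:
    """One FASTA entry: identifier, validated sequence, optional class label.

    The sequence is uppercased on construction and must be non-empty over
    the standard alphabet. ``description`` keeps any header text after the
    first whitespace.
    """

    id: str
    sequence: str
    label: str | None = None
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"empty sequence for record {self.id!r}")
        for ch in self.sequence:
            if ch not in ALPHABET_SET:
                raise AlphabetError(self.id, ch)
        if self.label is not None and self.label not in _LABELS:
            raise ValidationError(
                f"label for {self.id!r} must be one of {_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def validate_peptide(
    sequence: str, min_len: int = MIN_PEPTIDE_LEN, max_len: int = MAX_PEPTIDE_LEN
) -> str:
    """Return the uppercased sequence iff alphabet-valid and within bounds.

    Raises :class:`AlphabetError` for a non-standard residue and
    :class:`LengthError` when the length falls outside ``[min_len, max_len]``.
    Idempotent on accepted inputs.
    """
    seq = sequence.upper()
    for ch in seq:
        if ch not in ALPHABET_SET:
            raise AlphabetError(sequence, ch)
    if not (min_len <= len(seq) <= max_len):
        raise LengthError(sequence, len(seq), min_len, max_len)
    return seq


def _check_fasta_shape(path: Path) -> None:
    # Biopython's FASTA reader is lenient; pre-scan so that syntax errors
    # carry a line number as promised by this module's contract.
    with open(path) as fh:
        seen_header = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError("empty FASTA header", line=lineno)
                seen_header = True
            elif not seen_header:
                raise FastaParseError(
                    "sequence data before the first '>' header", line=lineno
                )


def _split_header(rec: SeqRecord) -> tuple[str, str, str | None]:
    ident = rec.id
    desc = rec.description
    if desc.startswith(ident):
        desc = desc[len(ident):].strip()
    label = None
    parts = []
    for tok in desc.split("|"):
        tok = tok.strip()
        if tok.startswith(_LABEL_TAG):
            label = tok[len(_LABEL_TAG):]
        elif tok:
            parts.append(tok)
    return ident, "|".join(parts), label


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read a FASTA file into a list of :class:`PeptideRecord`.

    Sequences are uppercased and whitespace-stripped; entry order is
    preserved. Headers are split at the first whitespace; a ``|label=``
    token in the description sets the class label. Duplicate ids raise
    :class:`ValidationError`; malformed syntax raises
    :class:`FastaParseError` with the line number.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        ident, desc, label = _split_header(rec)
        if ident in seen:
            raise ValidationError(f"duplicate record id {ident!r} in {path}")
        seen.add(ident)
        records.append(
            PeptideRecord(id=ident, sequence=str(rec.seq), label=label, description=desc)
        )
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records to FASTA, encoding labels as ``|label=...``."""
    out = []
    for r in records:
        desc = r.description
        if r.label is not None:
            desc = (desc + " " if desc else "") + f"|{_LABEL_TAG}{r.label}"
        out.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")


def write_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
    float_precision: int = 3,
) -> None:
    """Write result records as TSV or JSON with deterministic column order.

    Column order follows the first row's key order (or the DataFrame's
    columns); floats are rendered with ``float_precision`` decimals. Empty
    input yields a header-only TSV / an empty JSON array.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        columns = list(rows[0].keys()) if rows else []
        frame = pd.DataFrame(rows, columns=columns)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}f")
    elif format == "json":
        def _coerce(v):
            if isinstance(v, float):
                return round(v, float_precision)
            if hasattr(v, "item"):  # numpy scalar
                return _coerce(v.item())
            return v

        payload = [
            {k: _coerce(v) for k, v in rec.items()}
            for rec in frame.to_dict(orient="records")
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValidationError(f"unknown table format {format!r}; use 'tsv' or 'json'")


def split_by_label(records: Sequence[PeptideRecord]) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Split a labeled dataset into (positives, negatives).

    Raises :class:`ValidationError` if any record is unlabeled.
    """
    pos, neg = [], []
    for r in records:
        if r.label == "positive":
            pos.append(r)
        elif r.label == "negative":
            neg.append(r)
        else:
            raise ValidationError(f"record {r.id!r} has no class label")
    return pos, neg
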