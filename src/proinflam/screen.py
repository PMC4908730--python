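"""Downstream screening tools: protein scan, virtual mutagenesis, epitope
mapping, and Smith–Waterman similarity search.

All coordinates are 1-based inclusive. The protein scan slides a window of
the chosen peptide length (step 1) across a protein and scores every window
with the hybrid model; virtual screening rescoring every single-residue
substitution of a peptide; epitope mapping reports exact substring
occurrences of database epitopes in a query; similarity search runs
affine-gap local alignment (Smith–Waterman–Gotoh) of the query against every
database entry. A gap of length ``g`` is penalized ``open + (g - 1) * extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .model import TrainedModel, classify, hybrid_score, hybrid_scores
from .sequence_io import (
    ALPHABET,
    MAX_PEPTIDE_LEN,
    MIN_PEPTIDE_LEN,
    PeptideRecord,
    validate_peptide,
)


@dataclass(frozen=True)
class WindowPrediction:
    """One scored window of a protein scan (1-based inclusive coordinates)."""

    start: int
    end: int
    sequence: str
    svm_score: float
    motif_adjustment: int
    score: float
    call: str


def protein_scan(
    protein: str,
    window: int,
    model: TrainedModel,
    threshold: float | None = None,
) -> list[WindowPrediction]:
    """Score every length-``window`` peptide of the protein, step 1.

    Returns ``L - window + 1`` predictions in order of start position.
    """
    seq = validate_peptide(protein, min_len=1, max_len=10**9)
    if not (MIN_PEPTIDE_LEN <= window <= MAX_PEPTIDE_LEN):
        raise ValidationError(
            f"window {window} outside peptide bounds "
            f"{MIN_PEPTIDE_LEN}-{MAX_PEPTIDE_LEN}"
        )
    if window > len(seq):
        raise ValidationError(
            f"window {window} longer than protein (length {len(seq)})"
        )
    thr = model.config.threshold if threshold is None else threshold
    windows = [seq[i : i + window] for i in range(len(seq) - window + 1)]
    preds = []
    for i, hs in enumerate(hybrid_scores(model, windows)):
        preds.append(
            WindowPrediction(
                start=i + 1,
                end=i + window,
                sequence=windows[i],
                svm_score=hs.base,
                motif_adjustment=hs.adjustment,
                score=hs.score,
                call=classify(hs.score, thr),
            )
        )
    return preds


def virtual_screen(
    peptide: str,
    model: TrainedModel,
    threshold: float | None = None,
) -> list[dict]:
    """Positional saturation mutagenesis: rescore all 19 substitutions per position.

    The original peptide appears first as the reference row (position 0);
    variant rows are ordered by position then substituted residue. Variants
    identical to the original are excluded ("the other 19").
    """
    seq = validate_peptide(peptide)
    thr = model.config.threshold if threshold is None else threshold
    variants: list[tuple[int, str, str, str]] = [(0, "-", "-", seq)]
    for pos in range(len(seq)):
        for res in ALPHABET:
            if res == seq[pos]:
                continue
            variants.append(
                (pos + 1, seq[pos], res, seq[:pos] + res + seq[pos + 1 :])
            )
    rows = []
    for (pos, wt, mut, var), hs in zip(
        variants, hybrid_scores(model, [v[3] for v in variants])
    ):
        rows.append(
            {
                "position": pos,
                "wildtype": wt,
                "substitution": mut,
                "sequence": var,
                "svm_score": hs.base,
                "motif_adjustment": hs.adjustment,
                "score": hs.score,
                "call": classify(hs.score, thr),
            }
        )
    return rows


@dataclass(frozen=True)
class EpitopeHit:
    """An exact occurrence of a database epitope in the query (1-based)."""

    epitope_id: str
    start: int
    end: int


def map_epitopes(query: str, epitope_db: Sequence[PeptideRecord]) -> list[EpitopeHit]:
    """All exact substring occurrences of each database epitope in the query.

    Overlapping and repeated occurrences are all reported, ordered by
    database order then position.
    """
    seq = validate_peptide(query, min_len=1, max_len=10**9)
    hits = []
    for rec in epitope_db:
        start = seq.find(rec.sequence)
        while start != -1:
            hits.append(EpitopeHit(rec.id, start + 1, start + len(rec.sequence)))
            start = seq.find(rec.sequence, start + 1)
    return hits


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment of the query against one database entry.

    ``query_aln`` and ``subject_aln`` are equal-length gapped segments;
    coordinates are 1-based inclusive. A hit with score 0 carries an empty
    alignment (coordinates 0).
    """

    query_id: str
    subject_id: str
    score: float
    query_aln: str
    subject_aln: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int


def identity_matrix(match: float = 2.0, mismatch: float = -1.0):
    """A simple identity substitution matrix over the 20 residues."""
    m = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            m[a, b] = match if a == b else mismatch
    return m


def load_matrix(matrix) -> substitution_matrices.Array:
    if isinstance(matrix, substitution_matrices.Array):
        return matrix
    if isinstance(matrix, str):
        if matrix.lower() == "identity":
            return identity_matrix()
        return substitution_matrices.load(matrix.upper())
    raise ValidationError(f"cannot interpret substitution matrix {matrix!r}")


def _aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ValidationError("gap penalties must be positive")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_matrix(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _gapped_strings(alignment) -> tuple[str, str, int, int, int, int]:
    qseq, sseq = alignment.sequences
    coords = alignment.coordinates
    q_parts, s_parts = [], []
    for col in range(coords.shape[1] - 1):
        q0, q1 = int(coords[0, col]), int(coords[0, col + 1])
        s0, s1 = int(coords[1, col]), int(coords[1, col + 1])
        dq, ds = q1 - q0, s1 - s0
        if dq and ds:
            q_parts.append(qseq[q0:q1])
            s_parts.append(sseq[s0:s1])
        elif dq:
            q_parts.append(qseq[q0:q1])
            s_parts.append("-" * dq)
        else:
            q_parts.append("-" * ds)
            s_parts.append(sseq[s0:s1])
    return (
        "".join(q_parts),
        "".join(s_parts),
        int(coords[0, 0]) + 1,
        int(coords[0, -1]),
        int(coords[1, 0]) + 1,
        int(coords[1, -1]),
    )


def smith_waterman(
    query: str,
    epitope_db: Sequence[PeptideRecord],
    matrix="BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    top_n: int = 10,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Affine-gap local alignment of the query against every database entry.

    Hits are sorted by score descending (ties by subject id) and the top
    ``top_n`` are returned with traceback strings.
    """
    qseq = validate_peptide(query, min_len=1, max_len=10**9)
    aligner = _aligner(matrix, gap_open, gap_extend)
    scored = sorted(
        ((float(aligner.score(qseq, rec.sequence)), rec) for rec in epitope_db),
        key=lambda t: (-t[0], t[1].id),
    )
    hits = []
    for score, rec in scored[:top_n]:
        if score <= 0:
            hits.append(
                AlignmentHit(query_id, rec.id, 0.0, "", "", 0, 0, 0, 0)
            )
            continue
        aln = aligner.align(qseq, rec.sequence)[0]
        q_aln, s_aln, qs, qe, ss, se = _gapped_strings(aln)
        hits.append(
            AlignmentHit(query_id, rec.id, score, q_aln, s_aln, qs, qe, ss, se)
        )
    return hits


def format_alignment(hit: AlignmentHit) -> str:
    """Plain-text pairwise block for one alignment hit."""
    if not hit.query_aln:
        return (
            f"# {hit.query_id} vs {hit.subject_id} score={hit.score:g}\n"
            "(no alignment)\n"
        )
    midline = "".join(
        "|" if a == b and a != "-" else " "
        for a, b in zip(hit.query_aln, hit.subject_aln)
    )
    return (
        f"# {hit.query_id} vs {hit.subject_id} score={hit.score:g}\n"
        f"query   {hit.query_start:>4} {hit.query_aln} {hit.query_end}\n"
        f"             {midline}\n"
        f"subject {hit.subject_start:>4} {hit.subject_aln} {hit.subject_end}\n"
    )
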