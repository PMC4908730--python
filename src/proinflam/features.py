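"""Sequence feature encodings and class-composition comparison.

Three fixed-order encodings are provided:

* **AAC** — amino-acid composition: 20 percentages summing to 100.
* **DPC** — dipeptide composition over the overlapping ordered pairs of a
  sequence: 400 percentages (denominator ``L - 1``) summing to 100.
* **PHYS** — ten physicochemical properties (amphipathicity, hydrophobicity,
  pI, bulkiness, hydrophilicity, net-hydrogen, steric hindrance, charge,
  hydropathy, molecular weight), each the mean of a per-residue scale over
  the peptide. The default scale table ships with the package as an editable
  TSV; the values are standard published scales (Kyte–Doolittle hydropathy,
  Hopp–Woods hydrophilicity, Eisenberg consensus hydrophobicity, Zimmerman
  bulkiness, monoisotopic residue masses, and a simple unit-charge model
  with His at +0.1).

Compositions are reported in percent (0–100) and enter downstream models on
that scale, un-standardized, so that small RBF gamma values remain
meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .sequence_io import ALPHABET, PeptideRecord, validate_peptide

FeatureKind = Literal["AAC", "DPC", "PHYS"]

AAC_NAMES: tuple[str, ...] = tuple(ALPHABET)
DPC_NAMES: tuple[str, ...] = tuple(a + b for a in ALPHABET for b in ALPHABET)
#: Property order of the PHYS encoding (also the scale-table column order).
PHYS_NAMES: tuple[str, ...] = (
    "amphipathicity",
    "hydrophobicity",
    "pI",
    "bulkiness",
    "hydrophilicity",
    "net_hydrogen",
    "steric_hindrance",
    "charge",
    "hydropathy",
    "molecular_weight",
)

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate(ALPHABET):
    _CODE[ord(_ch)] = _i


def _encode(sequence: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        validate_peptide(sequence, min_len=1, max_len=10**9)  # raises AlphabetError
    return codes


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-order numeric encoding of one peptide."""

    kind: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValidationError("feature names and values disagree in length")


def aac(sequence: str | PeptideRecord) -> FeatureVector:
    """Amino-acid composition in percent; alphabetical A..Y order."""
    seq = sequence.sequence if isinstance(sequence, PeptideRecord) else sequence
    if not seq:
        raise ValidationError("cannot compute AAC of an empty sequence")
    codes = _encode(seq)
    counts = np.bincount(codes, minlength=20).astype(float)
    return FeatureVector("AAC", AAC_NAMES, 100.0 * counts / len(seq))


def dpc(sequence: str | PeptideRecord) -> FeatureVector:
    """Overlapping dipeptide composition in percent; AA..YY lexicographic order."""
    seq = sequence.sequence if isinstance(sequence, PeptideRecord) else sequence
    if len(seq) < 2:
        raise ValidationError(
            f"DPC requires length >= 2, got {len(seq)} for {seq!r}"
        )
    codes = _encode(seq)
    idx = codes[:-1] * 20 + codes[1:]
    counts = np.bincount(idx, minlength=400).astype(float)
    return FeatureVector("DPC", DPC_NAMES, 100.0 * counts / (len(seq) - 1))


def load_scales(path: str | Path | None = None) -> pd.DataFrame:
    """Load a 20x10 physicochemical scale table (residues x properties).

    ``None`` loads the packaged default. The table must cover all 20
    residues and all 10 properties, otherwise :class:`ConfigError`.
    """
    if path is None:
        with resources.files("proinflam.data").joinpath("physchem_scales.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t", index_col="residue")
    else:
        table = pd.read_csv(path, sep="\t", index_col="residue")
    missing_res = sorted(set(ALPHABET) - set(table.index))
    missing_prop = [p for p in PHYS_NAMES if p not in table.columns]
    if missing_res or missing_prop:
        raise ConfigError(
            f"incomplete scale table: missing residues {missing_res}, "
            f"missing properties {missing_prop}"
        )
    table = table.loc[list(ALPHABET), list(PHYS_NAMES)].astype(float)
    if table.isna().any().any():
        raise ConfigError("scale table contains missing values")
    return table


_DEFAULT_SCALES: pd.DataFrame | None = None


def default_scales() -> pd.DataFrame:
    global _DEFAULT_SCALES
    if _DEFAULT_SCALES is None:
        _DEFAULT_SCALES = load_scales(None)
    return _DEFAULT_SCALES


def physchem(
    sequence: str | PeptideRecord, scales: pd.DataFrame | None = None
) -> FeatureVector:
    """Ten physicochemical properties, each the per-residue scale mean."""
    seq = sequence.sequence if isinstance(sequence, PeptideRecord) else sequence
    if not seq:
        raise ValidationError("cannot compute properties of an empty sequence")
    table = default_scales() if scales is None else load_scales_frame(scales)
    codes = _encode(seq)
    mat = table.to_numpy()
    return FeatureVector("PHYS", PHYS_NAMES, mat[codes].mean(axis=0))


def load_scales_frame(scales: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Accept a pre-loaded scale frame or a TSV path, validating coverage."""
    if isinstance(scales, (str, Path)):
        return load_scales(scales)
    missing_res = sorted(set(ALPHABET) - set(scales.index))
    missing_prop = [p for p in PHYS_NAMES if p not in scales.columns]
    if missing_res or missing_prop:
        raise ConfigError(
            f"incomplete scale table: missing residues {missing_res}, "
            f"missing properties {missing_prop}"
        )
    return scales.loc[list(ALPHABET), list(PHYS_NAMES)].astype(float)


_ENCODERS = {"AAC": aac, "DPC": dpc, "PHYS": physchem}


def encode(sequence: str | PeptideRecord, kind: FeatureKind, scales=None) -> FeatureVector:
    """Encode one peptide with the named feature kind."""
    kind = kind.upper()
    if kind not in _ENCODERS:
        raise ConfigError(f"unknown feature kind {kind!r}; use AAC, DPC or PHYS")
    if kind == "PHYS":
        return physchem(sequence, scales=scales)
    return _ENCODERS[kind](sequence)


def feature_matrix(
    peptides: Sequence[str | PeptideRecord], kind: FeatureKind, scales=None
) -> np.ndarray:
    """Stack feature vectors of many peptides into an (n, d) matrix."""
    return np.vstack([encode(p, kind, scales=scales).values for p in peptides])


def feature_names(kind: FeatureKind) -> tuple[str, ...]:
    kind = kind.upper()
    if kind == "AAC":
        return AAC_NAMES
    if kind == "DPC":
        return DPC_NAMES
    if kind == "PHYS":
        return PHYS_NAMES
    raise ConfigError(f"unknown feature kind {kind!r}")


@dataclass(frozen=True)
class CompositionComparison:
    """Welch's t comparison of one composition feature between the classes."""

    feature: str
    mean_pos: float
    mean_neg: float
    t_stat: float
    p_value: float
    significant: bool


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    with warnings.catch_warnings():
        # near-identical groups trigger a precision warning; the degenerate
        # exactly-identical case is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_compositions(
    positives: Sequence[str | PeptideRecord],
    negatives: Sequence[str | PeptideRecord],
    granularity: str = "residue",
    alpha: float = 0.05,
    correction: str = "none",
) -> list[CompositionComparison]:
    """Per-feature Welch's unequal-variance t test between the two classes.

    Compositions are the per-peptide percentages (AAC for ``residue``, DPC
    for ``dipeptide``). Results are sorted by ascending p-value (ties by
    feature label); ``significant`` is ``p < alpha`` on the raw p-values, or
    the Benjamini–Hochberg decision at level ``alpha`` when
    ``correction='bh'``.
    """
    if len(positives) < 2 or len(negatives) < 2:
        raise ValidationError(
            "each class needs at least 2 peptides for a variance estimate"
        )
    if granularity == "residue":
        kind, names = "AAC", AAC_NAMES
    elif granularity == "dipeptide":
        kind, names = "DPC", DPC_NAMES
    else:
        raise ConfigError("granularity must be 'residue' or 'dipeptide'")
    pos = feature_matrix(positives, kind)
    neg = feature_matrix(negatives, kind)
    stats_rows = []
    for j, name in enumerate(names):
        t, p = _welch(pos[:, j], neg[:, j])
        stats_rows.append((name, pos[:, j].mean(), neg[:, j].mean(), t, p))
    pvals = np.array([r[4] for r in stats_rows])
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        sig = dict(zip([r[0] for r in stats_rows], reject))
    elif correction == "none":
        sig = {r[0]: r[4] < alpha for r in stats_rows}
    else:
        raise ConfigError("correction must be 'none' or 'bh'")
    out = [
        CompositionComparison(name, float(mp), float(mn), t, p, bool(sig[name]))
        for name, mp, mn, t, p in stats_rows
    ]
    out.sort(key=lambda c: (c.p_value, c.feature))
    return out
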