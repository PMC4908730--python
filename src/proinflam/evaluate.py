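"""Dataset splitting, pooled k-fold cross-validation, and performance metrics.

Metrics follow the standard confusion-matrix definitions: sensitivity
``100*TP/(TP+FN)``, specificity ``100*TN/(TN+FP)``, accuracy
``100*(TP+TN)/n``, and the Matthews correlation coefficient
``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``. AUC is the
Mann–Whitney probability that a random positive outscores a random negative
(ties credited one half), computed from the full ROC sweep.

Cross-validation is stratified and *pooled*: each record is scored exactly
once by a model trained on the other folds, and one report is computed from
all pooled predictions. When a residue-class scheme is supplied, exclusive
motifs are re-mined inside each training fold by default so that no
held-out record influences the motif sets (``motif_mining='global'``
reproduces the simpler protocol of mining once on the full data before CV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .model import ModelConfig, hybrid_scores, train
from .motifs import ResidueClassScheme, mine_exclusive_motifs
from .sequence_io import PeptideRecord, split_by_label


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    #: False when an MCC denominator factor was zero and 0 was reported.
    mcc_defined: bool = True


@dataclass(frozen=True)
class EvaluationReport:
    threshold: float
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float
    roc_points: tuple[tuple[float, float], ...]
    mcc_defined: bool = True


def metrics(counts: ConfusionCounts) -> ClassMetrics:
    """Sensitivity, specificity, accuracy (percent) and MCC from counts.

    When any MCC denominator factor is zero, MCC is reported as 0 with
    ``mcc_defined=False``. An entirely absent class makes sensitivity or
    specificity undefined and raises :class:`ValidationError`.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if tp + fn == 0:
        raise ValidationError("sensitivity undefined: no positive records")
    if tn + fp == 0:
        raise ValidationError("specificity undefined: no negative records")
    sen = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return ClassMetrics(sen, spec, acc, 0.0, mcc_defined=False)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return ClassMetrics(sen, spec, acc, mcc)


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(
        [1 if lab in (1, "positive") else 0 for lab in labels], dtype=int
    )
    if arr.all() or not arr.any():
        raise ValidationError("both classes must be present")
    return arr


def roc_auc(scores: Sequence[float], labels: Sequence) -> tuple[float, tuple[tuple[float, float], ...]]:
    """AUC (Mann–Whitney, half credit for ties) and the ROC point list."""
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, tuple(zip(fpr.tolist(), tpr.tolist()))


def counts_at_threshold(scores: Sequence[float], labels: Sequence, threshold: float) -> ConfusionCounts:
    y = _as_binary_labels(labels)
    calls = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    tn = int(np.sum(~calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def evaluate_scores(scores: Sequence[float], labels: Sequence, threshold: float) -> EvaluationReport:
    """Full report (counts, threshold metrics, AUC, ROC) for pooled scores."""
    counts = counts_at_threshold(scores, labels, threshold)
    m = metrics(counts)
    auc, points = roc_auc(scores, labels)
    return EvaluationReport(
        threshold=threshold,
        counts=counts,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        accuracy=m.accuracy,
        mcc=m.mcc,
        auc=auc,
        roc_points=points,
        mcc_defined=m.mcc_defined,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    peptides: Sequence[PeptideRecord],
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Per-class random split into (training, validation).

    Exactly ``round(fraction * class size)`` records per class (half away
    from zero) go to validation, drawn uniformly without replacement;
    deterministic under ``seed``. With 729 positives and 171 negatives at
    fraction 0.2 this yields 583/137 training and 146/34 validation.
    """
    if not 0 < validation_fraction < 1:
        raise ValidationError("validation_fraction must be in (0, 1)")
    pos, neg = split_by_label(peptides)
    rng = np.random.default_rng(seed)
    train_set: list[PeptideRecord] = []
    val_set: list[PeptideRecord] = []
    for group in (pos, neg):
        n_val = _round_half_away(validation_fraction * len(group))
        if n_val == 0 or n_val == len(group):
            raise ValidationError(
                f"split empties one side of a class of size {len(group)} "
                f"at fraction {validation_fraction}"
            )
        chosen = set(rng.choice(len(group), size=n_val, replace=False).tolist())
        for i, rec in enumerate(group):
            (val_set if i in chosen else train_set).append(rec)
    return train_set, val_set


@dataclass
class CVResult:
    """Pooled cross-validation predictions plus the summary report."""

    ids: tuple[str, ...]
    scores: np.ndarray
    labels: tuple[str, ...]
    report: EvaluationReport


def default_min_coverage(n_positives: int) -> int:
    """Motif support floor used by the modeling pipeline: 5% of positives.

    The published motif tables report exclusive motifs covering roughly
    7-9% of the positive class; requiring at least 5% support keeps the
    hybrid adjustment driven by recurrent patterns rather than singletons.
    """
    return max(2, round(0.05 * n_positives))


def mine_both_directions(
    positives: Sequence[PeptideRecord],
    negatives: Sequence[PeptideRecord],
    scheme: ResidueClassScheme,
    max_len: int = 9,
    gap: int = 1,
    min_positive_coverage: int | None = None,
):
    """Mine positive-exclusive and negative-exclusive motif sets.

    The second direction simply swaps the classes, mirroring the two-step
    discovery protocol. Returns (positive reports, negative reports).
    """
    min_pos = min_positive_coverage or default_min_coverage(len(positives))
    min_neg = min_positive_coverage or default_min_coverage(len(negatives))
    pos_reports = mine_exclusive_motifs(
        positives, negatives, scheme, max_len=max_len, gap=gap,
        min_positive_coverage=min_pos,
    )
    neg_reports = mine_exclusive_motifs(
        negatives, positives, scheme, max_len=max_len, gap=gap,
        min_positive_coverage=min_neg,
    )
    return pos_reports, neg_reports


def kfold_cv(
    peptides: Sequence[PeptideRecord],
    config: ModelConfig,
    scheme: ResidueClassScheme | None = None,
    k: int = 10,
    seed: int = 0,
    min_positive_coverage: int | None = None,
    motif_mining: str = "per-fold",
    max_len: int = 9,
    gap: int = 1,
    scales=None,
) -> CVResult:
    """Stratified k-fold cross-validation with pooled predictions.

    Per fold the model (and, when ``scheme`` is given, both exclusive motif
    sets) is rebuilt on the k-1 training folds and the held-out fold is
    scored with the hybrid score. All n predictions are pooled into one
    report at ``config.threshold``.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if motif_mining not in ("per-fold", "global"):
        raise ValidationError("motif_mining must be 'per-fold' or 'global'")
    peptides = list(peptides)
    pos, neg = split_by_label(peptides)
    if len(pos) < k or len(neg) < k:
        raise ValidationError(
            f"each class needs at least k={k} members for stratified folds"
        )
    y = np.array([1 if r.label == "positive" else 0 for r in peptides])
    global_motifs = None
    if scheme is not None and motif_mining == "global":
        global_motifs = mine_both_directions(
            pos, neg, scheme, max_len=max_len, gap=gap,
            min_positive_coverage=min_positive_coverage,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(peptides)
    pooled_scores = np.full(n, np.nan)
    for train_idx, test_idx in skf.split(np.zeros(n), y):
        fold_train = [peptides[i] for i in train_idx]
        fold_test = [peptides[i] for i in test_idx]
        if scheme is None:
            pos_motifs, neg_motifs = (), ()
        elif global_motifs is not None:
            pos_motifs = tuple(r.motif for r in global_motifs[0])
            neg_motifs = tuple(r.motif for r in global_motifs[1])
        else:
            ftr_pos, ftr_neg = split_by_label(fold_train)
            rep_pos, rep_neg = mine_both_directions(
                ftr_pos, ftr_neg, scheme, max_len=max_len, gap=gap,
                min_positive_coverage=min_positive_coverage,
            )
            pos_motifs = tuple(r.motif for r in rep_pos)
            neg_motifs = tuple(r.motif for r in rep_neg)
        mdl = train(
            fold_train, config, seed=seed,
            positive_motifs=pos_motifs, negative_motifs=neg_motifs,
            scheme=scheme, scales=scales,
        )
        for i, hs in zip(test_idx, hybrid_scores(mdl, fold_test)):
            pooled_scores[i] = hs.score
    assert not np.isnan(pooled_scores).any()
    labels = tuple(r.label for r in peptides)
    report = evaluate_scores(pooled_scores, labels, config.threshold)
    return CVResult(
        ids=tuple(r.id for r in peptides),
        scores=pooled_scores,
        labels=labels,
        report=report,
    )


def threshold_sweep(
    scores: Sequence[float], labels: Sequence, thresholds: Sequence[float]
) -> list[EvaluationReport]:
    """One evaluation report per threshold over the same pooled scores."""
    return [evaluate_scores(scores, labels, t) for t in thresholds]


def reports_to_rows(reports: Sequence[EvaluationReport]) -> list[dict]:
    """Flatten reports for tabular output (threshold, Sen, Spec, Acc, MCC, AUC)."""
    return [
        {
            "threshold": r.threshold,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "accuracy": r.accuracy,
            "mcc": r.mcc,
            "auc": r.auc,
            "TP": r.counts.TP,
            "FP": r.counts.FP,
            "TN": r.counts.TN,
            "FN": r.counts.FN,
        }
        for r in reports
    ]
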