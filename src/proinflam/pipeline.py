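"""End-to-end model development pipeline.

Mirrors the development workflow of the prediction tool: split the labeled
data into training and validation, mine both exclusive motif sets on the
training data, train the hybrid SVM, evaluate by pooled tenfold
cross-validation on the training set and once on the held-out validation
set, and persist the deployable model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluate import (
    CVResult,
    EvaluationReport,
    evaluate_scores,
    kfold_cv,
    mine_both_directions,
    reports_to_rows,
)
from .model import (
    DEFAULT_CONFIG,
    ModelConfig,
    TrainedModel,
    hybrid_scores,
    save_model,
    train,
)
from .evaluate import split_dataset
from .motifs import BETTS_RUSSELL, ResidueClassScheme
from .sequence_io import PeptideRecord, split_by_label, write_table

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    model: TrainedModel
    cv: CVResult
    validation_report: EvaluationReport
    training_set: list[PeptideRecord]
    validation_set: list[PeptideRecord]


def end_to_end(
    peptides: Sequence[PeptideRecord],
    config: ModelConfig = DEFAULT_CONFIG,
    scheme: ResidueClassScheme | None = BETTS_RUSSELL,
    k: int = 10,
    seed: int = 0,
    validation_fraction: float = 0.2,
    min_positive_coverage: int | None = None,
    motif_mining: str = "per-fold",
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run split -> motif mining -> training -> CV -> validation -> persist.

    When ``outdir`` is given, writes ``model.json``, ``cv_report.tsv`` and
    ``validation_report.tsv`` there.
    """
    log.info(
        "pipeline: %d records, features=%s scheme=%s k=%d seed=%d",
        len(peptides), config.feature_kind,
        scheme.name if scheme else "none", k, seed,
    )
    training, validation = split_dataset(peptides, validation_fraction, seed=seed)
    tr_pos, tr_neg = split_by_label(training)
    if scheme is not None:
        rep_pos, rep_neg = mine_both_directions(
            tr_pos, tr_neg, scheme, min_positive_coverage=min_positive_coverage
        )
        pos_motifs = tuple(r.motif for r in rep_pos)
        neg_motifs = tuple(r.motif for r in rep_neg)
        log.info("mined %d positive / %d negative exclusive motifs",
                 len(pos_motifs), len(neg_motifs))
    else:
        pos_motifs, neg_motifs = (), ()
    model = train(
        training, config, seed=seed,
        positive_motifs=pos_motifs, negative_motifs=neg_motifs, scheme=scheme,
    )
    cv = kfold_cv(
        training, config, scheme=scheme, k=k, seed=seed,
        min_positive_coverage=min_positive_coverage, motif_mining=motif_mining,
    )
    val_scores = np.array([hs.score for hs in hybrid_scores(model, validation)])
    val_labels = [r.label for r in validation]
    val_report = evaluate_scores(val_scores, val_labels, config.threshold)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_model(model, outdir / "model.json")
        write_table(reports_to_rows([cv.report]), outdir / "cv_report.tsv")
        write_table(reports_to_rows([val_report]), outdir / "validation_report.tsv")
    return PipelineResult(
        model=model,
        cv=cv,
        validation_report=val_report,
        training_set=training,
        validation_set=validation,
    )
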