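"""RBF-kernel SVM classifier with motif-based hybrid score adjustment.

The classifier is a soft-margin SVM on one of the composition encodings
(percent scale, un-standardized). Three published parameters mirror the
SVM-light convention: ``gamma`` (g), ``cost`` (c), and ``cost_factor`` (j),
the ratio by which training errors on the positive class outweigh errors on
the negative class. The *hybrid* score adds ``+1`` to the SVM decision value
when the peptide carries any positive-exclusive motif and ``-1`` when it
carries any negative-exclusive motif (indicators, not counts; a peptide
matching both kinds nets zero). Classification calls a peptide positive when
its (hybrid) score is at or above the decision threshold.

The default deployment configuration replicates the published tool's
selected model: DPC features with Betts–Russell motifs, rbf kernel,
g = 0.001, c = 8, j = 3, threshold 0.3.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConfigError, ModelFormatError, ValidationError
from .features import feature_matrix, feature_names
from .motifs import (
    MotifPattern,
    NONE_SCHEME,
    ResidueClassScheme,
    matches,
    parse_motif,
)
from .sequence_io import PeptideRecord, split_by_label

MODEL_FORMAT = "proinflam-model"
MODEL_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """SVM and decision parameters for one model."""

    feature_kind: str = "DPC"
    kernel: str = "rbf"
    gamma: float = 0.001
    cost: float = 8.0
    cost_factor: float = 3.0
    threshold: float = 0.3

    def __post_init__(self):
        object.__setattr__(self, "feature_kind", self.feature_kind.upper())
        if self.feature_kind not in ("AAC", "DPC", "PHYS"):
            raise ConfigError(f"unknown feature kind {self.feature_kind!r}")
        if self.kernel != "rbf":
            raise ConfigError("only the rbf kernel is supported")
        for name in ("gamma", "cost", "cost_factor"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be finite and positive, got {v}")
        if not np.isfinite(self.threshold):
            raise ConfigError("threshold must be finite")


#: Published parameter sets of the original tool, per feature/scheme variant
#: (gamma, cost, cost_factor, threshold).
REFERENCE_CONFIGS: dict[str, ModelConfig] = {
    "AAC": ModelConfig("AAC", gamma=0.005, cost=80, cost_factor=1, threshold=0.6),
    "DPC": ModelConfig("DPC", gamma=0.001, cost=10, cost_factor=1, threshold=0.4),
    "PHYS": ModelConfig("PHYS", gamma=0.001, cost=50, cost_factor=4, threshold=0.7),
    "DPC_HYBRID_NONE": ModelConfig("DPC", gamma=0.001, cost=20, cost_factor=1, threshold=0.4),
    "DPC_HYBRID_KOOLMAN": ModelConfig("DPC", gamma=0.001, cost=4, cost_factor=2, threshold=0.4),
    "DPC_HYBRID_BETTS": ModelConfig("DPC", gamma=0.001, cost=8, cost_factor=3, threshold=0.3),
}

DEFAULT_CONFIG = REFERENCE_CONFIGS["DPC_HYBRID_BETTS"]


@dataclass
class TrainedModel:
    """A fitted classifier plus the motif sets used for hybrid scoring."""

    config: ModelConfig
    classifier: SVC
    feature_names: tuple[str, ...]
    positive_motifs: tuple[MotifPattern, ...] = ()
    negative_motifs: tuple[MotifPattern, ...] = ()
    scheme: ResidueClassScheme = NONE_SCHEME
    n_pos: int = 0
    n_neg: int = 0
    seed: int = 0
    scales: pd.DataFrame | None = None


@dataclass(frozen=True)
class HybridScore:
    """Decomposed hybrid score of one peptide."""

    base: float
    positive_motif: bool
    negative_motif: bool

    @property
    def adjustment(self) -> int:
        return int(self.positive_motif) - int(self.negative_motif)

    @property
    def score(self) -> float:
        return self.base + self.adjustment


def train(
    peptides: Sequence[PeptideRecord],
    config: ModelConfig = DEFAULT_CONFIG,
    seed: int = 0,
    positive_motifs: Sequence[MotifPattern] = (),
    negative_motifs: Sequence[MotifPattern] = (),
    scheme: ResidueClassScheme | None = None,
    scales: pd.DataFrame | None = None,
) -> TrainedModel:
    """Fit the SVM on labeled peptides.

    Positive-class training errors are penalized ``cost * cost_factor``,
    negative-class errors ``cost``. Motif lists, mined beforehand, are
    attached for hybrid scoring; they may be empty (pure-feature model).
    Training is deterministic given (data, config, seed).
    """
    pos, neg = split_by_label(peptides)
    if not pos or not neg:
        raise ValidationError("training data must contain both classes")
    X = feature_matrix([r.sequence for r in peptides], config.feature_kind, scales=scales)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite feature values in training data")
    y = np.array([1 if r.label == "positive" else 0 for r in peptides])
    clf = SVC(
        kernel="rbf",
        gamma=config.gamma,
        C=config.cost,
        class_weight={1: config.cost_factor},
        random_state=seed,
    )
    clf.fit(X, y)
    if scheme is None:
        for m in tuple(positive_motifs) + tuple(negative_motifs):
            scheme = m.scheme
            break
        else:
            scheme = NONE_SCHEME
    return TrainedModel(
        config=config,
        classifier=clf,
        feature_names=feature_names(config.feature_kind),
        positive_motifs=tuple(positive_motifs),
        negative_motifs=tuple(negative_motifs),
        scheme=scheme,
        n_pos=len(pos),
        n_neg=len(neg),
        seed=seed,
        scales=scales,
    )


def decision_scores(model: TrainedModel, peptides: Sequence[str | PeptideRecord]) -> np.ndarray:
    """Raw SVM decision values (no motif adjustment) for many peptides."""
    X = feature_matrix(peptides, model.config.feature_kind, scales=model.scales)
    return model.classifier.decision_function(X)


def decision_score(model: TrainedModel, peptide: str | PeptideRecord) -> float:
    """Signed SVM decision value of one peptide on the model's features."""
    return float(decision_scores(model, [peptide])[0])


def hybrid_score(model: TrainedModel, peptide: str | PeptideRecord) -> HybridScore:
    """SVM decision value plus the +1/-1 exclusive-motif adjustments."""
    base = decision_score(model, peptide)
    pos_hit = any(matches(m, peptide) for m in model.positive_motifs)
    neg_hit = any(matches(m, peptide) for m in model.negative_motifs)
    return HybridScore(base=base, positive_motif=pos_hit, negative_motif=neg_hit)


def hybrid_scores(model: TrainedModel, peptides: Sequence[str | PeptideRecord]) -> list[HybridScore]:
    bases = decision_scores(model, peptides)
    out = []
    for base, pep in zip(bases, peptides):
        pos_hit = any(matches(m, pep) for m in model.positive_motifs)
        neg_hit = any(matches(m, pep) for m in model.negative_motifs)
        out.append(HybridScore(float(base), pos_hit, neg_hit))
    return out


def classify(score: float, threshold: float) -> str:
    """``positive`` iff score >= threshold (boundary inclusive)."""
    return "positive" if score >= threshold else "negative"


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model as a JSON envelope with an embedded classifier blob."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "config": {
            "feature_kind": model.config.feature_kind,
            "kernel": model.config.kernel,
            "gamma": model.config.gamma,
            "cost": model.config.cost,
            "cost_factor": model.config.cost_factor,
            "threshold": model.config.threshold,
        },
        "feature_names": list(model.feature_names),
        "scheme": {
            "name": model.scheme.name,
            "classes": {k: "".join(sorted(v)) for k, v in model.scheme.classes.items()},
        },
        "positive_motifs": [str(m) for m in model.positive_motifs],
        "negative_motifs": [str(m) for m in model.negative_motifs],
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "seed": model.seed,
        "scales": None if model.scales is None else model.scales.to_dict(),
        "classifier_b64": base64.b64encode(pickle.dumps(model.classifier)).decode(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; scores reproduce bitwise."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path} is not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"model version {payload.get('version')!r} is not supported "
            f"(expected {MODEL_VERSION})"
        )
    cfg = ModelConfig(**payload["config"])
    scheme = ResidueClassScheme(
        payload["scheme"]["name"],
        {k: frozenset(v) for k, v in payload["scheme"]["classes"].items()},
    )
    clf = pickle.loads(base64.b64decode(payload["classifier_b64"]))
    scales = payload.get("scales")
    return TrainedModel(
        config=cfg,
        classifier=clf,
        feature_names=tuple(payload["feature_names"]),
        positive_motifs=tuple(parse_motif(s, scheme) for s in payload["positive_motifs"]),
        negative_motifs=tuple(parse_motif(s, scheme) for s in payload["negative_motifs"]),
        scheme=scheme,
        n_pos=payload["n_pos"],
        n_neg=payload["n_neg"],
        seed=payload["seed"],
        scales=None if scales is None else pd.DataFrame(scales),
    )


def predict_table(
    model: TrainedModel,
    peptides: Sequence[PeptideRecord],
    threshold: float | None = None,
) -> list[dict]:
    """One result row per peptide: scores, motif adjustment, and call."""
    thr = model.config.threshold if threshold is None else threshold
    rows = []
    for pep, hs in zip(peptides, hybrid_scores(model, peptides)):
        rows.append(
            {
                "id": pep.id,
                "sequence": pep.sequence,
                "svm_score": hs.base,
                "motif_adjustment": hs.adjustment,
                "hybrid_score": hs.score,
                "call": classify(hs.score, thr),
            }
        )
    return rows
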