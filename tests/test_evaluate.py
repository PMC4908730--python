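import numpy as np
import pytest

from conftest import make_records
from helpers import auc_pair_counting, confusion_metrics_formulas
from proinflam import evaluate as ev
from proinflam.errors import ValidationError
from proinflam.evaluate import (
    ConfusionCounts,
    evaluate_scores,
    kfold_cv,
    metrics,
    roc_auc,
    split_dataset,
    threshold_sweep,
)
from proinflam.model import ModelConfig
from proinflam.motifs import BETTS_RUSSELL
from proinflam.synthetic import SyntheticSpec, generate_dataset


def labeled_dataset(n_pos, n_neg, seed=0):
    spec = SyntheticSpec(n_pos=n_pos, n_neg=n_neg, seed=seed)
    return generate_dataset(spec)


class TestSplit:
    def test_published_class_arithmetic(self):
        recs = labeled_dataset(729, 171)
        training, validation = split_dataset(recs, 0.2, seed=11)
        t_pos = sum(r.label == "positive" for r in training)
        v_pos = sum(r.label == "positive" for r in validation)
        assert (t_pos, len(training) - t_pos) == (583, 137)
        assert (v_pos, len(validation) - v_pos) == (146, 34)

    def test_partition(self):
        recs = labeled_dataset(40, 25)
        training, validation = split_dataset(recs, 0.2, seed=3)
        assert len(training) + len(validation) == len(recs)
        ids = {r.id for r in training} | {r.id for r in validation}
        assert ids == {r.id for r in recs}
        assert not ({r.id for r in training} & {r.id for r in validation})

    def test_deterministic(self):
        recs = labeled_dataset(30, 30)
        a = split_dataset(recs, 0.2, seed=5)
        b = split_dataset(recs, 0.2, seed=5)
        assert a == b

    def test_emptied_class_rejected(self):
        recs = labeled_dataset(10, 2)
        with pytest.raises(ValidationError):
            split_dataset(recs, 0.2, seed=0)  # 0.2*2 rounds to 0

    def test_bad_fraction(self):
        recs = labeled_dataset(10, 10)
        with pytest.raises(ValidationError):
            split_dataset(recs, 0.0)


class TestMetrics:
    def test_perfect_and_inverted(self):
        perfect = metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (perfect.sensitivity, perfect.specificity, perfect.accuracy,
                perfect.mcc) == (100.0, 100.0, 100.0, 1.0)
        inverted = metrics(ConfusionCounts(TP=0, FP=5, TN=0, FN=5))
        assert inverted.accuracy == 0.0 and inverted.mcc == -1.0

    def test_worked_example(self):
        m = metrics(ConfusionCounts(TP=3, FP=2, TN=4, FN=1))
        assert m.sensitivity == pytest.approx(75.0)
        assert m.specificity == pytest.approx(100 * 4 / 6)
        assert m.accuracy == pytest.approx(70.0)
        assert m.mcc == pytest.approx(0.4082, abs=1e-4)

    def test_zero_denominator_flagged(self):
        m = metrics(ConfusionCounts(TP=5, FP=0, TN=3, FN=0))  # TP+FP? no: FN=0
        # TP+FN=5, TN+FP=3, TP+FP=5, TN+FN=3 -> fine; force a zero factor:
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=2))
        assert m.mcc == 0.0 and not m.mcc_defined

    def test_absent_class_raises(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(TP=0, FP=1, TN=1, FN=0))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = roc_auc([1, 1, 1, 0, 0], ["positive"] * 3 + ["negative"] * 2)
        assert auc == 1.0
        fprs, tprs = zip(*pts)
        assert list(fprs) == sorted(fprs) and list(tprs) == sorted(tprs)

    def test_all_ties(self):
        auc, _ = roc_auc([0.5] * 6, ["positive"] * 3 + ["negative"] * 3)
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2], ["positive", "positive"])

    def test_matches_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 25))
            scores = rng.choice([-1.0, 0.0, 0.5, 1.0, 2.0], size=n)
            labels = ["positive" if rng.random() < 0.5 else "negative" for _ in range(n)]
            if len(set(labels)) < 2:
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_pair_counting(scores, labels))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = ["positive" if rng.random() < 0.5 else "negative" for _ in range(30)]
        if len(set(labels)) < 2:
            labels[0], labels[1] = "positive", "negative"
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(scores) * 3 + 7, labels)
        assert a1 == pytest.approx(a2)


class TestThresholdSweep:
    def test_extreme_thresholds(self):
        scores = [0.2, -0.4, 1.1, 0.9]
        labels = ["positive", "negative", "positive", "negative"]
        lo, hi = threshold_sweep(scores, labels, [-np.inf, np.inf])
        assert (lo.sensitivity, lo.specificity) == (100.0, 0.0)
        assert (hi.sensitivity, hi.specificity) == (0.0, 100.0)

    def test_accuracy_maxima_match_exhaustive_cutpoints(self, rng):
        scores = rng.normal(size=40)
        labels = ["positive" if s + rng.normal(scale=1.2) > 0 else "negative"
                  for s in scores]
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        cuts = np.concatenate([[-np.inf], np.sort(scores), [np.inf]])
        reports = threshold_sweep(scores, labels, cuts)
        best = max(r.accuracy for r in reports)
        # brute force: accuracy of every possible decision rule score >= c
        y = np.array([1 if l == "positive" else 0 for l in labels])
        s = np.asarray(scores)
        brute = max(
            100 * np.mean((s >= c).astype(int) == y) for c in cuts
        )
        assert best == pytest.approx(brute)


class TestKFold:
    def test_each_record_scored_once(self):
        recs = labeled_dataset(12, 12)
        config = ModelConfig("AAC", gamma=0.01, cost=10, cost_factor=1, threshold=0)
        result = kfold_cv(recs, config, scheme=None, k=4, seed=2)
        assert len(result.scores) == len(recs)
        assert result.report.counts.total == len(recs)
        assert result.ids == tuple(r.id for r in recs)

    def test_leave_one_out_limit(self):
        recs = labeled_dataset(5, 5)
        config = ModelConfig("AAC", gamma=0.01, cost=10, cost_factor=1, threshold=0)
        result = kfold_cv(recs, config, scheme=None, k=5, seed=0)
        assert len(result.scores) == 10

    def test_separable_data_perfect_pooled_accuracy(self):
        pos = make_records(["AAAAAAAG", "AAAAAAGA", "AAAAAGAA", "AAAAGAAA",
                            "AAAGAAAA", "AAGAAAAA"], label="positive", prefix="p")
        neg = make_records(["CCCCCCCG", "CCCCCCGC", "CCCCCGCC", "CCCCGCCC",
                            "CCCGCCCC", "CCGCCCCC"], label="negative", prefix="n")
        config = ModelConfig("AAC", gamma=0.001, cost=10, cost_factor=1, threshold=0)
        result = kfold_cv(pos + neg, config, scheme=None, k=3, seed=1)
        assert result.report.accuracy == 100.0

    def test_class_smaller_than_k_rejected(self):
        recs = labeled_dataset(20, 4)
        config = ModelConfig("AAC", gamma=0.01, cost=10, cost_factor=1, threshold=0)
        with pytest.raises(ValidationError):
            kfold_cv(recs, config, k=10)

    def test_per_fold_mining_never_sees_held_out_records(self, monkeypatch):
        recs = labeled_dataset(20, 20, seed=4)
        config = ModelConfig("DPC", gamma=0.001, cost=8, cost_factor=3, threshold=0.3)
        calls = []
        real = ev.mine_exclusive_motifs

        def spy(positives, negatives, *args, **kwargs):
            calls.append({r.id for r in positives} | {r.id for r in negatives})
            return real(positives, negatives, *args, **kwargs)

        monkeypatch.setattr(ev, "mine_exclusive_motifs", spy)
        k = 4
        result = kfold_cv(recs, config, scheme=BETTS_RUSSELL, k=k, seed=0,
                          min_positive_coverage=4)
        assert len(calls) == 2 * k  # both directions per fold
        n = len(recs)
        fold_sizes = {len(ids) for ids in calls}
        # every mining call saw only the k-1 training folds
        assert all(size < n for size in fold_sizes)
        all_ids = {r.id for r in recs}
        for i in range(0, len(calls), 2):
            train_ids = calls[i]
            held_out = all_ids - train_ids
            assert held_out and not (train_ids & held_out)

    def test_global_mining_mode_runs(self):
        recs = labeled_dataset(15, 15, seed=5)
        config = ModelConfig("DPC", gamma=0.001, cost=8, cost_factor=3, threshold=0.3)
        result = kfold_cv(recs, config, scheme=BETTS_RUSSELL, k=3, seed=0,
                          motif_mining="global", min_positive_coverage=3)
        assert result.report.counts.total == 30


def test_counts_match_metrics_on_random_scores(rng):
    scores = rng.normal(size=50)
    labels = ["positive" if rng.random() < 0.6 else "negative" for _ in range(50)]
    if len(set(labels)) < 2:
        labels[:2] = ["positive", "negative"]
    report = evaluate_scores(scores, labels, 0.1)
    counts = report.counts
    sen, spec, acc, mcc = confusion_metrics_formulas(
        counts.TP, counts.FP, counts.TN, counts.FN
    )
    assert report.sensitivity == pytest.approx(sen)
    assert report.specificity == pytest.approx(spec)
    assert report.accuracy == pytest.approx(acc)
    assert report.mcc == pytest.approx(mcc)
    # per-record brute-force recount
    tp = sum(1 for s, l in zip(scores, labels) if s >= 0.1 and l == "positive")
    assert counts.TP == tp
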