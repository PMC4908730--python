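import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_records, random_peptides
from proinflam.errors import ConfigError, ModelFormatError, ValidationError
from proinflam.model import (
    DEFAULT_CONFIG,
    ModelConfig,
    classify,
    decision_score,
    decision_scores,
    hybrid_score,
    load_model,
    save_model,
    train,
)
from proinflam.motifs import BETTS_RUSSELL, MotifPattern, parse_motif


class TestConfig:
    def test_defaults_are_the_deployed_hybrid(self):
        assert DEFAULT_CONFIG.feature_kind == "DPC"
        assert (DEFAULT_CONFIG.gamma, DEFAULT_CONFIG.cost,
                DEFAULT_CONFIG.cost_factor, DEFAULT_CONFIG.threshold) == (0.001, 8, 3, 0.3)

    @pytest.mark.parametrize("bad", [
        {"gamma": 0.0}, {"cost": -1.0}, {"cost_factor": float("nan")},
        {"feature_kind": "XXX"}, {"kernel": "linear"},
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ConfigError):
            ModelConfig(**bad)


class TestTrain:
    def test_separable_data_perfect_at_zero_threshold(self, separable_model):
        model, pos, neg = separable_model
        scores = decision_scores(model, pos + neg)
        calls = [classify(s, 0.0) for s in scores]
        truth = [r.label for r in pos + neg]
        assert calls == truth

    def test_deterministic_given_seed(self, separable_model):
        model, pos, neg = separable_model
        again = train(pos + neg, model.config, seed=model.seed)
        s1 = decision_scores(model, pos + neg)
        s2 = decision_scores(again, pos + neg)
        assert np.array_equal(s1, s2)

    def test_single_class_rejected(self):
        pos = make_records(["AAAA", "AAAC"], label="positive")
        with pytest.raises(ValidationError):
            train(pos, DEFAULT_CONFIG)

    def test_length_normalization_via_composition(self, separable_model):
        model, _, _ = separable_model
        # identical compositions at different lengths get identical scores
        assert decision_score(model, "ACACAC") == pytest.approx(
            decision_score(model, "ACAC")
        )

    def test_cost_factor_shifts_boundary_toward_positives(self):
        # overlapping A-rich vs A-poor peptides; a larger positive-class
        # error weight must not lower (and should raise) training sensitivity
        rng = np.random.default_rng(3)

        def sample(p_a, n):
            return [
                "".join("A" if rng.random() < p_a else "CGT"[rng.integers(3)]
                        for _ in range(10))
                for _ in range(n)
            ]

        recs = make_records(sample(0.55, 30), label="positive", prefix="p") + \
            make_records(sample(0.45, 30), label="negative", prefix="n")
        lo = train(recs, ModelConfig("AAC", gamma=0.005, cost=1, cost_factor=1, threshold=0))
        hi = train(recs, ModelConfig("AAC", gamma=0.005, cost=1, cost_factor=20, threshold=0))
        pos = [r for r in recs if r.label == "positive"]
        sen_lo = np.mean(decision_scores(lo, pos) >= 0)
        sen_hi = np.mean(decision_scores(hi, pos) >= 0)
        assert sen_hi > sen_lo


class TestHybrid:
    @pytest.fixture()
    def motif_model(self, separable_model):
        model, pos, neg = separable_model
        model2 = train(
            pos + neg,
            model.config,
            seed=0,
            positive_motifs=(parse_motif("K-A-L", BETTS_RUSSELL),),
            negative_motifs=(parse_motif("D-E", BETTS_RUSSELL),),
            scheme=BETTS_RUSSELL,
        )
        return model2

    def test_positive_motif_adds_one(self, motif_model):
        hs = hybrid_score(motif_model, "WKALW")
        assert hs.positive_motif and not hs.negative_motif
        assert hs.score == pytest.approx(hs.base + 1.0)

    def test_negative_motif_subtracts_one(self, motif_model):
        hs = hybrid_score(motif_model, "WDEWW")
        assert hs.negative_motif and not hs.positive_motif
        assert hs.score == pytest.approx(hs.base - 1.0)

    def test_both_motifs_cancel(self, motif_model):
        hs = hybrid_score(motif_model, "KALDE")
        assert hs.positive_motif and hs.negative_motif
        assert hs.adjustment == 0
        assert hs.score == pytest.approx(hs.base)

    def test_indicator_not_count(self, separable_model):
        model, pos, neg = separable_model
        two = train(
            pos + neg, model.config, seed=0,
            positive_motifs=(MotifPattern(("K", "A")), MotifPattern(("A", "L"))),
        )
        hs = hybrid_score(two, "WKALW")  # matches both positive motifs
        assert hs.adjustment == 1

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=4, max_size=30))
    def test_adjustment_always_in_unit_band(self, seq):
        model = _cached_motif_model()
        hs = hybrid_score(model, seq)
        assert hs.score - hs.base in (-1, 0, 1)


_MODEL_CACHE = {}


def _cached_motif_model():
    if "m" not in _MODEL_CACHE:
        pos = make_records(["AAAAKAL", "AAKALAA", "KALAAAA"], label="positive", prefix="p")
        neg = make_records(["CCCCDEC", "CCDECCC", "DECCCCC"], label="negative", prefix="n")
        _MODEL_CACHE["m"] = train(
            pos + neg,
            ModelConfig("AAC", gamma=0.01, cost=10, cost_factor=1, threshold=0),
            positive_motifs=(MotifPattern(("K", "A", "L")),),
            negative_motifs=(MotifPattern(("D", "E")),),
        )
    return _MODEL_CACHE["m"]


class TestClassify:
    def test_boundary_inclusive(self):
        assert classify(0.31, 0.3) == "positive"
        assert classify(0.3, 0.3) == "positive"
        assert classify(-2.0, 0.3) == "negative"

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0, 5))
    def test_raising_threshold_never_flips_to_positive(self, score, thr, bump):
        if classify(score, thr) == "negative":
            assert classify(score, thr + bump) == "negative"


class TestPersistence:
    def test_round_trip_scores_bitwise_equal(self, separable_model, tmp_path, rng):
        model, pos, neg = separable_model
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        probe = random_peptides(rng, 10)
        assert np.array_equal(
            decision_scores(model, probe), decision_scores(loaded, probe)
        )
        assert loaded.config == model.config
        assert loaded.positive_motifs == model.positive_motifs

    def test_motifs_survive_round_trip(self, tmp_path):
        model = _cached_motif_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        hs0, hs1 = hybrid_score(model, "WKALW"), hybrid_score(loaded, "WKALW")
        assert hs0 == hs1

    def test_truncated_file(self, separable_model, tmp_path):
        model, _, _ = separable_model
        path = tmp_path / "model.json"
        save_model(model, path)
        path.write_text(path.read_text()[: 100])
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_version_mismatch(self, separable_model, tmp_path):
        import json

        model, _, _ = separable_model
        path = tmp_path / "model.json"
        save_model(model, path)
        payload = json.loads(path.read_text())
        payload["version"] = 999
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_empty_motif_lists_hybrid_equals_decision(self, separable_model, tmp_path):
        model, pos, _ = separable_model
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        pep = pos[0].sequence
        hs = hybrid_score(loaded, pep)
        assert hs.adjustment == 0
        assert hs.score == pytest.approx(decision_score(loaded, pep))
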