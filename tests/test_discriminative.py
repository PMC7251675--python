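"""Feature templates, resampling policy and noise-aware training."""

import io

import numpy as np
import pytest

from rxnminer.discriminative import (
    DiscriminativeParams,
    FeatureVocabulary,
    ResamplePolicy,
    classify,
    extract_features,
    predict,
    resample_training,
    soft_cross_entropy,
    train_discriminative,
)
from rxnminer.labeling_functions import build_context

from .conftest import candidate_pair, make_document


def features_for(sentence, surfaces, i, j, annotator, resources):
    doc, mentions = make_document(sentence, surfaces, annotator)
    cand = candidate_pair(doc, mentions, i, j)
    return extract_features(cand, build_context(cand, doc), resources)


class TestFeatures:
    def test_between_bigram_and_order_flag(self, annotator, resources):
        feats = features_for("glucose is oxidized to ethanol.",
                             ["glucose", "ethanol"], 0, 1, annotator, resources)
        assert "between_2gram=oxidized_to" in feats
        assert "order_reversed=0" in feats
        assert "kw=oxidize" in feats

    def test_reversed_candidate_same_ngrams_different_flag(
            self, annotator, resources):
        fwd = features_for("glucose is oxidized to ethanol.",
                           ["glucose", "ethanol"], 0, 1, annotator, resources)
        rev = features_for("glucose is oxidized to ethanol.",
                           ["glucose", "ethanol"], 1, 0, annotator, resources)
        assert {k for k in fwd if k.startswith("between_")} == \
            {k for k in rev if k.startswith("between_")}
        assert "order_reversed=1" in rev

    def test_adjacent_mentions_have_no_between_ngrams(self, annotator, resources):
        feats = features_for("glucose ethanol mixtures were studied.",
                             ["glucose", "ethanol"], 0, 1, annotator, resources)
        assert not any(k.startswith("between_1gram") for k in feats)
        assert "dist_bin=0" in feats

    def test_ase_adjacency_indicator(self, annotator, resources):
        feats = features_for("glucose dehydrogenase oxidizes xylose.",
                             ["glucose", "xylose"], 0, 1, annotator, resources)
        assert feats.get("ase_adjacent") == 1.0

    def test_determinism(self, annotator, resources):
        a = features_for("glucose is converted to ethanol.",
                         ["glucose", "ethanol"], 0, 1, annotator, resources)
        b = features_for("glucose is converted to ethanol.",
                         ["glucose", "ethanol"], 0, 1, annotator, resources)
        assert a == b


class TestVocabulary:
    def test_frequency_floor(self):
        dicts = [{"a": 1.0, "b": 1.0}, {"a": 1.0}, {"c": 1.0}]
        vocab = FeatureVocabulary.build(dicts, min_count=2)
        assert set(vocab.index) == {"a"}
        X = vocab.transform(dicts)
        assert X.shape == (3, 1)
        assert X.toarray().ravel().tolist() == [1.0, 1.0, 0.0]


class TestResampling:
    def test_policy_arithmetic(self):
        ids = [f"c{i}" for i in range(1000)]
        marg = {cid: (0.9 if i < 30 else 0.1) for i, cid in enumerate(ids)}
        subset = resample_training(ids, marg, ResamplePolicy(0.10, seed=4))
        assert len(subset) == 100
        assert set(ids[:30]) <= set(subset)

    def test_identity_at_full_fraction(self):
        ids = ["a", "b", "c"]
        marg = {"a": 0.9, "b": 0.2, "c": 0.4}
        assert resample_training(ids, marg, ResamplePolicy(1.0, seed=0)) == ids

    def test_same_seed_same_subset(self):
        ids = [f"c{i}" for i in range(500)]
        marg = {cid: 0.2 for cid in ids}
        a = resample_training(ids, marg, ResamplePolicy(0.2, seed=9))
        b = resample_training(ids, marg, ResamplePolicy(0.2, seed=9))
        assert a == b

    def test_target_below_kept_returns_kept(self, caplog):
        ids = [f"c{i}" for i in range(10)]
        marg = {cid: 0.9 for cid in ids[:5]} | {cid: 0.1 for cid in ids[5:]}
        subset = resample_training(ids, marg, ResamplePolicy(0.2, seed=0))
        assert subset == ids[:5]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ResamplePolicy(target_fraction=0.0)


SEP_FEATS = [
    {"a": 1.0, "b": 1.0}, {"a": 1.0}, {"a": 1.0, "c": 1.0},
    {"b": 1.0, "c": 1.0}, {"c": 1.0}, {"b": 1.0},
]
SEP_MARG = np.array([0.95, 0.95, 0.95, 0.05, 0.05, 0.05])


class TestTraining:
    def test_separable_fixture_perfect_at_threshold(self):
        params = train_discriminative(SEP_FEATS, SEP_MARG, seed=0)
        scores = predict(params, SEP_FEATS)
        assert (classify(scores) == np.where(SEP_MARG > 0.5, 1, -1)).all()

    def test_training_reduces_loss_from_initialization(self):
        params = train_discriminative(SEP_FEATS, SEP_MARG, seed=0)
        init_loss = soft_cross_entropy(np.full(len(SEP_MARG), 0.5), SEP_MARG)
        final_loss = soft_cross_entropy(predict(params, SEP_FEATS), SEP_MARG)
        assert final_loss <= init_loss

    def test_huge_penalty_shrinks_to_constant(self):
        params = train_discriminative(SEP_FEATS, SEP_MARG, seed=0,
                                      penalty_strength=1e4)
        scores = predict(params, SEP_FEATS)
        assert np.ptp(scores) < 1e-3

    def test_duplicating_examples_leaves_optimum_unchanged(self):
        p1 = train_discriminative(SEP_FEATS, SEP_MARG, seed=0)
        p2 = train_discriminative(SEP_FEATS * 2, np.tile(SEP_MARG, 2), seed=0)
        s1 = predict(p1, SEP_FEATS)
        s2 = predict(p2, SEP_FEATS)
        # identical optimum; residual difference is stochastic-solver noise
        assert np.abs(s1 - s2).max() < 2e-3

    def test_shuffle_invariance_at_convergence(self):
        rng = np.random.default_rng(3)
        order = rng.permutation(len(SEP_FEATS))
        p1 = train_discriminative(SEP_FEATS, SEP_MARG, seed=0)
        p2 = train_discriminative([SEP_FEATS[i] for i in order], SEP_MARG[order],
                                  seed=0)
        assert np.abs(predict(p1, SEP_FEATS) - predict(p2, SEP_FEATS)).max() < 1e-4

    def test_constant_marginals_warn(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="rxnminer.discriminative"):
            train_discriminative(SEP_FEATS, np.full(6, 0.5), seed=0)
        assert any("constant" in r.message for r in caplog.records)

    def test_no_examples_rejected(self):
        with pytest.raises(ValueError):
            train_discriminative([], np.array([]), seed=0)


class TestPredict:
    def test_zero_model_scores_half(self):
        params = DiscriminativeParams(weights={}, bias=0.0, l1_ratio=0.5,
                                      penalty_strength=1e-3)
        assert predict(params, [{"x": 1.0}])[0] == pytest.approx(0.5)

    def test_score_at_threshold_is_positive(self):
        assert classify(np.array([0.5]), threshold=0.5)[0] == 1

    def test_unknown_features_ignored(self):
        params = DiscriminativeParams(weights={"a": 2.0}, bias=0.0, l1_ratio=0.5,
                                      penalty_strength=1e-3)
        known = predict(params, [{"a": 1.0}])[0]
        extra = predict(params, [{"a": 1.0, "zzz": 5.0}])[0]
        assert known == extra


def test_model_file_round_trip():
    params = train_discriminative(SEP_FEATS, SEP_MARG, seed=7,
                                  l1_ratio=0.3, penalty_strength=1e-2)
    buf = io.StringIO()
    params.save(buf)
    buf.seek(0)
    loaded = DiscriminativeParams.load(buf)
    assert loaded.weights == params.weights
    assert loaded.bias == params.bias
    assert loaded.l1_ratio == params.l1_ratio
    assert loaded.seed == 7
    assert np.array_equal(predict(loaded, SEP_FEATS), predict(params, SEP_FEATS))
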