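import numpy as np
import pytest

from slideroi.head_search import HeadArchitecture
from slideroi.roi_classifier import (
    ClassifierSpec,
    EvalMetrics,
    FinetuneMode,
    UnavailableBackboneError,
    build_classifier,
    cross_validate,
    evaluate,
)

from conftest import luminance_tiles


def _spec(**kw):
    defaults = dict(
        backbone="tiny-cnn",
        head=HeadArchitecture((32,)),
        epochs=12,
        seed=0,
        learning_rate=0.01,
    )
    defaults.update(kw)
    return ClassifierSpec(**defaults)


class TestBuild:
    def test_head_only_trainable_params_equal_head_params(self):
        spec = _spec(head=HeadArchitecture((128, 64, 32)))
        clf = build_classifier(spec)
        assert clf.trainable_parameter_count == spec.head.param_count

    def test_mhsa_with_cnn_backbone_rejected(self):
        with pytest.raises(ValueError):
            build_classifier(_spec(finetune_mode=FinetuneMode.MHSA_ONLY))

    def test_mhsa_only_trains_attention_parameters_only(self):
        clf = build_classifier(
            _spec(backbone="tiny-vit", finetune_mode=FinetuneMode.MHSA_ONLY)
        )
        d = clf.backbone.dim
        assert clf.trainable_parameter_count == 4 * d * d

    def test_mhsa_plus_head_trains_both(self):
        spec = _spec(backbone="tiny-vit", finetune_mode=FinetuneMode.MHSA_PLUS_HEAD)
        clf = build_classifier(spec)
        d = clf.backbone.dim
        assert clf.trainable_parameter_count == 4 * d * d + spec.head.param_count

    def test_pretrained_backbones_loadable_by_name_but_unavailable(self):
        for name in ("VGG16", "ViT-B/32"):
            with pytest.raises(UnavailableBackboneError):
                build_classifier(_spec(backbone=name))

    def test_incompatible_head_width(self):
        head = HeadArchitecture((32,), input_width=512)
        with pytest.raises(ValueError, match="incompatible"):
            build_classifier(_spec(head=head))

    def test_invalid_dropout(self):
        with pytest.raises(ValueError):
            _spec(dropout=1.0)


class TestTraining:
    def test_separable_tiles_reach_high_accuracy(self):
        X, y = luminance_tiles(400, 0)
        Xv, yv = luminance_tiles(200, 1)
        clf = build_classifier(_spec())
        log = clf.train((X, y), (Xv, yv))
        assert len(log) == 12
        assert log[-1]["val_accuracy"] >= 0.95

    def test_shuffled_labels_chance_level(self):
        X, y = luminance_tiles(400, 2)
        y_shuffled = np.random.default_rng(99).permutation(y)
        Xv, yv = luminance_tiles(400, 1)
        clf = build_classifier(_spec())
        log = clf.train((X, y_shuffled), (Xv, yv))
        # 3 sigma of Binomial(400, 0.5) on the validation accuracy
        assert abs(log[-1]["val_accuracy"] - 0.5) <= 0.075

    def test_one_class_training_predicts_that_class(self):
        X, y = luminance_tiles(200, 3)
        X1, y1 = X[y == 1], y[y == 1]
        clf = build_classifier(_spec(epochs=5))
        clf.train((X1, y1))
        p = clf.predict_proba(X1)
        assert ((p >= 0.5).astype(int) == 1).all()

    def test_frozen_backbone_outputs_unchanged_by_training(self):
        X, y = luminance_tiles(120, 4)
        clf = build_classifier(_spec(epochs=3))
        probe = X[:10]
        before = clf.backbone_features(probe)
        clf.train((X, y))
        after = clf.backbone_features(probe)
        assert np.array_equal(before, after)

    def test_deterministic_under_seed(self):
        X, y = luminance_tiles(120, 5)
        runs = []
        for _ in range(2):
            clf = build_classifier(_spec(epochs=3))
            clf.train((X, y))
            runs.append(clf.predict_proba(X[:20]))
        assert np.array_equal(runs[0], runs[1])

    def test_mhsa_training_updates_attention_not_ffn(self):
        X, y = luminance_tiles(80, 6)
        clf = build_classifier(
            _spec(
                backbone="tiny-vit",
                finetune_mode=FinetuneMode.MHSA_PLUS_HEAD,
                epochs=2,
                learning_rate=0.001,
            )
        )
        wq0 = clf.backbone.Wq.copy()
        ffn0 = clf.backbone.W_ffn1.copy()
        emb0 = clf.backbone.W_embed.copy()
        clf.train((X, y))
        assert not np.array_equal(wq0, clf.backbone.Wq)
        assert np.array_equal(ffn0, clf.backbone.W_ffn1)
        assert np.array_equal(emb0, clf.backbone.W_embed)

    def test_empty_training_set_rejected(self):
        clf = build_classifier(_spec())
        with pytest.raises(ValueError):
            clf.train((np.zeros((0, 56, 56, 3), dtype=np.uint8), np.zeros(0)))


def _brute_force_auc(y, scores):
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestEvaluate:
    def test_perfect_predictor(self):
        y = np.array([1] * 10 + [0] * 10)
        scores = np.array([0.9] * 10 + [0.1] * 10)
        m = EvalMetrics.from_scores(y, scores)
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == (1, 1, 1, 1)

    def test_auc_all_pairs_ordered(self):
        y = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.4, 0.1])
        assert EvalMetrics.from_scores(y, scores).auc == 1.0

    def test_constant_predictor_chance(self):
        y = np.array([1] * 10 + [0] * 10)
        scores = np.full(20, 0.5)
        m = EvalMetrics.from_scores(y, scores)
        assert m.accuracy == 0.5  # all predicted positive on a balanced set
        assert m.auc == 0.5

    def test_single_class_nan_with_warning(self):
        y = np.ones(6, dtype=int)
        with pytest.warns(UserWarning):
            m = EvalMetrics.from_scores(y, np.linspace(0, 1, 6))
        assert np.isnan(m.specificity)
        assert np.isnan(m.auc)
        assert m.sensitivity >= 0

    def test_metric_identities_on_random_confusions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.random(50)
            m = EvalMetrics.from_scores(y, scores)
            n = m.tp + m.tn + m.fp + m.fn
            assert n == 50
            assert m.accuracy == pytest.approx((m.tp + m.tn) / n)
            assert m.sensitivity == pytest.approx(m.tp / (m.tp + m.fn))
            assert m.specificity == pytest.approx(m.tn / (m.tn + m.fp))

    def test_auc_equals_brute_force_concordance(self):
        rng = np.random.default_rng(1)
        for n in (20, 60, 200):
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            m = EvalMetrics.from_scores(y, scores)
            assert m.auc == pytest.approx(_brute_force_auc(y, scores))

    def test_evaluate_uses_handle(self):
        X, y = luminance_tiles(120, 7)
        clf = build_classifier(_spec(epochs=8))
        clf.train((X, y))
        m = evaluate(clf, (X, y))
        assert m.accuracy >= 0.9


class TestCrossValidate:
    def test_separable_mean_accuracy(self):
        X, y = luminance_tiles(300, 8)
        result = cross_validate(_spec(epochs=8), X, y, k=5, seed=0)
        assert len(result.fold_metrics) == 5
        assert result.mean_accuracy >= 0.95

    def test_deterministic(self):
        X, y = luminance_tiles(100, 9)
        a = cross_validate(_spec(epochs=2), X, y, k=3, seed=1)
        b = cross_validate(_spec(epochs=2), X, y, k=3, seed=1)
        assert [m.accuracy for m in a.fold_metrics] == [m.accuracy for m in b.fold_metrics]

    def test_k_less_than_two_rejected(self):
        X, y = luminance_tiles(20, 10)
        with pytest.raises(ValueError):
            cross_validate(_spec(), X, y, k=1)
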