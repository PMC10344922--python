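"""Backbone-agnostic tile classifier and evaluation harness.

A classifier is a frozen (or partially fine-tunable) feature backbone plus a
trainable dense head. The named ImageNet-scale backbones require a deep
learning framework with pretrained weights and are not available offline;
the two ``tiny-*`` backbones cover every contract at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from . import _nn
from .annotation_consensus import random_augment, stratified_kfold_indices
from .head_search import HeadArchitecture

__all__ = [
    "ClassifierSpec",
    "CrossValidationResult",
    "EvalMetrics",
    "FinetuneMode",
    "TrainingDivergedError",
    "UnavailableBackboneError",
    "build_classifier",
    "cross_validate",
    "evaluate",
]


class UnavailableBackboneError(RuntimeError):
    """Backbone needs pretrained weights / a framework not bundled here."""


class TrainingDivergedError(RuntimeError):
    pass


class FinetuneMode:
    HEAD_ONLY = "HEAD_ONLY"
    MHSA_ONLY = "MHSA_ONLY"
    MHSA_PLUS_HEAD = "MHSA_PLUS_HEAD"


_PRETRAINED_NAMES = (
    "VGG16",
    "VGG19",
    "ResNet50",
    "ResNet152",
    "Xception",
    "InceptionV3",
    "DenseNet121",
    "ViT-B/32",
)


def _make_backbone(name: str):
    if name == "tiny-cnn":
        return _nn.TinyCNNBackbone()
    if name == "tiny-vit":
        return _nn.TinyViTBackbone()
    if name in _PRETRAINED_NAMES:
        raise UnavailableBackboneError(
            f"backbone {name!r} requires pretrained weights and a deep-learning "
            "framework; use 'tiny-cnn' or 'tiny-vit' for offline runs"
        )
    raise ValueError(f"unknown backbone {name!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    backbone: str = "tiny-cnn"
    head: HeadArchitecture = field(default_factory=lambda: HeadArchitecture((128, 64, 32)))
    finetune_mode: str = FinetuneMode.HEAD_ONLY
    epochs: int = 30
    batch_size: int = 32
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    learning_rate: float = 0.01
    dropout: float = 0.0
    seed: int = 0
    magnification: float | None = None
    augment: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.finetune_mode not in (
            FinetuneMode.HEAD_ONLY,
            FinetuneMode.MHSA_ONLY,
            FinetuneMode.MHSA_PLUS_HEAD,
        ):
            raise ValueError(f"unknown finetune mode {self.finetune_mode!r}")


class Classifier:
    """Handle exposing ``train`` and ``predict_proba`` over raw tile rasters."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.magnification = spec.magnification
        self.backbone = _make_backbone(spec.backbone)
        if spec.finetune_mode != FinetuneMode.HEAD_ONLY:
            if self.backbone.kind != "vit":
                raise ValueError(
                    f"{spec.finetune_mode} requires a transformer backbone, "
                    f"got {spec.backbone!r}"
                )
            self.backbone.attention_trainable = True
        if spec.head.input_width != self.backbone.feature_width:
            raise ValueError(
                f"head input width {spec.head.input_width} incompatible with "
                f"backbone output width {self.backbone.feature_width}"
            )
        self.rng = np.random.default_rng(spec.seed)
        # frozen feature standardization, estimated once at the start of
        # training; keeps the head's input well-scaled for any backbone
        self._feat_mean = 0.0
        self._feat_std = 1.0
        head_trainable = spec.finetune_mode != FinetuneMode.MHSA_ONLY
        self.head_layers: list = []
        widths = spec.head.widths
        for i, (a, b) in enumerate(zip(widths, widths[1:])):
            self.head_layers.append(_nn.Dense(a, b, self.rng, trainable=head_trainable))
            if i == 0 and spec.dropout > 0:
                self.head_layers.append(_nn.Dropout(spec.dropout, self.rng))
            if i < len(widths) - 2:
                self.head_layers.append(_nn.ReLU())

    # -- bookkeeping -------------------------------------------------------

    @property
    def trainable_parameter_count(self) -> int:
        n = self.backbone.trainable_parameter_count()
        for layer in self.head_layers:
            for p in layer.params().values():
                n += p.size
        return n

    def backbone_features(self, images: np.ndarray) -> np.ndarray:
        return self.backbone.features(np.asarray(images))

    # -- forward paths -----------------------------------------------------

    def _head_forward(self, feats: np.ndarray, train: bool) -> np.ndarray:
        x = (feats - self._feat_mean) / self._feat_std
        for layer in self.head_layers:
            x = layer.forward(x, train=train)
        return x

    def _head_backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.head_layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each tile."""
        feats = self.backbone_features(images)
        logits = self._head_forward(feats, train=False)
        return _nn.softmax(logits)[:, 1]

    # -- training ----------------------------------------------------------

    def train(
        self,
        train_set: tuple[np.ndarray, np.ndarray],
        val_set: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> list[dict]:
        """Mini-batch training; returns a per-epoch log of loss/accuracy."""
        spec = self.spec
        X, y = np.asarray(train_set[0]), np.asarray(train_set[1], dtype=int)
        if len(X) == 0:
            raise ValueError("empty training set")
        finetune_backbone = spec.finetune_mode != FinetuneMode.HEAD_ONLY
        opt = _nn.make_optimizer(spec.optimizer, spec.learning_rate)
        layers = list(self.head_layers) + self.backbone.trainable_layers()

        feats_cache = None
        if not finetune_backbone and not spec.augment:
            feats_cache = self.backbone_features(X)
            probe = feats_cache
        else:
            probe = self.backbone.features(X[: min(len(X), 256)])
        self._feat_mean = probe.mean(axis=0)
        self._feat_std = np.maximum(probe.std(axis=0), 1e-6)

        log: list[dict] = []
        for epoch in range(spec.epochs):
            order = self.rng.permutation(len(X))
            epoch_loss = 0.0
            for start in range(0, len(X), spec.batch_size):
                idx = order[start : start + spec.batch_size]
                if feats_cache is not None:
                    feats = feats_cache[idx]
                else:
                    batch = X[idx]
                    if spec.augment:
                        batch = np.stack([random_augment(im, self.rng) for im in batch])
                    if finetune_backbone:
                        feats = self.backbone.features(batch, train=True)
                    else:
                        feats = self.backbone.features(batch)
                logits = self._head_forward(feats, train=True)
                loss, grad = _nn.softmax_loss(logits, y[idx], spec.loss)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}: {loss}"
                    )
                dfeat = self._head_backward(grad)
                if finetune_backbone:
                    self.backbone.backward(dfeat / self._feat_std)
                opt.step(layers)
                epoch_loss += loss * len(idx)
            entry = {"epoch": epoch, "loss": epoch_loss / len(X)}
            if val_set is not None:
                p = self.predict_proba(val_set[0])
                entry["val_accuracy"] = float(
                    np.mean((p >= 0.5).astype(int) == np.asarray(val_set[1], dtype=int))
                )
            log.append(entry)
        return log


def build_classifier(spec: ClassifierSpec) -> Classifier:
    return Classifier(spec)


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float

    @classmethod
    def from_scores(
        cls, y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
    ) -> "EvalMetrics":
        y_true = np.asarray(y_true, dtype=int)
        scores = np.asarray(scores, dtype=float)
        pred = (scores >= threshold).astype(int)
        tp = int(np.sum((pred == 1) & (y_true == 1)))
        tn = int(np.sum((pred == 0) & (y_true == 0)))
        fp = int(np.sum((pred == 1) & (y_true == 0)))
        fn = int(np.sum((pred == 0) & (y_true == 1)))
        acc = (tp + tn) / len(y_true)
        if tp + fn == 0:
            warnings.warn("no positive items: sensitivity undefined")
            tpr = float("nan")
        else:
            tpr = tp / (tp + fn)
        if tn + fp == 0:
            warnings.warn("no negative items: specificity undefined")
            tnr = float("nan")
        else:
            tnr = tn / (tn + fp)
        if len(np.unique(y_true)) < 2:
            warnings.warn("single-class test set: AUC undefined")
            auc = float("nan")
        else:
            auc = float(roc_auc_score(y_true, scores))
        return cls(tp, tn, fp, fn, acc, tpr, tnr, auc)


def evaluate(
    handle: Classifier,
    test_set: tuple[np.ndarray, np.ndarray],
    threshold: float = 0.5,
) -> EvalMetrics:
    scores = handle.predict_proba(test_set[0])
    return EvalMetrics.from_scores(test_set[1], scores, threshold)


@dataclass
class CrossValidationResult:
    fold_metrics: list[EvalMetrics]
    mean_accuracy: float
    std_accuracy: float
    roc_curves: list[tuple[np.ndarray, np.ndarray]]


def cross_validate(
    spec: ClassifierSpec,
    images: np.ndarray,
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified k-fold: train on k-1 folds, evaluate on the held-out fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels, dtype=int)
    folds = stratified_kfold_indices(labels, k, seed)
    metrics: list[EvalMetrics] = []
    rocs: list[tuple[np.ndarray, np.ndarray]] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        clf = build_classifier(spec)
        clf.train((images[train_idx], labels[train_idx]))
        scores = clf.predict_proba(images[test_idx])
        metrics.append(EvalMetrics.from_scores(labels[test_idx], scores))
        if len(np.unique(labels[test_idx])) == 2:
            fpr, tpr, _ = roc_curve(labels[test_idx], scores)
            rocs.append((fpr, tpr))
    accs = np.array([m.accuracy for m in metrics])
    return CrossValidationResult(metrics, float(accs.mean()), float(accs.std()), rocs)
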