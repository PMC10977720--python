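"""Two-unit emotion readout on a frozen backbone.

The backbone's final classification layer is replaced by a two-unit head that
discriminates one emotion against the other two (pleasant vs non-pleasant,
neutral vs non-neutral, unpleasant vs non-unpleasant).  Only the head is
trained (softmax cross-entropy, plain SGD); every other weight is frozen,
which is verified by hashing the non-head weights.  Performance is the
positive-class F1-score (macro-F1 behind a switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .backbone import Backbone, GainConfig, LayerCache
from .stimuli import CATEGORIES, StimulusSet


@dataclass(frozen=True)
class ReadoutTask:
    """One-vs-rest emotion recognition task (positive emotion vs the rest)."""

    positive: str

    def __post_init__(self) -> None:
        if self.positive not in CATEGORIES:
            raise ValueError(f"unknown emotion {self.positive!r}")

    def binary_labels(self, categories: np.ndarray) -> np.ndarray:
        return (np.asarray(categories, dtype=object) == self.positive).astype(np.int64)


@dataclass
class TrainConfig:
    """Readout training hyper-parameters (defaults follow the study protocol:
    lr 1e-3, 10 epochs, batch 128, 50/25/25 stratified split)."""

    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 128
    split: tuple[float, float, float] = (0.5, 0.25, 0.25)
    seed: int = 0
    class_balance: str = "weighted"  # "weighted" (inverse prevalence) | "none"

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.class_balance not in ("weighted", "none"):
            raise ValueError("class_balance must be 'weighted' or 'none'")


@dataclass
class ReadoutModel:
    """Trained two-unit head plus provenance and feature standardization."""

    task: ReadoutTask
    weights: np.ndarray  # (2, hidden_dim)
    bias: np.ndarray  # (2,)
    feature_mean: np.ndarray
    feature_std: np.ndarray
    backbone_hash: str
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    def decision(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.feature_mean) / self.feature_std
        return z @ self.weights.T + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.decision(features), axis=1)


def split_dataset(
    stimuli: StimulusSet, config: TrainConfig
) -> tuple[StimulusSet, StimulusSet, StimulusSet]:
    """Stratified-by-category train/val/test partition, seeded-deterministic."""
    rng = np.random.default_rng(config.seed)
    r1, r2, _ = config.split
    parts: list[list[int]] = [[], [], []]
    for c in CATEGORIES:
        idx = np.flatnonzero(stimuli.categories == c)
        if len(idx) < 4:
            raise ValueError(f"category {c!r} has too few images to stratify")
        idx = idx[rng.permutation(len(idx))]
        c1 = int(round(len(idx) * r1))
        c2 = c1 + int(round(len(idx) * r2))
        parts[0].extend(idx[:c1])
        parts[1].extend(idx[c1:c2])
        parts[2].extend(idx[c2:])
    return tuple(stimuli.subset(np.sort(p)) for p in parts)  # type: ignore[return-value]


def f1_score(predictions, labels, positive) -> float:
    """Positive-class F1 = 2TP / (2TP + FP + FN); 0 when the denominator is 0."""
    predictions = np.asarray(predictions, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    if positive not in set(labels) | set(predictions):
        raise ValueError(f"unknown positive class {positive!r}")
    tp = int(np.sum((predictions == positive) & (labels == positive)))
    fp = int(np.sum((predictions == positive) & (labels != positive)))
    fn = int(np.sum((predictions != positive) & (labels == positive)))
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def macro_f1(predictions, labels) -> float:
    classes = sorted(set(np.asarray(labels, dtype=object)))
    return float(np.mean([f1_score(predictions, labels, c) for c in classes]))


def _extract_features(backbone: Backbone, stimuli: StimulusSet,
                      gains: GainConfig | None = None, batch_size: int = 256) -> np.ndarray:
    out = []
    for start in range(0, len(stimuli), batch_size):
        out.append(backbone.features(stimuli.images[start : start + batch_size], gains))
    return np.concatenate(out, axis=0).astype(np.float64)


def train_readout(
    backbone: Backbone,
    task: ReadoutTask,
    train_set: StimulusSet,
    val_set: StimulusSet | None,
    config: TrainConfig,
) -> ReadoutModel:
    """Train only the two-unit head on frozen, unmanipulated backbone features."""
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if not np.any(train_set.categories == task.positive):
        raise ValueError(f"task emotion {task.positive!r} absent from training labels")
    feats = _extract_features(backbone, train_set)
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    z = (feats - mean) / std
    y = task.binary_labels(train_set.categories)

    if config.class_balance == "weighted":
        prevalence = np.array([np.mean(y == 0), np.mean(y == 1)])
        class_w = 1.0 / np.clip(prevalence, 1e-9, None)
        class_w /= class_w.mean()
        sample_w = class_w[y]
    else:
        sample_w = np.ones(len(y))

    rng = np.random.default_rng(config.seed)
    head = nn.Linear(z.shape[1], 2, rng)
    opt = nn.SGD([head], lr=config.learning_rate)
    history = []
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            logits = head.forward(z[idx].astype(np.float32), train=True)
            loss, grad = nn.cross_entropy_grad(logits, y[idx], sample_w[idx])
            head.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))

    return ReadoutModel(
        task=task,
        weights=head.w.astype(np.float64),
        bias=head.b.astype(np.float64),
        feature_mean=mean,
        feature_std=std,
        backbone_hash=backbone.frozen_hash(),
        config=config,
        loss_history=history,
    )


def evaluate(
    backbone: Backbone,
    readout: ReadoutModel,
    gains: GainConfig | None,
    test_set: StimulusSet,
    average: str = "positive",
) -> float:
    """Test F1 under a gain configuration (baseline gains reproduce plain F1)."""
    if readout.backbone_hash != backbone.frozen_hash():
        raise ValueError("readout was trained on a different backbone")
    feats = _extract_features(backbone, test_set, gains)
    pred = readout.predict(feats)
    y = readout.task.binary_labels(test_set.categories)
    if average == "macro":
        return macro_f1(pred, y)
    return f1_score(pred, y, positive=1)


def evaluate_cached(
    backbone: Backbone,
    readout: ReadoutModel,
    gains: GainConfig | None,
    cache: LayerCache,
    categories: np.ndarray,
    average: str = "positive",
) -> float:
    """Like :func:`evaluate` but resuming from cached pre-activations (used by
    the manipulation sweeps, where only one layer's gains change)."""
    if readout.backbone_hash != backbone.frozen_hash():
        raise ValueError("readout was trained on a different backbone")
    feats = backbone.features_from_cache(cache, gains).astype(np.float64)
    pred = readout.predict(feats)
    y = readout.task.binary_labels(categories)
    if average == "macro":
        return macro_f1(pred, y)
    return f1_score(pred, y, positive=1)


def predictions_frame(backbone: Backbone, readout: ReadoutModel,
                      gains: GainConfig | None, stimuli: StimulusSet) -> pd.DataFrame:
    feats = _extract_features(backbone, stimuli, gains)
    scores = readout.decision(feats)
    return pd.DataFrame(
        {
            "image_id": stimuli.image_ids,
            "score": scores[:, 1] - scores[:, 0],
            "predicted": np.argmax(scores, axis=1),
            "label": readout.task.binary_labels(stimuli.categories),
        }
    )
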