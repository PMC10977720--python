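"""Dataset splitting, head-only training, F1 scoring and gain-aware evaluation."""

import numpy as np
import pytest

from emosel.backbone import GainConfig, build_backbone, mini_cnn_spec
from emosel.readout import (
    ReadoutTask,
    TrainConfig,
    evaluate,
    f1_score,
    split_dataset,
    train_readout,
)
from emosel.stimuli import CATEGORIES, StimulusSet
from emosel.synth import SynthStimulusConfig, generate_affective_set


def _set_with_counts(counts, seed=0):
    rng = np.random.default_rng(seed)
    cats = sum(([c] * n for c, n in zip(CATEGORIES, counts)), [])
    n = len(cats)
    return StimulusSet(
        images=rng.normal(size=(n, 16, 16)).astype(np.float32),
        valence=np.full(n, 5.0),
        categories=np.array(cats, dtype=object),
        image_ids=[f"i{k:03d}" for k in range(n)],
    )


def test_split_100_images_gives_50_25_25():
    stimuli = _set_with_counts((40, 32, 28))
    train, val, test = split_dataset(stimuli, TrainConfig(seed=1))
    assert (len(train), len(val), len(test)) == (50, 25, 25)


def test_split_is_a_seeded_stratified_partition():
    stimuli = _set_with_counts((20, 16, 12))
    cfg = TrainConfig(seed=7)
    a = split_dataset(stimuli, cfg)
    b = split_dataset(stimuli, cfg)
    for x, y in zip(a, b):
        assert x.image_ids == y.image_ids  # identical seeds -> identical partition
    ids = [i for part in a for i in part.image_ids]
    assert sorted(ids) == sorted(stimuli.image_ids)  # union is the input, no dupes
    for part in a:  # stratification: every category present
        assert set(part.categories) == set(CATEGORIES)


def test_split_rejects_tiny_categories():
    with pytest.raises(ValueError):
        split_dataset(_set_with_counts((3, 10, 10)), TrainConfig())


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(split=(0.5, 0.3, 0.3))
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    # defaults follow the study protocol
    cfg = TrainConfig()
    assert cfg.learning_rate == pytest.approx(1e-3)
    assert cfg.epochs == 10 and cfg.batch_size == 128
    assert cfg.split == (0.5, 0.25, 0.25)


@pytest.mark.parametrize(
    "pred, labels, expected",
    [
        ([1, 0, 1], [1, 0, 1], 1.0),
        ([1, 1, 1, 1, 0, 0], [1, 1, 1, 0, 1, 0], 0.75),  # TP=3 FP=1 FN=1
        ([0, 0, 0], [1, 0, 0], 0.0),  # all-negative with a positive label
    ],
)
def test_f1_examples(pred, labels, expected):
    assert f1_score(pred, labels, positive=1) == pytest.approx(expected)


def test_f1_validation():
    with pytest.raises(ValueError):
        f1_score([1, 0], [1], positive=1)
    with pytest.raises(ValueError):
        f1_score([1, 0], [1, 0], positive=7)


def test_f1_matches_sklearn_on_random_pairs(rng):
    from sklearn.metrics import f1_score as sk_f1

    for _ in range(100):
        pred = rng.integers(0, 2, size=30)
        labels = rng.integers(0, 2, size=30)
        assert f1_score(pred, labels, positive=1) == pytest.approx(
            sk_f1(labels, pred, zero_division=0)
        )


@pytest.fixture(scope="module")
def trained_readout_setup(recovery):
    cfg = TrainConfig(seed=5, learning_rate=0.3, epochs=40, batch_size=32)
    train, val, test = split_dataset(recovery.set_a, cfg)
    readout = train_readout(recovery.backbone, ReadoutTask("pleasant"), train, val, cfg)
    return recovery.backbone, readout, val, test


def test_backbone_stays_frozen_and_loss_decreases(trained_readout_setup, recovery):
    backbone, readout, _, _ = trained_readout_setup
    assert readout.backbone_hash == backbone.frozen_hash()
    assert readout.loss_history[-1] <= readout.loss_history[0]


def test_separable_planted_features_reach_high_f1(trained_readout_setup):
    """With strongly planted category statistics, the head's validation F1 is
    high and agrees with an independent regularized linear classifier fit on
    the same frozen features."""
    from sklearn.linear_model import LogisticRegression

    backbone, readout, val, _ = trained_readout_setup
    val_f1 = evaluate(backbone, readout, None, val)
    assert val_f1 >= 0.9
    feats = backbone.features(val.images)
    y = readout.task.binary_labels(val.categories)
    oracle = LogisticRegression(max_iter=2000).fit(feats, y)
    from emosel.readout import f1_score as our_f1

    oracle_f1 = our_f1(oracle.predict(feats), y, positive=1)
    assert val_f1 >= oracle_f1 - 0.1


def test_shuffled_labels_give_chance_level_f1(recovery, rng):
    stimuli = recovery.set_a
    shuffled = StimulusSet(
        images=stimuli.images,
        valence=stimuli.valence,
        categories=stimuli.categories[rng.permutation(len(stimuli))],
        image_ids=stimuli.image_ids,
        dataset="shuffled",
    )
    cfg = TrainConfig(seed=5, learning_rate=0.3, epochs=40, batch_size=32)
    train, val, test = split_dataset(shuffled, cfg)
    readout = train_readout(recovery.backbone, ReadoutTask("pleasant"), train, val, cfg)
    f1 = evaluate(recovery.backbone, readout, None, test)
    # prevalence 1/3: a random classifier scores ~0.33-0.5 depending on rate
    assert f1 < 0.6


def test_evaluate_is_deterministic_and_baseline_equivalent(trained_readout_setup):
    backbone, readout, _, test = trained_readout_setup
    a = evaluate(backbone, readout, None, test)
    b = evaluate(backbone, readout, GainConfig.baseline(), test)
    c = evaluate(backbone, readout, GainConfig.baseline(), test)
    assert a == b == c


def test_evaluate_rejects_foreign_backbone(trained_readout_setup):
    _, readout, _, test = trained_readout_setup
    other = build_backbone(mini_cnn_spec(seed=12345))
    with pytest.raises(ValueError):
        evaluate(other, readout, None, test)


def test_lesioning_entire_layer_collapses_predictions(trained_readout_setup):
    backbone, readout, _, test = trained_readout_setup
    gains = GainConfig.lesion(backbone.neurons(1))
    f1 = evaluate(backbone, readout, gains, test)
    # all layer-1 maps are zero -> features constant -> a single predicted class
    feats = backbone.features(test.images, gains)
    assert len(np.unique(readout.predict(feats))) == 1
    y = readout.task.binary_labels(test.categories)
    from emosel.readout import f1_score as our_f1

    constant = readout.predict(feats)[0]
    assert f1 == pytest.approx(our_f1(np.full_like(y, constant), y, positive=1))


def test_train_readout_validation(recovery):
    cfg = TrainConfig(seed=0)
    train, val, _ = split_dataset(recovery.set_a, cfg)
    empty = train.subset(np.array([], dtype=int))
    with pytest.raises(ValueError):
        train_readout(recovery.backbone, ReadoutTask("pleasant"), empty, val, cfg)
    only_neutral = train.subset(np.flatnonzero(train.categories == "neutral"))
    with pytest.raises(ValueError):
        train_readout(recovery.backbone, ReadoutTask("pleasant"), only_neutral, val, cfg)
    with pytest.raises(ValueError):
        ReadoutTask("joyful")
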