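"""Percent-change arithmetic, sweep/lesion protocol, controls and the permutation test."""

import numpy as np
import pytest

import emosel.manipulation as manip
from emosel.manipulation import (
    DEFAULT_ALPHA_GRID,
    ManipulationPlan,
    ManipulationResult,
    compare_selective_vs_random,
    enhancement_sweep,
    percent_change,
    random_control,
    summarize,
)
from emosel.backbone import NeuronID


@pytest.mark.parametrize(
    "original, manipulated, expected",
    [
        (0.70, 0.73, 4.2857),
        (0.70, 0.56, -20.0),
        (0.63, 0.69, 9.5238),
        (0.55, 0.55, 0.0),
    ],
)
def test_percent_change(original, manipulated, expected):
    assert percent_change(original, manipulated) == pytest.approx(expected, abs=1e-3)


def test_percent_change_rejects_zero_baseline():
    with pytest.raises(ValueError):
        percent_change(0.0, 0.5)


def test_protocol_alpha_grid_has_51_points():
    assert len(DEFAULT_ALPHA_GRID) == 51
    assert DEFAULT_ALPHA_GRID[0] == 0.0 and DEFAULT_ALPHA_GRID[-1] == 5.0
    assert np.allclose(np.diff(DEFAULT_ALPHA_GRID), 0.1)


def test_plan_validation():
    t = frozenset({NeuronID(2, 0)})
    with pytest.raises(ValueError):
        ManipulationPlan("boost", 2, t)
    with pytest.raises(ValueError):
        ManipulationPlan("enhance", 1, t)  # target not in stated layer
    with pytest.raises(ValueError):
        ManipulationPlan("enhance", 2, t, alpha_grid=(0.0, 7.0))
    with pytest.raises(ValueError):
        ManipulationPlan("enhance", 2, t, n_controls=0)


def test_permutation_p_value_formula():
    # selective exceeds all 19 controls -> p = 1/20
    assert compare_selective_vs_random(100.0, list(range(19)), "enhance") == pytest.approx(0.05)
    # selective at the control median -> p about 0.5
    controls = list(np.linspace(-5, 5, 19))
    p = compare_selective_vs_random(0.0, controls, "lesion")
    assert 0.4 < p < 0.6
    with pytest.raises(ValueError):
        compare_selective_vs_random(1.0, [0.0, 0.1], "enhance")
    with pytest.raises(ValueError):
        compare_selective_vs_random(1.0, list(range(10)), "sideways")


def test_lesion_counts_controls_at_least_as_damaging():
    # lesion mode: controls <= selective are the extreme ones
    assert compare_selective_vs_random(-30.0, [-40.0] + [0.0] * 18, "lesion") == pytest.approx(2 / 20)


def _result(dataset, emotion, mode, orig, manip_f1, layer):
    return ManipulationResult(
        dataset=dataset, emotion=emotion, layer_index=layer, mode=mode,
        original_f1=orig, manipulated_f1=manip_f1,
        pct_change=percent_change(orig, manip_f1),
        alpha=1.0 if mode == "enhance" else -1.0,
    )


def test_summarize_reproduces_derived_enhancement_cells():
    """The printed F1 pairs (0.70, 0.73), (0.63, 0.69), (0.62, 0.69) give
    maximum enhancement changes 4.29%, 9.52% and 11.29%."""
    results = [
        _result("IAPS", "pleasant", "enhance", 0.70, 0.73, 13),
        _result("IAPS", "pleasant", "enhance", 0.70, 0.71, 3),  # weaker layer
        _result("IAPS", "neutral", "enhance", 0.63, 0.69, 11),
        _result("IAPS", "unpleasant", "enhance", 0.62, 0.69, 12),
    ]
    table = summarize(results).set_index("emotion")
    assert table.loc["pleasant", "max_abs_pct_change"] == pytest.approx(4.29)
    assert table.loc["pleasant", "layer_index"] == 13
    assert table.loc["neutral", "max_abs_pct_change"] == pytest.approx(9.52)
    assert table.loc["unpleasant", "max_abs_pct_change"] == pytest.approx(11.29)


def test_summarize_single_and_constant_cases():
    one = [_result("d", "neutral", "lesion", 0.5, 0.4, 2)]
    table = summarize(one)
    assert table["max_abs_pct_change"].iloc[0] == 20  # lesion rows rounded to integer
    const = [_result("d", "neutral", "lesion", 0.5, 0.4, layer) for layer in (1, 2, 3)]
    assert summarize(const)["max_abs_pct_change"].iloc[0] == 20
    with pytest.raises(ValueError):
        summarize([])


def test_selective_and_controls_share_the_protocol_code_path(monkeypatch, recovery):
    """Protocol symmetry: the selective run and every random control go
    through the same protocol function object."""
    calls = []
    real = manip._apply_protocol

    def spy(*args, **kwargs):
        calls.append(args[2])  # the target set argument
        return real(*args, **kwargs)

    monkeypatch.setattr(manip, "_apply_protocol", spy)
    from emosel.readout import ReadoutTask, TrainConfig, split_dataset, train_readout

    cfg = TrainConfig(seed=2, learning_rate=0.3, epochs=10, batch_size=32)
    train, val, test = split_dataset(recovery.set_a, cfg)
    readout = train_readout(recovery.backbone, ReadoutTask("pleasant"), train, val, cfg)
    targets = recovery.genuine["pleasant"]
    plan = ManipulationPlan("lesion", 1, targets, n_controls=5)
    manip.run_manipulation(recovery.backbone, readout, plan, val, test, "synthA", "pleasant")
    assert len(calls) == 1 + 5  # selective + each control
    assert calls[0] == targets and all(len(c) == len(targets) for c in calls[1:])
    assert all(c.isdisjoint(targets) for c in calls[1:])  # controls exclude targets


def test_random_control_seeded_and_validated(recovery, manipulation_outcome):
    from emosel.readout import ReadoutTask, TrainConfig, split_dataset, train_readout

    cfg = TrainConfig(seed=2, learning_rate=0.3, epochs=10, batch_size=32)
    train, val, test = split_dataset(recovery.set_a, cfg)
    readout = train_readout(recovery.backbone, ReadoutTask("pleasant"), train, val, cfg)
    a = random_control(recovery.backbone, readout, 1, 3, "lesion", 1, 42, val, test)
    b = random_control(recovery.backbone, readout, 1, 3, "lesion", 1, 42, val, test)
    assert a == b  # same seed -> same single draw
    c = random_control(recovery.backbone, readout, 1, 3, "lesion", 1, 43, val, test)
    assert len(c) == 1
    with pytest.raises(ValueError):
        random_control(recovery.backbone, readout, 1, 99, "lesion", 1, 0, val, test)


def test_enhancement_sweep_contracts(recovery, manipulation_outcome):
    curve = manipulation_outcome.sweep_curve
    # the alpha = 0 point anchors the curve at the unmanipulated baseline
    baseline_row = curve[curve["alpha"] == 0.0].iloc[0]
    assert baseline_row["test_f1"] == pytest.approx(manipulation_outcome.baseline_f1)
    # the validation optimum is never below the alpha = 0 validation point
    assert curve["val_f1"].max() >= baseline_row["val_f1"]
    assert len(curve) == 51


def test_enhancement_sweep_degenerate_grid(recovery):
    from emosel.readout import ReadoutTask, TrainConfig, evaluate, split_dataset, train_readout

    cfg = TrainConfig(seed=2, learning_rate=0.3, epochs=10, batch_size=32)
    train, val, test = split_dataset(recovery.set_a, cfg)
    readout = train_readout(recovery.backbone, ReadoutTask("pleasant"), train, val, cfg)
    targets = recovery.genuine["pleasant"]
    alpha, f1, curve = enhancement_sweep(recovery.backbone, readout, targets, [0.0], val, test)
    assert alpha == 0.0 and len(curve) == 1
    assert f1 == pytest.approx(evaluate(recovery.backbone, readout, None, test))
    with pytest.raises(ValueError):
        enhancement_sweep(recovery.backbone, readout, targets, [], val, test)
    with pytest.raises(ValueError):
        enhancement_sweep(recovery.backbone, readout, frozenset(), [0.0], val, test)
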