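"""Attention-enhancement and lesion experiments on emotion-selective neurons.

One layer is manipulated at a time.  Enhancement sweeps the gain offset alpha
over a grid (protocol: 0 to 5 in steps of 0.1), chooses the alpha maximizing
validation F1, and reports test F1 at that alpha; lesion sets alpha = -1 on
the targets.  Matched random controls draw equal-size neuron sets from the
same layer (excluding the targets) and run through the *same* protocol
function, so the comparison isolates the selectivity of the targeted set.
Selective-vs-control significance is a one-sided empirical permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import Backbone, GainConfig, NeuronID
from .readout import ReadoutModel, evaluate, evaluate_cached
from .stimuli import StimulusSet

#: The enhancement protocol's alpha grid: 0 to 5, step 0.1 (51 points).
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10))


@dataclass
class ManipulationPlan:
    mode: str  # "enhance" | "lesion"
    layer_index: int
    targets: frozenset[NeuronID]
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    n_controls: int = 20
    control_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("enhance", "lesion"):
            raise ValueError("mode must be 'enhance' or 'lesion'")
        if self.n_controls < 1:
            raise ValueError("need at least one control repetition")
        if any(t.layer_index != self.layer_index for t in self.targets):
            raise ValueError("targets must all lie in the stated layer")
        if self.mode == "enhance" and any(a < 0 or a > 5 for a in self.alpha_grid):
            raise ValueError("enhancement grid must lie within [0, 5]")


@dataclass
class ManipulationResult:
    dataset: str
    emotion: str
    layer_index: int
    mode: str
    original_f1: float
    manipulated_f1: float
    pct_change: float
    alpha: float
    control_changes: list[float] = field(default_factory=list)
    p_value: float | None = None


def percent_change(original: float, manipulated: float) -> float:
    """Signed percent change 100 * (manipulated - original) / original."""
    if original <= 0:
        raise ValueError("original performance must be > 0")
    return 100.0 * (manipulated - original) / original


def _apply_protocol(
    backbone: Backbone,
    readout: ReadoutModel,
    targets: frozenset[NeuronID],
    mode: str,
    alpha_grid,
    val_cache,
    test_cache,
    val_categories,
    test_categories,
) -> tuple[float, float, pd.DataFrame | None]:
    """Shared code path for selective targets and random controls.

    Returns (manipulated test F1, chosen alpha, sweep curve or None).
    """
    if not targets:
        raise ValueError("empty target set")
    if mode == "lesion":
        f1 = evaluate_cached(backbone, readout, GainConfig.lesion(targets),
                             test_cache, test_categories)
        return f1, -1.0, None
    rows = []
    for alpha in alpha_grid:
        gains = GainConfig.uniform(targets, float(alpha))
        rows.append(
            {
                "alpha": float(alpha),
                "val_f1": evaluate_cached(backbone, readout, gains, val_cache, val_categories),
                "test_f1": evaluate_cached(backbone, readout, gains, test_cache, test_categories),
            }
        )
    curve = pd.DataFrame(rows)
    best = int(np.argmax(curve["val_f1"].to_numpy()))  # ties -> smallest alpha
    return float(curve["test_f1"].iloc[best]), float(curve["alpha"].iloc[best]), curve


def _caches(backbone, layer_index, val_set, test_set):
    return (
        backbone.cache_preactivation(val_set.images, layer_index),
        backbone.cache_preactivation(test_set.images, layer_index),
    )


def enhancement_sweep(
    backbone: Backbone,
    readout: ReadoutModel,
    targets: frozenset[NeuronID],
    alpha_grid,
    val_set: StimulusSet,
    test_set: StimulusSet,
) -> tuple[float, float, pd.DataFrame]:
    """Sweep alpha on ``targets``; best alpha maximizes validation F1.

    Returns (best alpha, test F1 at best alpha, full curve).  With 0 in the
    grid the curve's alpha = 0 row equals the unmanipulated baseline.
    """
    alpha_grid = list(alpha_grid)
    if not alpha_grid:
        raise ValueError("empty alpha grid")
    if not targets:
        raise ValueError("empty target set")
    layer = next(iter(targets)).layer_index
    val_cache, test_cache = _caches(backbone, layer, val_set, test_set)
    f1, alpha, curve = _apply_protocol(
        backbone, readout, targets, "enhance", alpha_grid,
        val_cache, test_cache, val_set.categories, test_set.categories,
    )
    return alpha, f1, curve


def lesion_run(
    backbone: Backbone,
    readout: ReadoutModel,
    targets: frozenset[NeuronID],
    test_set: StimulusSet,
) -> float:
    """Test F1 with every target at alpha = -1 and all other gains at 0."""
    if not targets:
        raise ValueError("empty target set")
    return evaluate(backbone, readout, GainConfig.lesion(targets), test_set)


def random_control(
    backbone: Backbone,
    readout: ReadoutModel,
    layer_index: int,
    set_size: int,
    mode: str,
    n_controls: int,
    seed: int,
    val_set: StimulusSet,
    test_set: StimulusSet,
    exclude: frozenset[NeuronID] = frozenset(),
    alpha_grid=DEFAULT_ALPHA_GRID,
) -> list[float]:
    """Percent changes for ``n_controls`` random same-size neuron sets drawn
    uniformly from the layer's non-target neurons, run through the same
    protocol as the selective set."""
    candidates = [n for n in backbone.neurons(layer_index) if n not in exclude]
    if set_size > len(candidates):
        raise ValueError("control set size exceeds available neurons")
    rng = np.random.default_rng(seed)
    val_cache, test_cache = _caches(backbone, layer_index, val_set, test_set)
    original = evaluate_cached(backbone, readout, None, test_cache, test_set.categories)
    changes = []
    for _ in range(n_controls):
        picked = frozenset(candidates[i] for i in rng.choice(len(candidates), set_size, replace=False))
        f1, _, _ = _apply_protocol(
            backbone, readout, picked, mode, alpha_grid,
            val_cache, test_cache, val_set.categories, test_set.categories,
        )
        changes.append(percent_change(original, f1))
    return changes


def compare_selective_vs_random(
    selective_change: float, control_changes: list[float], mode: str
) -> float:
    """One-sided empirical permutation p-value.

    Enhance: p = (1 + #{controls >= selective}) / (R + 1); lesion counts
    controls <= selective (i.e. at least as damaging).
    """
    if len(control_changes) < 5:
        raise ValueError("need at least 5 control values")
    controls = np.asarray(control_changes)
    if mode == "enhance":
        extreme = int(np.sum(controls >= selective_change))
    elif mode == "lesion":
        extreme = int(np.sum(controls <= selective_change))
    else:
        raise ValueError("mode must be 'enhance' or 'lesion'")
    return (1 + extreme) / (len(controls) + 1)


def run_manipulation(
    backbone: Backbone,
    readout: ReadoutModel,
    plan: ManipulationPlan,
    val_set: StimulusSet,
    test_set: StimulusSet,
    dataset: str,
    emotion: str,
) -> ManipulationResult:
    """Full protocol for one (layer, emotion, mode): selective targets plus
    matched random controls and the permutation p-value."""
    val_cache, test_cache = _caches(backbone, plan.layer_index, val_set, test_set)
    original = evaluate_cached(backbone, readout, None, test_cache, test_set.categories)
    f1, alpha, _ = _apply_protocol(
        backbone, readout, plan.targets, plan.mode, plan.alpha_grid,
        val_cache, test_cache, val_set.categories, test_set.categories,
    )
    change = percent_change(original, f1)
    controls = random_control(
        backbone, readout, plan.layer_index, len(plan.targets), plan.mode,
        plan.n_controls, plan.control_seed, val_set, test_set,
        exclude=plan.targets, alpha_grid=plan.alpha_grid,
    )
    return ManipulationResult(
        dataset=dataset,
        emotion=emotion,
        layer_index=plan.layer_index,
        mode=plan.mode,
        original_f1=original,
        manipulated_f1=f1,
        pct_change=change,
        alpha=alpha,
        control_changes=controls,
        p_value=compare_selective_vs_random(change, controls, plan.mode),
    )


def results_frame(results: list[ManipulationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dataset": [r.dataset for r in results],
            "emotion": [r.emotion for r in results],
            "layer_index": [r.layer_index for r in results],
            "mode": [r.mode for r in results],
            "original_f1": [r.original_f1 for r in results],
            "manipulated_f1": [r.manipulated_f1 for r in results],
            "pct_change": [r.pct_change for r in results],
            "alpha": [r.alpha for r in results],
            "p_value": [r.p_value for r in results],
        }
    )


def summarize(results: list[ManipulationResult]) -> pd.DataFrame:
    """Maximum-magnitude percent change per (dataset, emotion, mode) across
    layers, with the layer where it is attained.  Enhancement magnitudes are
    rounded to 2 decimals in the export, lesion magnitudes to integers."""
    if not results:
        raise ValueError("no results to summarize")
    df = results_frame(results)
    rows = []
    for (dataset, emotion, mode), grp in df.groupby(["dataset", "emotion", "mode"], sort=True):
        i = grp["pct_change"].abs().idxmax()
        pct = df.loc[i, "pct_change"]
        rows.append(
            {
                "dataset": dataset,
                "emotion": emotion,
                "mode": mode,
                "max_abs_pct_change": round(abs(pct), 2) if mode == "enhance" else round(abs(pct)),
                "signed_pct_change": pct,
                "layer_index": int(df.loc[i, "layer_index"]),
                "original_f1": df.loc[i, "original_f1"],
                "manipulated_f1": df.loc[i, "manipulated_f1"],
            }
        )
    return pd.DataFrame(rows)
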