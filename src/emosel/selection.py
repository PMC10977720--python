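"""Identification of genuine emotion-selective neurons.

Per layer and per dataset, neurons are rank-ordered by SI and the lowest
(1 - keep_fraction) are removed; the retained neurons are partitioned by
their selective emotion.  Neurons selective for the same emotion in both
datasets form the "genuine" set, which is compared against the chance-level
overlap of two uniformly random subsets (hypergeometric mean n1*n2/N, or a
seeded Monte-Carlo estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import NeuronID
from .stimuli import CATEGORIES
from .tuning import SelectivityRecord


@dataclass
class SelectionResult:
    """Per layer x emotion: selected sets for each dataset and their overlap."""

    layer_index: int
    emotion: str
    set_a: frozenset[NeuronID]
    set_b: frozenset[NeuronID]
    genuine: frozenset[NeuronID]
    keep_fraction: float
    chance_expected_overlap: float
    observed_overlap: int


def threshold_by_si(
    records: list[SelectivityRecord], keep_fraction: float
) -> dict[str, set[NeuronID]]:
    """Retain the top ``keep_fraction`` of a layer's neurons by SI, partitioned
    by selective emotion.

    Retained count is floor(keep_fraction * K) with K the layer's neuron count
    (minimum 1 when any non-degenerate neuron exists); degenerate neurons are
    never retained.  Ties at the cut are broken by (SI desc, layer asc,
    filter asc).
    """
    if not records:
        raise ValueError("empty record list")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    layers = {r.neuron.layer_index for r in records}
    if len(layers) != 1:
        raise ValueError("records must all come from one layer")
    n_keep = max(int(np.floor(keep_fraction * len(records))), 1)
    alive = [r for r in records if not r.degenerate]
    alive.sort(key=lambda r: (-r.si, r.neuron.layer_index, r.neuron.filter_index))
    kept = alive[:n_keep]
    out: dict[str, set[NeuronID]] = {c: set() for c in CATEGORIES}
    for r in kept:
        out[r.selective_emotion].add(r.neuron)
    return out


def chance_overlap(
    n1: int,
    n2: int,
    population: int,
    method: str = "analytic",
    draws: int = 10_000,
    seed: int = 0,
) -> float | tuple[float, float]:
    """Expected overlap of two uniform random subsets of sizes n1, n2 from N.

    Analytic: hypergeometric mean n1*n2/N.  Monte-Carlo: (mean, sd) of
    |A intersect B| over ``draws`` seeded draws.
    """
    if population < 1:
        raise ValueError("population must be >= 1")
    if not (0 <= n1 <= population and 0 <= n2 <= population):
        raise ValueError("subset sizes must lie in [0, population]")
    if method == "analytic":
        return n1 * n2 / population
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        counts = np.empty(draws)
        for i in range(draws):
            a = rng.choice(population, size=n1, replace=False)
            b = rng.choice(population, size=n2, replace=False)
            counts[i] = len(np.intersect1d(a, b, assume_unique=True))
        return float(counts.mean()), float(counts.std(ddof=1))
    raise ValueError("method must be 'analytic' or 'montecarlo'")


def overlap_selection(
    records_a: list[SelectivityRecord],
    records_b: list[SelectivityRecord],
    keep_fraction: float,
) -> list[SelectionResult]:
    """Threshold each dataset's records per layer, intersect per emotion."""
    pop_a = {r.neuron for r in records_a}
    pop_b = {r.neuron for r in records_b}
    if pop_a != pop_b:
        raise ValueError("records must cover identical neuron populations")
    by_layer_a: dict[int, list[SelectivityRecord]] = {}
    by_layer_b: dict[int, list[SelectivityRecord]] = {}
    for r in records_a:
        by_layer_a.setdefault(r.neuron.layer_index, []).append(r)
    for r in records_b:
        by_layer_b.setdefault(r.neuron.layer_index, []).append(r)
    results = []
    for layer in sorted(by_layer_a):
        sel_a = threshold_by_si(by_layer_a[layer], keep_fraction)
        sel_b = threshold_by_si(by_layer_b[layer], keep_fraction)
        population = len(by_layer_a[layer])
        for emotion in CATEGORIES:
            genuine = sel_a[emotion] & sel_b[emotion]
            results.append(
                SelectionResult(
                    layer_index=layer,
                    emotion=emotion,
                    set_a=frozenset(sel_a[emotion]),
                    set_b=frozenset(sel_b[emotion]),
                    genuine=frozenset(genuine),
                    keep_fraction=keep_fraction,
                    chance_expected_overlap=chance_overlap(
                        len(sel_a[emotion]), len(sel_b[emotion]), population
                    ),
                    observed_overlap=len(genuine),
                )
            )
    return results


def trained_vs_random_comparison(
    selection_trained: list[SelectionResult],
    selection_random: list[SelectionResult],
) -> pd.DataFrame:
    """Side-by-side genuine-overlap counts for a trained vs a random backbone."""
    key = lambda results: {(r.layer_index, r.emotion): r for r in results}
    kt, kr = key(selection_trained), key(selection_random)
    if set(kt) != set(kr):
        raise ValueError("selections cover different layer/emotion sets")
    rows = []
    for layer, emotion in sorted(kt):
        t, r = kt[(layer, emotion)], kr[(layer, emotion)]
        rows.append(
            {
                "layer_index": layer,
                "emotion": emotion,
                "overlap_trained": t.observed_overlap,
                "overlap_random": r.observed_overlap,
                "difference": t.observed_overlap - r.observed_overlap,
            }
        )
    return pd.DataFrame(rows)


def threshold_sweep(
    records_a: list[SelectivityRecord],
    records_b: list[SelectivityRecord],
    keep_fractions,
    evaluate,
) -> pd.DataFrame:
    """Evaluate a callback over selections at each keep_fraction of a grid."""
    keep_fractions = list(keep_fractions)
    if not keep_fractions:
        raise ValueError("empty keep_fraction grid")
    rows = []
    for f in keep_fractions:
        selection = overlap_selection(records_a, records_b, f)
        rows.append({"keep_fraction": f, "performance": float(evaluate(selection))})
    return pd.DataFrame(rows)


def selection_to_json(results: list[SelectionResult]) -> dict:
    """layer -> emotion -> neuron lists + counts, for JSON export."""
    out: dict = {}
    for r in results:
        layer = out.setdefault(str(r.layer_index), {})
        layer[r.emotion] = {
            "set_a": sorted([n.filter_index for n in r.set_a]),
            "set_b": sorted([n.filter_index for n in r.set_b]),
            "genuine": sorted([n.filter_index for n in r.genuine]),
            "observed_overlap": r.observed_overlap,
            "chance_expected_overlap": r.chance_expected_overlap,
            "keep_fraction": r.keep_fraction,
        }
    return out


def selection_to_frame(results: list[SelectionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "layer_index": [r.layer_index for r in results],
            "emotion": [r.emotion for r in results],
            "n_set_a": [len(r.set_a) for r in results],
            "n_set_b": [len(r.set_b) for r in results],
            "observed_overlap": [r.observed_overlap for r in results],
            "chance_expected_overlap": [r.chance_expected_overlap for r in results],
            "keep_fraction": [r.keep_fraction for r in results],
        }
    )
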