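"""Per-neuron tuning values, tuning curves, d-prime values and the selectivity index.

For one neuron with spatially averaged responses p(n) over a dataset of N
images, the tuning value for emotion category e is the mean z-scored response
over the N_e images of that category:

    S_e = (1/N_e) sum_{n in e} (p(n) - p_hat) / sqrt((1/N) sum_n (p(n) - p_hat)^2)

with p_hat the grand-mean response.  The preferred category maximizes S_e.
The one-vs-rest discriminability for category e against the other two
categories o1, o2 is

    d'(e) = (m_e - (m_o1 + m_o2)/2) / sqrt((v_e + (v_o1 + v_o2)/2) / 2)

and the selectivity index SI is the largest of the three d' values; the
arg-max category is the neuron's selective emotion.  The printed form of the
d' denominator is typographically ambiguous, so the alternative grouping
sqrt((v_e + v_o1 + v_o2) / 2) is available behind ``denominator="flat"``;
variances are population variances by default (``variance="sample"`` for
N-1 normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import NeuronID, ResponseMatrix
from .stimuli import CATEGORIES


@dataclass
class TuningProfile:
    neuron: NeuronID
    tuning: dict[str, float]  # S_e per category
    preferred: str
    degenerate: bool


@dataclass
class SelectivityRecord:
    neuron: NeuronID
    dprime: dict[str, float]
    si: float
    selective_emotion: str
    degenerate: bool


def _check_labels(responses: ResponseMatrix, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    if len(labels) != responses.values.shape[0]:
        raise ValueError("labels must align with response-matrix rows")
    for c in CATEGORIES:
        if not np.any(labels == c):
            raise ValueError(f"category {c!r} missing from labels")
    return labels


def _argmax_category(values: dict[str, float]) -> str:
    # ties broken by the fixed order pleasant < neutral < unpleasant
    best = max(values[c] for c in CATEGORIES)
    for c in CATEGORIES:
        if values[c] == best:
            return c
    raise AssertionError("unreachable")


def tuning_values(responses: ResponseMatrix, labels) -> list[TuningProfile]:
    """Tuning values S_e and preferred category for every neuron of one layer."""
    labels = _check_labels(responses, labels)
    vals = responses.values
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 images")
    grand_mean = vals.mean(axis=0)
    centered = vals - grand_mean
    denom = np.sqrt(np.mean(centered**2, axis=0))  # population std over all images
    masks = {c: labels == c for c in CATEGORIES}
    profiles = []
    for k in range(vals.shape[1]):
        if denom[k] == 0:
            tuning = {c: 0.0 for c in CATEGORIES}
            profiles.append(
                TuningProfile(NeuronID(responses.layer_index, k), tuning,
                              preferred=_argmax_category(tuning), degenerate=True)
            )
            continue
        tuning = {c: float(centered[masks[c], k].mean() / denom[k]) for c in CATEGORIES}
        profiles.append(
            TuningProfile(NeuronID(responses.layer_index, k), tuning,
                          preferred=_argmax_category(tuning), degenerate=False)
        )
    return profiles


def dprime_si(
    responses: ResponseMatrix,
    labels,
    denominator: str = "pooled",
    variance: str = "population",
) -> list[SelectivityRecord]:
    """d' per category and selectivity index SI = max d' for every neuron.

    ``denominator="pooled"`` averages the two non-target variances before
    pooling with the target variance; ``"flat"`` sums all three and halves.
    """
    if denominator not in ("pooled", "flat"):
        raise ValueError("denominator must be 'pooled' or 'flat'")
    if variance not in ("population", "sample"):
        raise ValueError("variance must be 'population' or 'sample'")
    labels = _check_labels(responses, labels)
    vals = responses.values
    ddof = 0 if variance == "population" else 1
    masks = {c: labels == c for c in CATEGORIES}
    for c in CATEGORIES:
        if masks[c].sum() < 2:
            raise ValueError(f"category {c!r} needs at least 2 images")
    means = {c: vals[masks[c]].mean(axis=0) for c in CATEGORIES}
    varis = {c: vals[masks[c]].var(axis=0, ddof=ddof) for c in CATEGORIES}
    records = []
    for k in range(vals.shape[1]):
        degenerate = all(varis[c][k] == 0 for c in CATEGORIES) and (
            means[CATEGORIES[0]][k] == means[CATEGORIES[1]][k] == means[CATEGORIES[2]][k]
        )
        dp: dict[str, float] = {}
        for e in CATEGORIES:
            others = [c for c in CATEGORIES if c != e]
            num = means[e][k] - (means[others[0]][k] + means[others[1]][k]) / 2.0
            if denominator == "pooled":
                den = np.sqrt((varis[e][k] + (varis[others[0]][k] + varis[others[1]][k]) / 2.0) / 2.0)
            else:
                den = np.sqrt((varis[e][k] + varis[others[0]][k] + varis[others[1]][k]) / 2.0)
            if den == 0:
                dp[e] = 0.0 if num == 0 else float(np.sign(num) * np.inf)
            else:
                dp[e] = float(num / den)
        if degenerate:
            records.append(
                SelectivityRecord(NeuronID(responses.layer_index, k),
                                  {c: 0.0 for c in CATEGORIES}, 0.0, CATEGORIES[0], True)
            )
        else:
            emo = _argmax_category(dp)
            records.append(
                SelectivityRecord(NeuronID(responses.layer_index, k), dp,
                                  float(dp[emo]), emo, False)
            )
    return records


def top_k_images(responses: ResponseMatrix, neuron: NeuronID, k: int) -> list[str]:
    """Image ids ranked by descending response; ties broken by ascending id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if neuron.layer_index != responses.layer_index or not (
        0 <= neuron.filter_index < responses.n_filters
    ):
        raise ValueError(f"unknown neuron {neuron} for this response matrix")
    col = responses.column(neuron.filter_index)
    order = sorted(range(len(col)), key=lambda i: (-col[i], responses.image_ids[i]))
    return [responses.image_ids[i] for i in order[:k]]


def tuning_table(profiles: list[TuningProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "layer_index": [p.neuron.layer_index for p in profiles],
            "filter_index": [p.neuron.filter_index for p in profiles],
            **{f"S_{c}": [p.tuning[c] for p in profiles] for c in CATEGORIES},
            "preferred": [p.preferred for p in profiles],
            "degenerate": [p.degenerate for p in profiles],
        }
    )


def selectivity_table(records: list[SelectivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "layer_index": [r.neuron.layer_index for r in records],
            "filter_index": [r.neuron.filter_index for r in records],
            **{f"dprime_{c}": [r.dprime[c] for r in records] for c in CATEGORIES},
            "SI": [r.si for r in records],
            "selective_emotion": [r.selective_emotion for r in records],
            "degenerate": [r.degenerate for r in records],
        }
    )
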