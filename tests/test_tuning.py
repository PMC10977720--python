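"""Tuning values, d-prime/SI, and top-image ranking against independent oracles."""

import numpy as np
import pytest

from emosel.backbone import NeuronID, ResponseMatrix
from emosel.stimuli import CATEGORIES
from emosel.tuning import dprime_si, top_k_images, tuning_values

# ---------------------------------------------------------------------------
# Independent literal transcriptions of the tuning-value and d' definitions,
# written as explicit loops so they share no code with the implementation.
# ---------------------------------------------------------------------------


def oracle_tuning(column, labels):
    n = len(column)
    p_hat = sum(column) / n
    denom = (sum((x - p_hat) ** 2 for x in column) / n) ** 0.5
    out = {}
    for e in CATEGORIES:
        members = [column[i] for i in range(n) if labels[i] == e]
        out[e] = sum(x - p_hat for x in members) / len(members) / denom
    return out


def oracle_dprime(column, labels, pooled=True):
    stats = {}
    for e in CATEGORIES:
        xs = [column[i] for i in range(len(column)) if labels[i] == e]
        m = sum(xs) / len(xs)
        v = sum((x - m) ** 2 for x in xs) / len(xs)
        stats[e] = (m, v)
    out = {}
    for e in CATEGORIES:
        o1, o2 = [c for c in CATEGORIES if c != e]
        num = stats[e][0] - (stats[o1][0] + stats[o2][0]) / 2
        if pooled:
            den = ((stats[e][1] + (stats[o1][1] + stats[o2][1]) / 2) / 2) ** 0.5
        else:
            den = ((stats[e][1] + stats[o1][1] + stats[o2][1]) / 2) ** 0.5
        out[e] = num / den
    return out


def _matrix(values, layer=1, dataset="t"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    return ResponseMatrix(dataset, layer, values,
                         [f"img{i:03d}" for i in range(values.shape[0])])


LABELS6 = ["pleasant", "pleasant", "neutral", "neutral", "unpleasant", "unpleasant"]


def test_tuning_hand_example():
    # responses 1..6, 2 per category: grand mean 3.5, population sd
    # sqrt(35/12) = 1.7078251, so S = (-2, 0, +2)/1.7078251 = -/+ 1.1710801
    prof = tuning_values(_matrix([1, 2, 3, 4, 5, 6]), LABELS6)[0]
    assert prof.tuning["pleasant"] == pytest.approx(-1.1710801, abs=1e-6)
    assert prof.tuning["neutral"] == pytest.approx(0.0, abs=1e-12)
    assert prof.tuning["unpleasant"] == pytest.approx(1.1710801, abs=1e-6)
    assert prof.preferred == "unpleasant"
    assert not prof.degenerate


def test_tuning_degenerate_constant_column():
    prof = tuning_values(_matrix([2, 2, 2, 2, 2, 2]), LABELS6)[0]
    assert prof.degenerate
    assert all(v == 0.0 for v in prof.tuning.values())


def test_preference_is_argmax_of_tuning_curve():
    # largest tuning value defines the preferred emotion
    prof = tuning_values(_matrix([1, 1, 4, 4, 7, 7]), LABELS6)[0]
    ranked = sorted(CATEGORIES, key=lambda c: prof.tuning[c])
    assert prof.preferred == ranked[-1] == "unpleasant"


def test_dprime_hand_example():
    # category means (2, 0, 0), population variances (1, 1, 1) -> d'(pleasant) = 2
    s = np.sqrt(1.5)
    col = [2 - s, 2.0, 2 + s, -s, 0.0, s, -s, 0.0, s]
    labels = ["pleasant"] * 3 + ["neutral"] * 3 + ["unpleasant"] * 3
    rec = dprime_si(_matrix(col), labels)[0]
    assert rec.dprime["pleasant"] == pytest.approx(2.0, abs=1e-12)
    assert rec.si == pytest.approx(2.0, abs=1e-12)
    assert rec.selective_emotion == "pleasant"


def test_dprime_symmetric_distributions_give_zero():
    col = [1, 2, 3] * 3
    labels = ["pleasant"] * 3 + ["neutral"] * 3 + ["unpleasant"] * 3
    rec = dprime_si(_matrix(col), labels)[0]
    assert all(abs(v) < 1e-12 for v in rec.dprime.values())
    assert rec.si == 0.0


def test_dprime_invariant_to_swapping_nontarget_labels(rng):
    col = rng.normal(size=12)
    labels = np.array(["pleasant"] * 4 + ["neutral"] * 4 + ["unpleasant"] * 4, dtype=object)
    swapped = labels.copy()
    swapped[labels == "neutral"] = "unpleasant"
    swapped[labels == "unpleasant"] = "neutral"
    a = dprime_si(_matrix(col), labels)[0]
    b = dprime_si(_matrix(col), swapped)[0]
    assert a.dprime["pleasant"] == pytest.approx(b.dprime["pleasant"], abs=1e-12)


def test_oracle_equivalence_on_random_matrices(rng):
    """Implementation matches the literal formula transcription to 1e-12 on
    100 random 30x5 matrices, and category-size-weighted tuning values sum
    to zero for every non-degenerate neuron."""
    labels = np.array(
        ["pleasant"] * 10 + ["neutral"] * 10 + ["unpleasant"] * 10, dtype=object
    )
    sizes = {c: 10 for c in CATEGORIES}
    for _ in range(100):
        mat = _matrix(rng.normal(size=(30, 5)) ** 2)
        profs = tuning_values(mat, labels)
        recs_pooled = dprime_si(mat, labels, denominator="pooled")
        recs_flat = dprime_si(mat, labels, denominator="flat")
        for k in range(5):
            col = list(mat.values[:, k])
            ot = oracle_tuning(col, labels)
            od_pooled = oracle_dprime(col, labels, pooled=True)
            od_flat = oracle_dprime(col, labels, pooled=False)
            for e in CATEGORIES:
                assert profs[k].tuning[e] == pytest.approx(ot[e], abs=1e-12)
                assert recs_pooled[k].dprime[e] == pytest.approx(od_pooled[e], abs=1e-12)
                assert recs_flat[k].dprime[e] == pytest.approx(od_flat[e], abs=1e-12)
            conservation = sum(sizes[e] * profs[k].tuning[e] for e in CATEGORIES)
            assert abs(conservation) < 1e-9 * max(1.0, max(abs(v) for v in ot.values()))
            assert recs_pooled[k].si == max(recs_pooled[k].dprime.values())


def test_scale_and_shift_invariance(rng):
    col = rng.normal(size=15) ** 2
    labels = np.array(["pleasant"] * 5 + ["neutral"] * 5 + ["unpleasant"] * 5, dtype=object)
    base_t = tuning_values(_matrix(col), labels)[0]
    base_d = dprime_si(_matrix(col), labels)[0]
    for c, shift in [(3.7, 0.0), (1.0, 2.2), (0.4, -1.1)]:
        t = tuning_values(_matrix(c * col + shift), labels)[0]
        d = dprime_si(_matrix(c * col + shift), labels)[0]
        for e in CATEGORIES:
            if shift == 0.0:
                assert t.tuning[e] == pytest.approx(base_t.tuning[e], rel=1e-9)
            assert d.dprime[e] == pytest.approx(base_d.dprime[e], rel=1e-9)
    # additive shift alone leaves tuning values unchanged
    t = tuning_values(_matrix(col + 5.0), labels)[0]
    for e in CATEGORIES:
        assert t.tuning[e] == pytest.approx(base_t.tuning[e], rel=1e-9)


def test_label_validation():
    with pytest.raises(ValueError):
        tuning_values(_matrix([1, 2, 3]), ["pleasant", "pleasant", "neutral"])
    with pytest.raises(ValueError):
        dprime_si(_matrix([1, 2, 3, 4]),
                  ["pleasant", "pleasant", "neutral", "unpleasant"])  # < 2 per category
    with pytest.raises(ValueError):  # label/row misalignment
        tuning_values(_matrix([1, 2, 3, 4, 5, 6]), LABELS6[:5])


def test_top_k_images():
    mat = _matrix([[5.0], [1.0], [9.0]])
    mat.image_ids = ["a", "b", "c"]
    neuron = NeuronID(1, 0)
    assert top_k_images(mat, neuron, 2) == ["c", "a"]
    assert sorted(top_k_images(mat, neuron, 3)) == ["a", "b", "c"]
    assert top_k_images(mat, neuron, 100) == ["c", "a", "b"]  # k > N returns all
    tie = _matrix([[2.0], [2.0], [1.0]])
    tie.image_ids = ["z", "a", "m"]
    assert top_k_images(tie, NeuronID(1, 0), 2) == ["a", "z"]  # ties by ascending id
    with pytest.raises(ValueError):
        top_k_images(mat, NeuronID(2, 0), 1)
    with pytest.raises(ValueError):
        top_k_images(mat, neuron, 0)
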