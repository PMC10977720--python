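"""Seeded synthetic stimulus sets and backbones with known ground truth.

Real affective picture sets are access-restricted, so every pipeline stage is
exercised on synthetic grayscale images in which each emotion category is
linked to one low-level image statistic of controllable strength:

* pleasant   - a mean-luminance gradient across columns,
* neutral    - dominant high spatial frequency (checkerboard energy),
* unpleasant - horizontal orientation energy (horizontal grating).

The three patterns are mutually orthogonal (and orthogonal to the matched
detection kernels of the other categories), so a "planted" backbone whose
first-layer filters are matched kernels for one category's statistic responds
preferentially to that category, giving exact ground truth for
selection-recovery and manipulation experiments.  An image is

    noise_level * white_noise + effect_size * amplitude * pattern_category

with a per-image positive amplitude drawn from a unit-mean gamma
distribution; ``effect_size`` is the dimensionless separation of the category
statistic over the nuisance noise.  The default amplitude shape of 1
(exponential) makes affective strength vary widely across images, so every
category contains weak exemplars in which the category statistic is barely
expressed - mirroring the wide normative-rating spread of real affective
picture sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .backbone import Backbone, BackboneSpec, NeuronID, build_backbone, extract_responses
from .stimuli import CATEGORIES, DEFAULT_THRESHOLDS, StimulusSet, categorize_valence

#: Default valence distribution centers/spreads per category (1-9 scale),
#: truncated unimodal stand-ins for typical normative-rating histograms.
DEFAULT_VALENCE_PARAMS = {
    "unpleasant": (3.0, 0.8),
    "neutral": (5.0, 0.6),
    "pleasant": (7.0, 0.8),
}


@dataclass
class SynthStimulusConfig:
    image_size: int = 32
    n_per_category: int = 150
    valence_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VALENCE_PARAMS)
    )
    effect_size: float = 3.0
    noise_level: float = 1.0
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    unknown_half_width: float = 0.0
    amplitude_shape: float = 1.0  # gamma shape of the per-image amplitude (mean 1)
    seed: int = 0
    dataset: str = "synth"

    def __post_init__(self) -> None:
        low, high = self.thresholds
        if not 1.0 <= low < high <= 9.0:
            raise ValueError("invalid thresholds")
        if self.n_per_category < 1:
            raise ValueError("need at least one image per category")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")
        if self.amplitude_shape <= 0:
            raise ValueError("amplitude shape must be > 0")


def category_pattern(category: str, size: int) -> np.ndarray:
    """Unit-RMS pattern carrying the category-linked statistic."""
    i, j = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    if category == "pleasant":  # mean-luminance gradient across columns
        p = j - (size - 1) / 2.0
    elif category == "neutral":  # dominant high spatial frequency
        p = (-1.0) ** (i + j)
    elif category == "unpleasant":  # horizontal orientation energy, period 4
        p = np.cos(2 * np.pi * i / 4.0)
    else:
        raise ValueError(f"unknown category {category!r}")
    return (p / np.sqrt(np.mean(p**2))).astype(np.float64)


def matched_kernel(category: str, kernel_size: int) -> np.ndarray:
    """Zero-mean, unit-norm detection kernel matched to a category's pattern."""
    if kernel_size < 3:
        raise ValueError("matched kernels need kernel size >= 3")
    k = category_pattern(category, kernel_size)
    k = k - k.mean()
    norm = np.linalg.norm(k)
    if norm == 0:
        raise ValueError(f"degenerate matched kernel for {category!r}")
    return k / norm


def _truncnorm(rng, mean, sd, lo, hi, n):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_affective_set(config: SynthStimulusConfig) -> StimulusSet:
    """Seeded synthetic affective picture set with category-linked structure."""
    rng = np.random.default_rng(config.seed)
    low, high = config.thresholds
    hw = config.unknown_half_width
    bands = {
        "unpleasant": (1.0, low - hw),
        "neutral": (low + hw, high - hw),
        "pleasant": (high + hw, 9.0),
    }
    size = config.image_size
    images, valences, categories, ids = [], [], [], []
    for cat in CATEGORIES:
        mean, sd = config.valence_params[cat]
        lo, hi = bands[cat]
        if not lo < hi:
            raise ValueError("thresholds / unknown band leave an empty valence band")
        vals = _truncnorm(rng, mean, sd, lo, hi, config.n_per_category)
        pattern = category_pattern(cat, size)
        for m in range(config.n_per_category):
            amp = rng.gamma(config.amplitude_shape, 1.0 / config.amplitude_shape)
            img = config.noise_level * rng.standard_normal((size, size))
            img += config.effect_size * amp * pattern
            images.append(img)
            v = float(np.clip(vals[m], 1.0, 9.0))
            valences.append(v)
            categories.append(categorize_valence(v, config.thresholds, hw))
            ids.append(f"{config.dataset}_{cat[:2]}_{m:04d}")
    return StimulusSet(
        images=np.stack(images).astype(np.float32),
        valence=np.array(valences),
        categories=np.array(categories, dtype=object),
        image_ids=ids,
        dataset=config.dataset,
    )


def planted_statistics(stimuli: StimulusSet) -> np.ndarray:
    """The three generative statistics of each image (projection onto each
    category pattern).  Independent oracle features for separability checks."""
    size = stimuli.image_size[0]
    pats = np.stack([category_pattern(c, size) for c in CATEGORIES])
    return np.einsum("nij,cij->nc", stimuli.images.astype(np.float64), pats) / (size * size)


@dataclass
class PlantedBackboneSpec:
    """Mini-cnn with first-layer filters engineered per emotion.

    ``planted`` maps each emotion to the NeuronIDs (all in layer 1) whose
    kernels are replaced by matched detectors for that emotion's statistic.
    """

    backbone: BackboneSpec
    planted: dict[str, tuple[NeuronID, ...]]
    strength: float = 2.0

    def __post_init__(self) -> None:
        seen: set[NeuronID] = set()
        for emotion, neurons in self.planted.items():
            if emotion not in CATEGORIES:
                raise ValueError(f"unknown emotion {emotion!r}")
            for n in neurons:
                if n.layer_index != 1:
                    raise ValueError("planting is supported in layer 1 only")
                if not 0 <= n.filter_index < self.backbone.conv_channels[0]:
                    raise ValueError(f"planted neuron {n} does not exist")
                if n in seen:
                    raise ValueError("planted sets must be disjoint across emotions")
                seen.add(n)
        if self.strength < 0:
            raise ValueError("planting strength must be >= 0")

    def all_planted(self) -> dict[str, frozenset[NeuronID]]:
        return {e: frozenset(ns) for e, ns in self.planted.items()}


def plant_backbone(
    spec: PlantedBackboneSpec,
    stimulus_config: SynthStimulusConfig,
    verify: bool = True,
) -> Backbone:
    """Build the backbone and add matched kernels to the planted filters.

    A planted filter's kernel is replaced by the zero-mean matched detector
    scaled to norm ``strength``.  Strength 0 plants nothing (every filter
    keeps its random initialization), so a null-planted backbone is exactly
    the random build.  With nonzero strength the remaining (non-planted)
    layer-1 kernels are projected onto the orthogonal complement of the
    pattern subspace (the DC direction plus the three matched detectors):
    a purely random kernel has chance overlap with the category patterns and
    is therefore weakly - but genuinely - selective, which would make the
    planted sets only an approximate ground truth; the projection makes
    non-planted neurons exactly non-selective by construction.  When ``verify`` is
    on (and the configuration carries signal), a small probe set drawn from
    ``stimulus_config`` checks empirically that every planted neuron's mean
    response is highest for its own category.
    """
    backbone = build_backbone(spec.backbone)
    ksize = spec.backbone.kernel_sizes[0]
    if spec.strength > 0:
        planted_ids = {n.filter_index for ns in spec.planted.values() for n in ns}
        # orthonormal basis of the pattern subspace: DC, the three matched
        # detectors, and the quadrature phase of the periodic grating (local
        # patches of a global grating occur at every phase)
        i = np.arange(ksize)[:, None] * np.ones((1, ksize))
        quad = np.sin(2 * np.pi * i / 4.0).ravel()
        basis = [np.full(ksize * ksize, 1.0 / ksize)]
        basis += [matched_kernel(c, ksize).ravel() for c in CATEGORIES]
        if np.linalg.norm(quad) > 1e-9:
            basis.append(quad / np.linalg.norm(quad))
        q, _ = np.linalg.qr(np.stack(basis).T)
        for k in range(backbone.n_filters(1)):
            if k not in planted_ids:
                w = backbone.convs[0].w[k, 0].ravel().astype(np.float64)
                w -= q @ (q.T @ w)
                backbone.convs[0].w[k, 0] = w.reshape(ksize, ksize).astype(np.float32)
        for emotion, neurons in spec.planted.items():
            kern = matched_kernel(emotion, ksize) * spec.strength
            for n in neurons:
                backbone.convs[0].w[n.filter_index] = kern[None].astype(np.float32)
                backbone.convs[0].b[n.filter_index] = 0.0
    if verify and spec.strength > 0 and stimulus_config.effect_size > 0:
        probe_cfg = SynthStimulusConfig(
            image_size=stimulus_config.image_size,
            n_per_category=min(30, stimulus_config.n_per_category),
            effect_size=stimulus_config.effect_size,
            noise_level=stimulus_config.noise_level,
            thresholds=stimulus_config.thresholds,
            seed=(stimulus_config.seed + 9973) % 2**31,
            dataset="probe",
        )
        probe = generate_affective_set(probe_cfg)
        responses = extract_responses(backbone, probe, layers=[1])[1]
        for emotion, neurons in spec.planted.items():
            for n in neurons:
                col = responses.column(n.filter_index)
                means = {c: col[probe.categories == c].mean() for c in CATEGORIES}
                if max(means, key=lambda c: means[c]) != emotion:
                    raise RuntimeError(
                        f"planted neuron {n} does not respond maximally to {emotion}"
                    )
    return backbone


@dataclass
class ObjectTaskSet:
    """Labeled toy object-recognition set for backbone pre-training."""

    images: np.ndarray  # (N, H, W) float32
    labels: np.ndarray  # (N,) int64
    class_names: tuple[str, ...]


def _object_pattern(name: str, size: int, rng: np.random.Generator) -> np.ndarray:
    i, j = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    if name == "hgrating":
        return category_pattern("unpleasant", size)
    if name == "gradient":
        return category_pattern("pleasant", size)
    if name == "checker":
        return category_pattern("neutral", size)
    if name == "vgrating":
        p = np.cos(2 * np.pi * j / 4.0)
        return p / np.sqrt(np.mean(p**2))
    if name == "blob":
        ci, cj = rng.uniform(size * 0.3, size * 0.7, size=2)
        p = np.exp(-(((i - ci) ** 2 + (j - cj) ** 2) / (2 * (size / 6.0) ** 2)))
        return p / np.sqrt(np.mean(p**2))
    if name == "diag":
        p = np.cos(2 * np.pi * (i + j) / 8.0)
        return p / np.sqrt(np.mean(p**2))
    raise ValueError(f"unknown object class {name!r}")


OBJECT_CLASS_POOL = ("hgrating", "gradient", "checker", "blob", "vgrating", "diag")


def generate_object_task(
    n_classes: int = 4,
    n_per_class: int = 200,
    size: int = 32,
    seed: int = 0,
    signal: float = 2.0,
    noise: float = 1.0,
) -> ObjectTaskSet:
    """Toy object classes built from distinct composite textures/shapes.

    The first classes reuse the affective statistic families, so object
    pre-training aligns filters with the statistics that later distinguish
    the affective categories (a desk-scale analog of natural-image
    pre-training inducing emergent selectivity).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 object classes")
    if n_classes > len(OBJECT_CLASS_POOL):
        raise ValueError(f"at most {len(OBJECT_CLASS_POOL)} object classes supported")
    if n_per_class < 1 or size < 8:
        raise ValueError("degenerate task size")
    rng = np.random.default_rng(seed)
    names = OBJECT_CLASS_POOL[:n_classes]
    images, labels = [], []
    for label, name in enumerate(names):
        for _ in range(n_per_class):
            amp = abs(1.0 + 0.25 * rng.standard_normal())
            img = noise * rng.standard_normal((size, size))
            img += signal * amp * _object_pattern(name, size, rng)
            images.append(img)
            labels.append(label)
    return ObjectTaskSet(
        images=np.stack(images).astype(np.float32),
        labels=np.array(labels, dtype=np.int64),
        class_names=names,
    )
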