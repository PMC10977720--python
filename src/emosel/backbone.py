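"""Layered convolutional backbones with a gain-parameterized rectifier.

Every convolutional filter ("neuron") passes its output through

    x_lk = (1 + alpha_lk) * max(0, w_lk * x_{l-1})

where alpha is 0 at baseline, -1 for a lesion (output silenced) and > 0 for
attention-like gain enhancement.  Convolutional layers are addressed with a
1-based ``layer_index``; filters within a layer with a 0-based
``filter_index``.  The per-filter "neuronal response" to an image is the
spatial mean of its rectified, gain-scaled feature map.

Two architectures are built in: a ``vgg16-layout`` (13 convolutional layers
with the standard VGG filter counts, 224x224 3-channel input; grayscale images
are replicated across channels) and a desk-scale ``mini-cnn`` (single-channel
input, a few small layers) used throughout the synthetic experiments.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .stimuli import StimulusSet

#: Channel-replication normalization constants for grayscale input to the
#: vgg16 layout (mean/std applied after mapping pixels to [0, 1]).
VGG_INPUT_MEAN = 0.449
VGG_INPUT_STD = 0.226


@dataclass(frozen=True, order=True)
class NeuronID:
    """One convolutional filter: 1-based layer index, 0-based filter index."""

    layer_index: int
    filter_index: int


@dataclass
class BackboneSpec:
    """Architecture description sufficient to rebuild a backbone bit-for-bit."""

    architecture: str  # "vgg16-layout" | "mini-cnn"
    conv_channels: tuple[int, ...]
    kernel_sizes: tuple[int, ...]
    pool_after: tuple[int, ...]  # 1-based conv-layer indices followed by 2x2 maxpool
    input_size: int
    in_channels: int
    hidden_dim: int = 64
    n_outputs: int = 2
    seed: int | None = 0
    weight_file: str | None = None

    def __post_init__(self) -> None:
        if self.architecture not in ("vgg16-layout", "mini-cnn"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if len(self.conv_channels) < 2:
            raise ValueError("a backbone needs at least 2 convolutional layers")
        if any(c <= 0 for c in self.conv_channels):
            raise ValueError("filter counts must be positive")
        if len(self.kernel_sizes) != len(self.conv_channels):
            raise ValueError("kernel_sizes must align with conv_channels")
        if self.weight_file is None and self.seed is None:
            raise ValueError("random-weight builds must record a seed")


def mini_cnn_spec(
    conv_channels: tuple[int, ...] = (20, 24, 28),
    kernel_sizes: tuple[int, ...] = (5, 3, 3),
    input_size: int = 32,
    hidden_dim: int = 64,
    n_outputs: int = 2,
    seed: int = 0,
) -> BackboneSpec:
    """Desk-scale architecture: pool after every conv layer, 1-channel input."""
    return BackboneSpec(
        architecture="mini-cnn",
        conv_channels=conv_channels,
        kernel_sizes=kernel_sizes,
        pool_after=tuple(range(1, len(conv_channels) + 1)),
        input_size=input_size,
        in_channels=1,
        hidden_dim=hidden_dim,
        n_outputs=n_outputs,
        seed=seed,
    )


def vgg16_spec(seed: int | None = 0, weight_file: str | None = None,
               hidden_dim: int = 64, n_outputs: int = 2) -> BackboneSpec:
    """The 13-convolutional-layer VGG-16 layout (224x224, 3-channel input)."""
    return BackboneSpec(
        architecture="vgg16-layout",
        conv_channels=(64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512),
        kernel_sizes=(3,) * 13,
        pool_after=(2, 4, 7, 10, 13),
        input_size=224,
        in_channels=3,
        hidden_dim=hidden_dim,
        n_outputs=n_outputs,
        seed=seed,
        weight_file=weight_file,
    )


@dataclass
class GainConfig:
    """Per-neuron rectifier slope offsets alpha; alpha >= -1 everywhere.

    ``default_alpha`` applies to every neuron without an explicit override.
    alpha = 0 is baseline, alpha = -1 a lesion, alpha > 0 enhancement.
    """

    default_alpha: float = 0.0
    overrides: dict[NeuronID, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.default_alpha < -1:
            raise ValueError("alpha must be >= -1")
        for nid, a in self.overrides.items():
            if a < -1:
                raise ValueError(f"alpha must be >= -1 (neuron {nid}: {a})")

    @classmethod
    def baseline(cls) -> "GainConfig":
        return cls()

    @classmethod
    def uniform(cls, neurons, alpha: float) -> "GainConfig":
        return cls(overrides={n: alpha for n in neurons})

    @classmethod
    def lesion(cls, neurons) -> "GainConfig":
        return cls.uniform(neurons, -1.0)

    def alpha_vector(self, layer_index: int, n_filters: int) -> np.ndarray:
        vec = np.full(n_filters, self.default_alpha, dtype=np.float32)
        for nid, a in self.overrides.items():
            if nid.layer_index == layer_index:
                vec[nid.filter_index] = a
        return vec

    def validate_for(self, backbone: "Backbone") -> None:
        for nid in self.overrides:
            if not 1 <= nid.layer_index <= backbone.n_conv_layers:
                raise ValueError(f"gain references nonexistent layer {nid.layer_index}")
            if not 0 <= nid.filter_index < backbone.n_filters(nid.layer_index):
                raise ValueError(f"gain references nonexistent filter {nid}")


@dataclass
class ResponseMatrix:
    """Images x neurons table of spatially averaged filter responses for one layer."""

    dataset: str
    layer_index: int
    values: np.ndarray  # (N images, K filters), float64
    image_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.image_ids):
            raise ValueError("values must be (n_images, n_filters) aligned to image_ids")

    @property
    def n_filters(self) -> int:
        return self.values.shape[1]

    def column(self, filter_index: int) -> np.ndarray:
        return self.values[:, filter_index]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"L{self.layer_index}F{k}" for k in range(self.n_filters)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "image_id", self.image_ids)
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class LayerCache:
    """Pre-activation maps of one conv layer, for fast re-evaluation under
    different gains at or after that layer (earlier layers held at baseline)."""

    layer_index: int
    preact: np.ndarray  # (N, K, H, W) pre-rectifier maps


class Backbone:
    """A built convolutional backbone; construct via :func:`build_backbone`."""

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed if spec.seed is not None else 0)
        self.convs: list[nn.Conv2d] = []
        self.relus: list[nn.GainReLU] = []
        in_ch = spec.in_channels
        size = spec.input_size
        for i, (ch, k) in enumerate(zip(spec.conv_channels, spec.kernel_sizes), start=1):
            self.convs.append(nn.Conv2d(in_ch, ch, k, rng))
            self.relus.append(nn.GainReLU(ch))
            in_ch = ch
            if i in spec.pool_after:
                size //= 2
        self.pools = {i: nn.MaxPool2() for i in spec.pool_after}
        self.flatten = nn.Flatten()
        self.flat_dim = in_ch * size * size
        self.fc1 = nn.Linear(self.flat_dim, spec.hidden_dim, rng)
        self.fc1_relu = nn.ReLU()
        self.fc_out = nn.Linear(spec.hidden_dim, spec.n_outputs, rng)
        if spec.weight_file is not None:
            self._load_weights(spec.weight_file)

    # ---- structure -------------------------------------------------------
    @property
    def n_conv_layers(self) -> int:
        return len(self.convs)

    def n_filters(self, layer_index: int) -> int:
        return self.convs[layer_index - 1].out_channels

    def neurons(self, layer_index: int) -> list[NeuronID]:
        return [NeuronID(layer_index, k) for k in range(self.n_filters(layer_index))]

    def expected_input(self, images: np.ndarray) -> np.ndarray:
        """Grayscale (N, H, W) stack -> network input (N, C, H, W)."""
        if images.ndim != 3:
            raise ValueError("expected a (N, H, W) grayscale stack")
        if images.shape[1] != self.spec.input_size or images.shape[2] != self.spec.input_size:
            raise ValueError(
                f"images are {images.shape[1]}x{images.shape[2]}, backbone expects "
                f"{self.spec.input_size}x{self.spec.input_size}"
            )
        x = images.astype(np.float32)[:, None]
        if self.spec.in_channels == 3:
            # replicate the grayscale channel and normalize with fixed constants
            lo, hi = x.min(), x.max()
            if hi > lo:
                x = (x - lo) / (hi - lo)
            x = (x - VGG_INPUT_MEAN) / VGG_INPUT_STD
            x = np.repeat(x, 3, axis=1)
        return x

    # ---- forward passes --------------------------------------------------
    def _set_gains(self, gains: GainConfig | None) -> None:
        for i, relu in enumerate(self.relus, start=1):
            if gains is None:
                relu.alpha[...] = 0.0
            else:
                relu.alpha[...] = gains.alpha_vector(i, relu.alpha.shape[0])

    def conv_maps(
        self,
        images: np.ndarray,
        gains: GainConfig | None = None,
        upto: int | None = None,
        train: bool = False,
    ) -> dict[int, np.ndarray]:
        """Run the convolutional stack, returning each layer's rectified,
        gain-scaled feature maps (before pooling), keyed by layer_index."""
        if gains is not None:
            gains.validate_for(self)
        self._set_gains(gains)
        x = self.expected_input(images)
        maps: dict[int, np.ndarray] = {}
        for i in range(1, self.n_conv_layers + 1):
            pre = self.convs[i - 1].forward(x, train=train)
            post = self.relus[i - 1].forward(pre, train=train)
            maps[i] = post
            x = self.pools[i].forward(post, train=train) if i in self.pools else post
            if upto is not None and i == upto:
                break
        maps["_tail"] = x  # type: ignore[index]
        return maps

    def features(self, images: np.ndarray, gains: GainConfig | None = None,
                 train: bool = False) -> np.ndarray:
        """Penultimate representation: flatten -> fc1 -> ReLU."""
        maps = self.conv_maps(images, gains, train=train)
        x = self.flatten.forward(maps["_tail"], train=train)  # type: ignore[index]
        return self.fc1_relu.forward(self.fc1.forward(x, train=train), train=train)

    def logits(self, images: np.ndarray, gains: GainConfig | None = None,
               train: bool = False) -> np.ndarray:
        return self.fc_out.forward(self.features(images, gains, train=train), train=train)

    # ---- cached partial forward (manipulation speed-up) ------------------
    def cache_preactivation(self, images: np.ndarray, layer_index: int) -> LayerCache:
        """Pre-rectifier maps at ``layer_index`` with baseline gains upstream."""
        self._set_gains(None)
        x = self.expected_input(images)
        for i in range(1, layer_index):
            pre = self.convs[i - 1].forward(x)
            post = self.relus[i - 1].forward(pre)
            x = self.pools[i].forward(post) if i in self.pools else post
        pre = self.convs[layer_index - 1].forward(x)
        return LayerCache(layer_index=layer_index, preact=pre)

    def features_from_cache(self, cache: LayerCache, gains: GainConfig | None = None) -> np.ndarray:
        """Resume the forward pass from cached pre-activations under ``gains``.

        Gains may modify the cached layer and any later layer; earlier layers
        are implicitly at baseline (as they were when the cache was built).
        """
        if gains is not None:
            gains.validate_for(self)
        self._set_gains(gains)
        i = cache.layer_index
        post = self.relus[i - 1].forward(cache.preact)
        x = self.pools[i].forward(post) if i in self.pools else post
        for j in range(i + 1, self.n_conv_layers + 1):
            pre = self.convs[j - 1].forward(x)
            post = self.relus[j - 1].forward(pre)
            x = self.pools[j].forward(post) if j in self.pools else post
        x = self.flatten.forward(x)
        return self.fc1_relu.forward(self.fc1.forward(x))

    # ---- training (toy object pre-training) ------------------------------
    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        epochs: int = 10,
        lr: float = 0.003,
        batch_size: int = 64,
        momentum: float = 0.9,
        seed: int = 0,
        clip_norm: float = 5.0,
    ) -> list[float]:
        """Train the whole network (convs + head) with softmax cross-entropy.

        Returns the per-epoch mean training loss.  Used to pre-train the
        mini-cnn on the toy object task; gains stay at baseline throughout.
        Gradients are clipped to a global norm to keep momentum SGD stable.
        """
        layers = self.convs + [self.fc1, self.fc_out]
        opt = nn.SGD(layers, lr=lr, momentum=momentum, clip_norm=clip_norm)
        rng = np.random.default_rng(seed)
        n = len(images)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                opt.zero_grad()
                logits = self.logits(images[idx], train=True)
                loss, grad = nn.cross_entropy_grad(logits, labels[idx])
                self._backward(grad)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history

    def _backward(self, grad_logits: np.ndarray) -> None:
        g = self.fc_out.backward(grad_logits)
        g = self.fc1.backward(self.fc1_relu.backward(g))
        g = self.flatten.backward(g)
        for i in range(self.n_conv_layers, 0, -1):
            if i in self.pools:
                g = self.pools[i].backward(g)
            g = self.relus[i - 1].backward(g)
            g = self.convs[i - 1].backward(g)

    def predict(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, len(images), batch_size):
            out.append(np.argmax(self.logits(images[start : start + batch_size]), axis=1))
        return np.concatenate(out)

    # ---- weights ---------------------------------------------------------
    def weight_arrays(self, include_head: bool = True) -> dict[str, np.ndarray]:
        arrays = {}
        for i, conv in enumerate(self.convs, start=1):
            arrays[f"conv{i}_w"] = conv.w
            arrays[f"conv{i}_b"] = conv.b
        if include_head:
            arrays["fc1_w"] = self.fc1.w
            arrays["fc1_b"] = self.fc1.b
            arrays["fc_out_w"] = self.fc_out.w
            arrays["fc_out_b"] = self.fc_out.b
        return arrays

    def frozen_hash(self) -> str:
        """SHA-256 over every non-readout weight (convs + fc1)."""
        h = hashlib.sha256()
        for name, arr in sorted(self.weight_arrays(include_head=True).items()):
            if name.startswith("fc_out"):
                continue
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def save_weights(self, path: str) -> None:
        """Single-container format: npz archive with a JSON layout manifest."""
        manifest = json.dumps(
            {
                "architecture": self.spec.architecture,
                "conv_channels": list(self.spec.conv_channels),
                "kernel_sizes": list(self.spec.kernel_sizes),
                "pool_after": list(self.spec.pool_after),
                "input_size": self.spec.input_size,
                "in_channels": self.spec.in_channels,
                "hidden_dim": self.spec.hidden_dim,
                "n_outputs": self.spec.n_outputs,
            }
        )
        np.savez(path, manifest=np.frombuffer(manifest.encode(), dtype=np.uint8),
                 **self.weight_arrays())

    def _load_weights(self, path: str) -> None:
        with np.load(path) as data:
            manifest = json.loads(bytes(data["manifest"]).decode())
            if (
                manifest["conv_channels"] != list(self.spec.conv_channels)
                or manifest["kernel_sizes"] != list(self.spec.kernel_sizes)
                or manifest["in_channels"] != self.spec.in_channels
            ):
                raise ValueError("weight file layout does not match the backbone spec")
            for i, conv in enumerate(self.convs, start=1):
                conv.w = data[f"conv{i}_w"].astype(np.float32)
                conv.b = data[f"conv{i}_b"].astype(np.float32)
            if "fc1_w" in data and data["fc1_w"].shape == self.fc1.w.shape:
                self.fc1.w = data["fc1_w"].astype(np.float32)
                self.fc1.b = data["fc1_b"].astype(np.float32)
            if "fc_out_w" in data and data["fc_out_w"].shape == self.fc_out.w.shape:
                self.fc_out.w = data["fc_out_w"].astype(np.float32)
                self.fc_out.b = data["fc_out_b"].astype(np.float32)


def build_backbone(spec: BackboneSpec) -> Backbone:
    """Construct a backbone; random-weight builds are bit-reproducible by seed."""
    return Backbone(spec)


def gain_forward(
    backbone: Backbone,
    images: np.ndarray,
    gains: GainConfig | None = None,
) -> dict[int, np.ndarray]:
    """Forward pass returning each conv layer's gain-scaled activation maps."""
    maps = backbone.conv_maps(images, gains)
    maps.pop("_tail", None)  # type: ignore[arg-type]
    return maps


def mean_filter_response(activation_map: np.ndarray) -> float:
    """Spatial mean of one filter's W x H activation map for one image."""
    arr = np.asarray(activation_map, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty activation map")
    return float(arr.mean())


def extract_responses(
    backbone: Backbone,
    stimuli: StimulusSet,
    layers: list[int] | None = None,
    gains: GainConfig | None = None,
    batch_size: int = 128,
) -> dict[int, ResponseMatrix]:
    """Spatially averaged per-filter responses to every image, one matrix per layer."""
    if len(stimuli) == 0:
        raise ValueError("empty stimulus set")
    if layers is None:
        layers = list(range(1, backbone.n_conv_layers + 1))
    for layer in layers:
        if not 1 <= layer <= backbone.n_conv_layers:
            raise ValueError(f"layer {layer} out of range")
    chunks: dict[int, list[np.ndarray]] = {layer: [] for layer in layers}
    for start in range(0, len(stimuli), batch_size):
        maps = backbone.conv_maps(stimuli.images[start : start + batch_size], gains,
                                  upto=max(layers))
        for layer in layers:
            chunks[layer].append(maps[layer].mean(axis=(2, 3)))
    return {
        layer: ResponseMatrix(
            dataset=stimuli.dataset,
            layer_index=layer,
            values=np.concatenate(chunks[layer], axis=0),
            image_ids=list(stimuli.image_ids),
        )
        for layer in layers
    }
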