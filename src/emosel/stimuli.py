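"""Affective stimulus sets: grayscale images with valence ratings and emotion categories.

The canonical in-memory container is :class:`StimulusSet`.  On disk a set is a
directory of PNG files plus a ``metadata.csv`` table with columns
``image_id, valence, category, dataset`` (the layout the backbone module reads).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Fixed category order used everywhere for argmax tie-breaking.
CATEGORIES = ("pleasant", "neutral", "unpleasant")

#: Valence thresholds separating unpleasant/neutral and neutral/pleasant (1-9 scale).
DEFAULT_THRESHOLDS = (4.3, 6.0)


@dataclass
class StimulusSet:
    """Ordered collection of grayscale images with valence ratings and labels.

    Attributes
    ----------
    images : float32 array, shape (N, H, W)
        Grayscale pixel intensities (arbitrary units; not necessarily in [0, 1]).
    valence : float array, shape (N,)
        Normative valence rating per image, 1 (most unpleasant) to 9 (most pleasant).
    categories : object array of str, shape (N,)
        One of ``pleasant | neutral | unpleasant`` per image.
    image_ids : list of str
        Unique identifiers aligned to rows.
    dataset : str
        Tag naming the picture set (e.g. ``"synthA"``).
    """

    images: np.ndarray
    valence: np.ndarray
    categories: np.ndarray
    image_ids: list[str]
    dataset: str = "unnamed"

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.valence) == len(self.categories) == len(self.image_ids) == n):
            raise ValueError("images, valence, categories and image_ids must align")
        if len(set(self.image_ids)) != n:
            raise ValueError("image_ids must be unique")
        self.images = np.asarray(self.images, dtype=np.float32)
        self.valence = np.asarray(self.valence, dtype=np.float64)
        self.categories = np.asarray(self.categories, dtype=object)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_size(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def subset(self, index: np.ndarray) -> "StimulusSet":
        index = np.asarray(index)
        return StimulusSet(
            images=self.images[index],
            valence=self.valence[index],
            categories=self.categories[index],
            image_ids=[self.image_ids[i] for i in index],
            dataset=self.dataset,
        )

    def category_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.categories == c)) for c in CATEGORIES}

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": self.image_ids,
                "valence": self.valence,
                "category": self.categories,
                "dataset": self.dataset,
            }
        )


def categorize_valence(
    rating: float,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    unknown_half_width: float = 0.0,
) -> str:
    """Map a valence rating to ``unpleasant | neutral | pleasant | unknown``.

    Ratings within ``unknown_half_width`` of either threshold are labelled
    ``"unknown"`` (soft-threshold band; such images are removed downstream).
    With half-width 0 an exact-threshold rating falls in the lower band.
    """
    low, high = thresholds
    if not low < high:
        raise ValueError("thresholds must satisfy low < high")
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"valence rating {rating} outside [1, 9]")
    if unknown_half_width > 0 and (
        abs(rating - low) <= unknown_half_width or abs(rating - high) <= unknown_half_width
    ):
        return "unknown"
    if rating <= low:
        return "unpleasant"
    if rating <= high:
        return "neutral"
    return "pleasant"


def save_stimulus_set(stimuli: StimulusSet, directory: str) -> None:
    """Write a set as 16-bit grayscale PNGs plus metadata.csv.

    Pixel floats are affinely mapped to the 16-bit range; the (scale, offset)
    pair is stored in the metadata so loading round-trips to quantization
    accuracy.
    """
    from PIL import Image

    os.makedirs(directory, exist_ok=True)
    lo = float(stimuli.images.min())
    hi = float(stimuli.images.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    meta = stimuli.metadata()
    meta["pixel_scale"] = scale
    meta["pixel_offset"] = lo
    for i, image_id in enumerate(stimuli.image_ids):
        arr = np.round((stimuli.images[i] - lo) / scale).astype(np.uint16)
        Image.fromarray(arr).save(os.path.join(directory, f"{image_id}.png"))
    meta.to_csv(os.path.join(directory, "metadata.csv"), index=False)


def load_stimulus_set(directory: str) -> StimulusSet:
    """Read the directory-of-PNGs + metadata.csv layout back into a StimulusSet."""
    from PIL import Image

    meta = pd.read_csv(os.path.join(directory, "metadata.csv"))
    images = []
    for _, row in meta.iterrows():
        arr = np.asarray(
            Image.open(os.path.join(directory, f"{row.image_id}.png")), dtype=np.float64
        )
        images.append(arr * row.pixel_scale + row.pixel_offset)
    return StimulusSet(
        images=np.stack(images).astype(np.float32),
        valence=meta["valence"].to_numpy(),
        categories=meta["category"].to_numpy(dtype=object),
        image_ids=[str(x) for x in meta["image_id"]],
        dataset=str(meta["dataset"].iloc[0]),
    )
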