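"""Rotation-based training-set augmentation and final resizing.

Augmentation is applied strictly after the train/test split: each training
image contributes itself plus its 90-degree and 180-degree rotations, all
inheriting the source label.  Rotations by multiples of 90 degrees are exact
pixel permutations (no interpolation), so no grayscale information is lost.
The encoded images are finally resized to 100x100 before entering the CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["AugmentedSet", "rotate", "augment_training_set", "resize"]


@dataclass
class AugmentedSet:
    """Originals plus their two rotations, with per-image provenance."""

    originals: List[np.ndarray]
    rotated90: List[np.ndarray]
    rotated180: List[np.ndarray]
    labels: List[int]
    #: (source id, transform tag) per output image, in `images()` order
    provenance: List[Tuple[str, str]] = field(default_factory=list)

    def images(self) -> List[np.ndarray]:
        return list(self.originals) + list(self.rotated90) + list(self.rotated180)

    def all_labels(self) -> List[int]:
        return list(self.labels) * 3

    @property
    def total(self) -> int:
        return 3 * len(self.originals)

    @property
    def n_augmented(self) -> int:
        return 2 * len(self.originals)


def rotate(image: np.ndarray, angle: int) -> np.ndarray:
    """Rotate by exactly 90 or 180 degrees (clockwise), losslessly.

    90 degrees maps pixel (r, c) to (c, H-1-r); other angles are rejected.
    """
    img = np.asarray(image)
    if angle == 90:
        return np.rot90(img, k=-1).copy()
    if angle == 180:
        return np.rot90(img, k=2).copy()
    raise ValueError(f"unsupported angle {angle}; only 90 and 180 are allowed")


def augment_training_set(images: Sequence[np.ndarray], labels: Sequence[int],
                         ids: Sequence[str] | None = None) -> AugmentedSet:
    """Triple the training set with 90/180-degree rotations."""
    if len(images) == 0:
        raise ValueError("empty training list")
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    ids = list(ids) if ids is not None else [f"img{i}" for i in range(len(images))]
    r90 = [rotate(im, 90) for im in images]
    r180 = [rotate(im, 180) for im in images]
    prov = ([(i, "orig") for i in ids] + [(i, "rot90") for i in ids]
            + [(i, "rot180") for i in ids])
    return AugmentedSet(originals=list(images), rotated90=r90, rotated180=r180,
                        labels=list(labels), provenance=prov)


def resize(image: np.ndarray, target: Tuple[int, int] = (100, 100)) -> np.ndarray:
    """Bilinear resize to ``target`` (default 100x100), 8-bit output.

    A same-size input is returned bit-identically.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.shape == tuple(target):
        return img.astype(np.uint8).copy()
    out = _sk_resize(img.astype(float), target, order=1, anti_aliasing=False,
                     preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
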