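"""Electronic biopsy and cheat-sheet frame encoding.

The "cheat sheet" encodes two classical attributes of the ROI as
easy-to-recognise artificial patterns before the image reaches the
classifier: two uniform 10-pixel-wide frames are drawn around the ROI crop,
the outer one carrying the electronic-biopsy mean (the average of randomly
sampled ROI pixels) and the inner one carrying the ROI radius.  For a normal,
low-variation ROI the outer frame is nearly indistinguishable from the
tissue; for a bright lesion it stands out, giving the network an explicit,
trivially learnable summary of the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BiopsyResult", "EncodedImage", "FRAME_WIDTH",
           "electronic_biopsy", "encode_frames", "strip_frames"]

FRAME_WIDTH = 10  # pixels, per frame


@dataclass
class BiopsyResult:
    """Mean of randomly sampled ROI pixels (grayscale units)."""

    mean_value: float
    n_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mean_value <= 255:
            raise ValueError("mean_value must lie in [0, 255]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class EncodedImage:
    """ROI crop wrapped in the two attribute frames."""

    pixels: np.ndarray
    frame_width: int
    outer_value: int
    inner_value: int


def electronic_biopsy(roi_pixels: np.ndarray, n_samples: int | None = None,
                      seed: int = 0, enumerate_all: bool = False) -> BiopsyResult:
    """Sample ROI pixels uniformly at random with replacement and average.

    ``n_samples`` defaults to 10% of the ROI pixel count (at least 100).
    With ``enumerate_all`` the sampling is replaced by a full enumeration,
    giving the exact arithmetic mean of the ROI (used in tests and whenever
    an unbiased deterministic value is preferred).
    """
    roi = np.asarray(roi_pixels, dtype=float).ravel()
    if roi.size == 0:
        raise ValueError("empty ROI: cannot take a biopsy")
    if enumerate_all:
        return BiopsyResult(mean_value=float(roi.mean()), n_samples=roi.size,
                            seed=None)
    if n_samples is None:
        n_samples = max(100, roi.size // 10)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, roi.size, size=n_samples)
    return BiopsyResult(mean_value=float(roi[picks].mean()),
                        n_samples=int(n_samples), seed=seed)


def encode_frames(roi_crop: np.ndarray, biopsy: BiopsyResult,
                  radius: float) -> EncodedImage:
    """Draw the two 10-pixel frames (outer: biopsy mean, inner: radius).

    The frames are appended around the crop, growing each axis by 40 pixels;
    the interior stays bit-identical to the crop.  Values are rounded to the
    nearest integer and clipped to the 8-bit range.
    """
    crop = np.asarray(roi_crop)
    if crop.size == 0:
        raise ValueError("empty crop")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    outer = int(np.clip(np.rint(biopsy.mean_value), 0, 255))
    inner = int(np.clip(np.rint(radius), 0, 255))
    framed = np.pad(crop.astype(np.uint8), FRAME_WIDTH, constant_values=inner)
    framed = np.pad(framed, FRAME_WIDTH, constant_values=outer)
    return EncodedImage(pixels=framed, frame_width=FRAME_WIDTH,
                        outer_value=outer, inner_value=inner)


def strip_frames(encoded: EncodedImage) -> np.ndarray:
    """Remove both frames, recovering the original crop exactly."""
    k = 2 * encoded.frame_width
    return encoded.pixels[k:-k, k:-k]
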