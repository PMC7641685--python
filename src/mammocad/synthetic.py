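"""Synthetic MLO-view mammogram phantoms with known ground truth.

The phantoms are deliberately schematic: a semi-elliptical breast region
attached to one vertical image edge, a brighter triangular pectoral-muscle
wedge in the upper corner of that edge, a dark gap, an optional bright label
strip near the opposite edge, and (for abnormal phantoms) a Gaussian-profile
lesion blob.  That is exactly the structure the preprocessing stages key on —
side attachment, relative brightness of the pectoral wedge, the dark gap
separating background artifacts — so every downstream stage can be tested
against analytic ground truth without any external data.  They are not meant
to look like real mammographic texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .mias import MammogramRecord

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one phantom.

    Intensities are 8-bit grayscale units.  ``pectoral_fraction`` is the
    fraction of the image width covered by the pectoral wedge at the top row.
    """

    image_size: int = 256
    side: str = "left"
    has_lesion: bool = False
    lesion_radius: float = 12.0
    lesion_intensity: float = 230.0
    pectoral_fraction: float = 0.25
    artifact: bool = True
    noise_sd: float = 5.0
    breast_intensity: float = 150.0
    pectoral_intensity: float = 220.0
    artifact_intensity: float = 200.0

    def validate(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not 0 <= self.lesion_intensity <= 255:
            raise ValueError("lesion_intensity must lie in [0, 255]")
        if not 0 < self.pectoral_fraction < 0.5:
            raise ValueError("pectoral_fraction must lie in (0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.lesion_radius <= 0:
            raise ValueError("lesion_radius must be positive")


@dataclass
class PhantomTruth:
    """Ground-truth masks and lesion location for one phantom."""

    breast_mask: np.ndarray
    pectoral_mask: np.ndarray
    artifact_bounds: Optional[Tuple[int, int, int, int]]  # r0, r1, c0, c1 half-open
    lesion_center: Optional[Tuple[int, int]] = None       # (row, col)
    lesion_radius: Optional[float] = None


@dataclass
class CohortSpec:
    """Class composition and reproducibility seed of a phantom cohort.

    The default composition mirrors the MIAS database: 208 normal, 63 benign
    and 51 malignant mammograms (322 in total).  Benign and malignant phantoms
    both carry lesions; malignant lesions are larger and brighter so that the
    binary separation is learnable at desk scale.
    """

    n_normal: int = 208
    n_benign: int = 63
    n_malignant: int = 51
    seed: int = 0
    image_size: int = 256
    noise_sd: float = 5.0
    benign_radius: Tuple[float, float] = (7.0, 11.0)
    benign_intensity: Tuple[float, float] = (185.0, 205.0)
    malignant_radius: Tuple[float, float] = (15.0, 21.0)
    malignant_intensity: Tuple[float, float] = (240.0, 255.0)

    def validate(self) -> None:
        if min(self.n_normal, self.n_benign, self.n_malignant) < 0:
            raise ValueError("class counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_normal + self.n_benign + self.n_malignant


def generate_phantom(spec: PhantomSpec, seed: int = 0,
                     record_id: str = "phantom") -> Tuple[MammogramRecord, PhantomTruth]:
    """Render one phantom; deterministic for a fixed spec and seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.image_size
    r = np.arange(n)[:, None].astype(float)
    c = np.arange(n)[None, :].astype(float)
    # work in left-side coordinates, mirror at the end if needed
    img = np.zeros((n, n), dtype=float)

    # breast: half-ellipse attached to the left edge
    a, b = 0.45 * n, 0.55 * n
    breast = ((r - n / 2) / a) ** 2 + (c / b) ** 2 <= 1.0
    img[breast] = spec.breast_intensity

    # pectoral wedge: triangle at the top-left corner, brighter than breast
    pw = spec.pectoral_fraction * n          # width along the top row
    ph = 1.5 * pw                            # height along the left edge
    pectoral = (c / pw + r / ph) < 1.0
    img[pectoral] = spec.pectoral_intensity

    # background label strip near the opposite edge, beyond the dark gap
    artifact_bounds = None
    if spec.artifact:
        r0, r1 = int(0.30 * n), int(0.50 * n)
        c0, c1 = int(0.86 * n), int(0.92 * n)
        img[r0:r1, c0:c1] = spec.artifact_intensity
        artifact_bounds = (r0, r1, c0, c1)

    lesion_center = None
    if spec.has_lesion:
        # keep the lesion inside the breast, clear of the wedge and the edge
        row = int(rng.uniform(0.45 * n, 0.70 * n))
        col = int(rng.uniform(0.12 * n, 0.35 * n))
        lesion_center = (row, col)
        d2 = (r - row) ** 2 + (c - col) ** 2
        sigma = spec.lesion_radius / 2.0
        blob = spec.breast_intensity + (spec.lesion_intensity - spec.breast_intensity) \
            * np.exp(-d2 / (2.0 * sigma ** 2))
        img = np.where(breast & (blob > img), blob, img)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = PhantomTruth(breast_mask=breast & ~pectoral, pectoral_mask=pectoral,
                         artifact_bounds=artifact_bounds,
                         lesion_center=lesion_center,
                         lesion_radius=spec.lesion_radius if spec.has_lesion else None)
    if spec.side == "right":
        img = img[:, ::-1].copy()
        truth.breast_mask = truth.breast_mask[:, ::-1].copy()
        truth.pectoral_mask = truth.pectoral_mask[:, ::-1].copy()
        if truth.artifact_bounds is not None:
            r0, r1, c0, c1 = truth.artifact_bounds
            truth.artifact_bounds = (r0, r1, n - c1, n - c0)
        if truth.lesion_center is not None:
            row, col = truth.lesion_center
            truth.lesion_center = (row, n - 1 - col)

    record = MammogramRecord(id=record_id, pixels=img, side=spec.side)
    return record, truth


def generate_cohort(spec: CohortSpec) -> Tuple[List[MammogramRecord], pd.DataFrame,
                                               List[PhantomTruth]]:
    """Generate a phantom cohort with the exact requested class composition.

    Returns the records, a metadata table (columns: id, class, and the
    ground-truth lesion x, y, radius — blank for normals), and the per-record
    ground truth.  Identical specs produce identical cohorts.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    classes = (["normal"] * spec.n_normal + ["benign"] * spec.n_benign
               + ["malignant"] * spec.n_malignant)
    records: List[MammogramRecord] = []
    truths: List[PhantomTruth] = []
    rows = []
    child_seeds = root.generate_state(2 * len(classes) + 1) % (2 ** 31)
    for i, cls in enumerate(classes):
        rng = np.random.default_rng(child_seeds[2 * i])
        side = "left" if rng.random() < 0.5 else "right"
        ps = PhantomSpec(image_size=spec.image_size, side=side,
                         noise_sd=spec.noise_sd)
        if cls == "benign":
            ps.has_lesion = True
            ps.lesion_radius = rng.uniform(*spec.benign_radius)
            ps.lesion_intensity = rng.uniform(*spec.benign_intensity)
        elif cls == "malignant":
            ps.has_lesion = True
            ps.lesion_radius = rng.uniform(*spec.malignant_radius)
            ps.lesion_intensity = rng.uniform(*spec.malignant_intensity)
        rec_id = f"syn{i + 1:03d}"
        rec, truth = generate_phantom(ps, seed=int(child_seeds[2 * i + 1]),
                                      record_id=rec_id)
        rec.class_raw = cls
        records.append(rec)
        truths.append(truth)
        row = {"id": rec_id, "class": cls}
        if truth.lesion_center is not None:
            row["x"] = float(truth.lesion_center[1])
            row["y"] = float(truth.lesion_center[0])
            row["radius"] = float(truth.lesion_radius)
        rows.append(row)
    meta = pd.DataFrame(rows, columns=["id", "class", "x", "y", "radius"])
    return records, meta, truths
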