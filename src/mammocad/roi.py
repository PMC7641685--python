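"""Automatic ROI determination for MLO mammograms.

The stages mirror the classical preprocessing chain for MLO views:

1. ``detect_side`` — decide whether the breast is attached to the left or
   right image edge (LMLO vs RMLO) from outer column-band intensities.
2. ``remove_artifacts`` — zero everything on the far side of the dark gap
   that separates the breast from background label strips.
3. ``remove_pectoral`` — zero the dense, bright pectoral-muscle wedge that
   touches the top corner on the breast side.
4. ``initial_roi`` — the tight bounding rectangle of the remaining tissue
   (the IROI); the length of its longer side is recorded as R.
5. ``refine_roi`` — zoom into the IROI using a three-gene chromosome
   (H, W, CutVal): the refined window has height H*R and width W*R and is
   placed so as to maximise the number of pixels at or above CutVal.
6. ``ga_optimize`` — a small generational genetic algorithm over the
   chromosome, with a pluggable fitness function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.segmentation import flood

__all__ = [
    "Chromosome",
    "ROIResult",
    "GAConfig",
    "UndecidableSideError",
    "EmptyROIError",
    "detect_side",
    "remove_artifacts",
    "remove_pectoral",
    "initial_roi",
    "refine_roi",
    "extract_roi",
    "ga_optimize",
    "lesion_overlap_fitness",
]


class UndecidableSideError(ValueError):
    """Raised when laterality cannot be decided (e.g. a blank image)."""


class EmptyROIError(ValueError):
    """Raised when no tissue remains to enclose."""


@dataclass(frozen=True)
class Chromosome:
    """GA genome: height and width factors (fractions of R) and a pixel
    threshold used to score candidate window placements."""

    H: float
    W: float
    CutVal: float

    def __post_init__(self) -> None:
        if not 0 < self.H <= 1 or not 0 < self.W <= 1:
            raise ValueError("H and W must lie in (0, 1]")
        if not 0 <= self.CutVal <= 255:
            raise ValueError("CutVal must lie in [0, 255]")


@dataclass
class ROIResult:
    """A rectangular ROI: 0-based half-open ``bounds`` (r0, r1, c0, c1),
    its center, half the larger side as ``radius``, and the IROI long side R.
    ``fallback`` marks a refinement that found no pixel above CutVal and
    returned the IROI unchanged."""

    bounds: Tuple[int, int, int, int]
    center: Tuple[float, float]
    radius: float
    R: int
    fallback: bool = False

    @property
    def height(self) -> int:
        return self.bounds[1] - self.bounds[0]

    @property
    def width(self) -> int:
        return self.bounds[3] - self.bounds[2]

    def crop(self, image: np.ndarray) -> np.ndarray:
        r0, r1, c0, c1 = self.bounds
        return image[r0:r1, c0:c1]


def detect_side(image: np.ndarray, band_fraction: float = 0.1) -> str:
    """Return the vertical edge ('left'/'right') the breast is attached to.

    Compares summed intensity over equal-width outer column bands, so adding
    a constant to every pixel cannot change the answer.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        raise UndecidableSideError("blank image: laterality undecidable")
    band = max(1, int(round(band_fraction * img.shape[1])))
    left = img[:, :band].sum()
    right = img[:, -band:].sum()
    if left == right:
        raise UndecidableSideError("outer bands equally bright")
    return "left" if left > right else "right"


def remove_artifacts(image: np.ndarray, side: str,
                     gap_fraction: float = 0.1) -> np.ndarray:
    """Zero everything beyond the dark gap on the far side of the breast.

    A column belongs to the dark gap when its maximum intensity falls below
    ``gap_fraction`` of the image maximum.  The contiguous run of bright
    columns attached to the breast edge is kept; all columns beyond it are
    cleared, which removes label strips and edge artifacts in one pass.
    """
    img = np.asarray(image).copy()
    if img.max() == 0:
        return img
    colmax = img.max(axis=0)
    thr = gap_fraction * float(img.max())
    bright = colmax >= thr
    order = np.arange(img.shape[1]) if side == "left" else \
        np.arange(img.shape[1])[::-1]
    # walk from the breast edge; stop at the first dark (gap) column
    keep_until = 0
    for k, c in enumerate(order):
        if not bright[c]:
            break
        keep_until = k + 1
    far = order[keep_until:]
    img[:, far] = 0
    return img


def remove_pectoral(image: np.ndarray, side: str) -> np.ndarray:
    """Zero the bright pectoral wedge touching the breast-side top corner.

    The threshold is Otsu's, computed on the nonzero pixels of the top-quarter
    breast-side region (the wedge is denser, hence brighter, than breast
    tissue); the removed set is the connected component of above-threshold
    pixels that contains the corner.
    """
    img = np.asarray(image).copy()
    n_rows, n_cols = img.shape
    corner = (0, 0) if side == "left" else (0, n_cols - 1)
    region = img[: max(1, n_rows // 4)]
    region = region[:, : n_cols // 2] if side == "left" else region[:, n_cols // 2:]
    # exclude (possibly noisy) background so Otsu separates wedge from breast
    vals = region[region > 0.1 * img.max()]
    if vals.size == 0 or np.unique(vals).size < 2:
        return img
    thr = threshold_otsu(vals)
    mask = img > thr
    if not mask[corner]:
        return img
    wedge = flood(mask, corner)
    img[wedge] = 0
    return img


def initial_roi(image: np.ndarray) -> ROIResult:
    """Tight bounding rectangle of all nonzero pixels (the IROI)."""
    img = np.asarray(image)
    rows = np.flatnonzero(img.any(axis=1))
    cols = np.flatnonzero(img.any(axis=0))
    if rows.size == 0:
        raise EmptyROIError("no nonzero pixels to enclose")
    r0, r1 = int(rows[0]), int(rows[-1] + 1)
    c0, c1 = int(cols[0]), int(cols[-1] + 1)
    h, w = r1 - r0, c1 - c0
    return ROIResult(bounds=(r0, r1, c0, c1),
                     center=((r0 + r1) / 2.0, (c0 + c1) / 2.0),
                     radius=max(1.0, max(h, w) / 2.0), R=max(h, w))


def refine_roi(image: np.ndarray, iroi: ROIResult, chrom: Chromosome,
               stride: int = 4) -> ROIResult:
    """Zoom into the IROI with the chromosome's window.

    The refined window measures ``H*R`` by ``W*R`` pixels (clipped to the
    IROI) and is slid over the IROI on a stride grid; the placement that
    maximises the count of pixels >= CutVal wins (first maximum in scan
    order on ties).  If no pixel reaches CutVal the IROI is returned with
    ``fallback=True``.
    """
    img = np.asarray(image)
    r0, r1, c0, c1 = iroi.bounds
    sub = img[r0:r1, c0:c1]
    h = min(sub.shape[0], max(1, int(round(chrom.H * iroi.R))))
    w = min(sub.shape[1], max(1, int(round(chrom.W * iroi.R))))

    hot = (sub >= chrom.CutVal)
    if not hot.any():
        return replace(iroi, fallback=True)

    # integral image of the hot mask -> O(1) window counts
    S = np.zeros((sub.shape[0] + 1, sub.shape[1] + 1), dtype=np.int64)
    S[1:, 1:] = np.cumsum(np.cumsum(hot, axis=0), axis=1)
    rr = np.arange(0, sub.shape[0] - h + 1, stride)
    if rr[-1] != sub.shape[0] - h:
        rr = np.append(rr, sub.shape[0] - h)
    cc = np.arange(0, sub.shape[1] - w + 1, stride)
    if cc[-1] != sub.shape[1] - w:
        cc = np.append(cc, sub.shape[1] - w)
    counts = (S[np.ix_(rr + h, cc + w)] - S[np.ix_(rr, cc + w)]
              - S[np.ix_(rr + h, cc)] + S[np.ix_(rr, cc)])
    best = np.unravel_index(int(np.argmax(counts)), counts.shape)
    br, bc = int(rr[best[0]]), int(cc[best[1]])
    bounds = (r0 + br, r0 + br + h, c0 + bc, c0 + bc + w)
    return ROIResult(bounds=bounds,
                     center=((bounds[0] + bounds[1]) / 2.0,
                             (bounds[2] + bounds[3]) / 2.0),
                     radius=max(1.0, max(h, w) / 2.0), R=iroi.R)


def extract_roi(image: np.ndarray, chrom: Optional[Chromosome] = None,
                stride: int = 4) -> Tuple[np.ndarray, ROIResult]:
    """Full chain: side -> artifacts -> pectoral -> IROI -> refine -> crop."""
    side = detect_side(image)
    clean = remove_pectoral(remove_artifacts(image, side), side)
    iroi = initial_roi(clean)
    result = refine_roi(clean, iroi, chrom, stride=stride) if chrom else iroi
    return result.crop(clean), result


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass
class GAConfig:
    """Generational GA settings.  Genes are handled on a normalised [0, 1]
    scale (CutVal divided by 255); mutation is per-gene Gaussian on that
    scale, clipped back into bounds."""

    population: int = 30
    generations: int = 20
    tournament: int = 3
    crossover_rate: float = 0.8
    mutation_sd: float = 0.1
    elitism: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.population < 1:
            raise ValueError("population must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


_GENE_LO = np.array([0.01, 0.01, 0.0])
_GENE_HI = np.array([1.0, 1.0, 1.0])


def _to_chrom(g: np.ndarray) -> Chromosome:
    return Chromosome(H=float(g[0]), W=float(g[1]), CutVal=float(g[2] * 255.0))


def ga_optimize(fitness_fn: Callable[[Chromosome], float],
                config: Optional[GAConfig] = None) -> Chromosome:
    """Maximise ``fitness_fn`` over chromosomes; reproducible under the seed.

    Tournament selection, uniform crossover, Gaussian mutation and elitism;
    the best chromosome ever seen is returned.
    """
    config = config or GAConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    pop = rng.uniform(_GENE_LO, _GENE_HI, size=(config.population, 3))
    fits = np.array([fitness_fn(_to_chrom(g)) for g in pop], dtype=float)
    best_g, best_f = pop[int(np.argmax(fits))].copy(), float(fits.max())

    for _ in range(config.generations):
        order = np.argsort(-fits)
        nxt = [pop[i].copy() for i in order[: config.elitism]]
        while len(nxt) < config.population:
            t = min(config.tournament, config.population)
            # two independent tournaments for the two parents
            ia = rng.integers(0, config.population, t)
            ib = rng.integers(0, config.population, t)
            pa = pop[ia[np.argmax(fits[ia])]].copy()
            pb = pop[ib[np.argmax(fits[ib])]].copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(3) < 0.5
                pa[swap], pb[swap] = pb[swap], pa[swap].copy()
            child = pa
            child += rng.normal(0.0, config.mutation_sd, 3)
            nxt.append(np.clip(child, _GENE_LO, _GENE_HI))
        pop = np.array(nxt[: config.population])
        fits = np.array([fitness_fn(_to_chrom(g)) for g in pop], dtype=float)
        if fits.max() > best_f:
            best_f = float(fits.max())
            best_g = pop[int(np.argmax(fits))].copy()
    return _to_chrom(best_g)


def lesion_overlap_fitness(preprocessed, stride: int = 8):
    """Fast surrogate fitness for phantom cohorts.

    ``preprocessed`` is a sequence of (clean_image, iroi, lesion_center)
    triples for abnormal phantoms; the fitness of a chromosome is the
    fraction of phantoms whose refined ROI contains the planted lesion
    center, minus a small area penalty that rewards actual zooming.
    """
    def fitness(chrom: Chromosome) -> float:
        hits = 0
        for clean, iroi, (lr, lc) in preprocessed:
            res = refine_roi(clean, iroi, chrom, stride=stride)
            r0, r1, c0, c1 = res.bounds
            if r0 <= lr < r1 and c0 <= lc < c1 and not res.fallback:
                hits += 1
        area_penalty = 0.05 * chrom.H * chrom.W
        return hits / max(1, len(preprocessed)) - area_penalty
    return fitness
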