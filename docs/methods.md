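# Methods

## Problem and model

The package classifies MLO-view mammograms into negative (normal or benign)
and positive (malignant). The central idea is *feature-encoding
augmentation*: instead of relying on the CNN to discover that a bright,
compact region is suspicious, two classical attributes of the automatically
extracted ROI are drawn into the image itself as artificial patterns — two
uniform 10-pixel frames around the ROI whose gray values are the rounded
electronic-biopsy mean (outer) and the rounded ROI radius (inner). For a
flat, normal ROI the outer frame blends into the tissue; for a lesion it
contrasts sharply, so the frames act as a cheat sheet the network can read
with trivial filters. Rotation augmentation (90°/180°, exact pixel
permutations) supplies additional labelled samples without interpolation
artifacts.

## ROI extraction

The chain is: side detection → artifact removal → pectoral removal → IROI →
chromosome-driven refinement.

* **Side detection** compares summed intensities of equal-width outer column
  bands (default 10% of the width). Using equal widths makes the decision
  invariant to adding a constant to every pixel. A blank image raises.
* **Artifact removal** keeps the contiguous run of "bright" columns attached
  to the breast edge and zeroes everything beyond it. A column is dark when
  its maximum falls below 10% of the image maximum; this is the dark gap
  that separates breast tissue from background label strips.
* **Pectoral removal** computes an Otsu threshold on the top-quarter,
  breast-side region, excluding pixels below 10% of the image maximum so
  noisy background cannot drag the threshold between background and tissue
  (it must fall between breast tissue and the denser, brighter wedge). The
  removed set is the connected component of above-threshold pixels
  containing the breast-side top corner, found by flood fill.
* **IROI** is the tight bounding rectangle of the remaining nonzero pixels;
  its longer side is recorded as *R* and half the longer side of any ROI
  rectangle serves as its radius.
* **Refinement** interprets the chromosome (*H*, *W*, CutVal) as a window of
  height *H·R* and width *W·R* (clipped to the IROI) slid over the IROI on a
  stride-4 grid (plus the flush-right/bottom positions); the placement
  maximising the count of pixels ≥ CutVal wins, first maximum in scan order
  on ties. Window counts use an integral image, so a full sweep is O(image).
  CutVal is used only for placement scoring; sub-threshold pixels inside the
  chosen window are kept, since zeroing them would destroy tissue context.
  If no pixel reaches CutVal the IROI is returned with a `fallback` flag.

The genetic algorithm over chromosomes is generational with population 30,
20 generations, tournament size 3, uniform crossover at rate 0.8, per-gene
Gaussian mutation (sd 0.1 on the normalised [0, 1] gene scale, clipped back
into bounds) and elitism 1. Fitness is pluggable: the surrogate used for
phantom cohorts scores the fraction of abnormal phantoms whose refined ROI
contains the planted lesion center, minus a small *H·W* area penalty so that
pure fallback (no zooming) is never optimal. A classifier-based AUOC fitness
can be substituted where its cost is acceptable; fitness is evaluated
per-dataset, not per-image.

## Cheat-sheet encoding

The electronic biopsy samples ROI pixels uniformly at random with
replacement; the default sample size is 10% of the ROI pixel count with a
floor of 100, and a full-enumeration mode replaces sampling with the exact
arithmetic mean (used by tests and available generally). Sampling is
unbiased, so for a constant ROI the frame value equals the region value
exactly. Frames are *appended* around the crop (each axis grows by 40
pixels) rather than overwriting its margins, which would destroy lesion
pixels. The biopsy mean and the radius are rounded to the nearest integer
and clipped to [0, 255] for 8-bit storage.

The processing order is: encode → split → augment → resize. Encoding
precedes the split, so test images in cheat-sheet arms carry frames too;
augmentation follows the split, so no rotation of a test image can enter
training (enforced by provenance tags and audited on every run). Resizing
to 100 × 100 (bilinear, no anti-aliasing, constant-preserving) comes last,
so the frame thickness in the final image scales with the crop size.

## The classifier

No deep-learning framework is used; the CNN is implemented directly in
numpy (sliding-window convolution via stride tricks, einsum contractions
for both passes, max-pooling with argmax bookkeeping, inverted dropout,
Adam). The backward pass is verified against finite differences in the test
suite. The default architecture — three valid 3×3 convolution blocks with
16/32/64 filters and 2×2 pooling, dense 64 with dropout 0.5, one sigmoid
output — has 433,025 parameters, deliberately below half a million so a
full experiment runs on a desktop CPU. Training uses binary cross-entropy
with class weights inversely proportional to class frequency (with 271
negatives vs 51 positives an unweighted loss rewards the all-negative
classifier, which already scores 84% accuracy), Adam at 1e-3, batch 32,
50 epochs by default. 25% of the training images are held out for
validation; the count is `round(0.25·n)` with banker's rounding (666 → 166).
All randomness (initialisation, splits, shuffles, dropout) derives from
explicit seeds, and training is bit-reproducible for a fixed seed.

The exact published layer stack is not recoverable, so this architecture is
the package's own design of equivalent scale; every element is overridable
through `ModelConfig`.

## Evaluation and statistics

A score ≥ 0.5 counts as a positive prediction for AC/SE/SP (the decision
threshold used for the published per-run numbers is not stated; 0.5 is the
assumption, recorded in `run_metrics`). The ROC sweeps all distinct scores
(ties grouped into one step) and the area is trapezoidal, which equals the
Mann–Whitney pair-counting statistic — the test suite asserts this
equivalence against an all-pairs brute force.

Variance comparisons use the lower 95% bound `(s²ₓ/s²ᵧ)/F₀.₉₅;₁₄,₁₄` with a
one-sided F-test p-value; mean comparisons use the pooled-variance t bound
`(x̄−ȳ) − t₀.₉₅;₂₈·s_p·√(2/15)`. The pooled form (df = 28) is used because
it regenerates the published CS-vs-OS bound 8.56 exactly, whereas the
unequal-variance form gives 8.54. From the packaged run table the seven
comparisons give 0.104, 2.292, 2.200 (variance ratios) and 8.565, 14.192,
2.394, −4.593 (mean differences). Three of the published mean-difference
bounds do not regenerate under any standard variant (printed 13.25 vs
recomputed 14.19; printed 1.45 vs 2.39; printed −4.56 vs −4.59, the last
agreeing at one decimal); `reproduce_published_analysis` therefore reports each
bound with a flag stating whether the printed value regenerates at its
printed precision, rather than silently asserting it.

## The synthetic phantom generator

Phantoms are schematic MLO views on a square 8-bit grid (default 256 px):
a half-elliptical breast (base intensity 150) attached to one vertical
edge, a triangular pectoral wedge at that edge's top corner (intensity 220,
width a configurable fraction of the image, default 0.25), a rectangular
background strip near the opposite edge (intensity 200) separated by a dark
gap, an optional Gaussian-profile lesion inside the breast, and Gaussian
pixel noise (default sd 5). Cohorts default to the 208/63/51
normal/benign/malignant composition; benign lesions draw radius 7–11 px and
peak intensity 185–205, malignant 15–21 px and 240–255, so the binary
separation is learnable at desk scale. Everything derives deterministically
from the cohort seed.

What the phantoms deliberately lack: real mammographic texture,
parenchymal patterns, calcifications, spiculation, and any overlap between
the benign and malignant intensity distributions. Passing tests on phantoms
therefore demonstrate that the pipeline's mechanics are correct (masks
removed exactly, lesions localised, the cheat sheet separable and learnable)
— not that the method attains any particular accuracy on clinical data.
Reproducing the published per-run MIAS numbers by retraining is out of
scope; the statistical analysis *of* those published runs is reproduced
exactly from the packaged table.

## Problem sizes used in tests and the acceptance script

The suite exercises the harness at reduced scale chosen as adequate for the
properties asserted: ROI ground-truth recovery uses 50 noise-free phantoms
(30 abnormal) with the surrogate-fitness GA; the counting invariants run
4 arms × 15 runs on an 18-phantom cohort with a 1-epoch reduced network
(counting, not accuracy, is asserted there); the end-to-end smoke trains
the DA/CS arm on a 60-phantom cohort (192 px, 40/20 split, 3 runs,
10 epochs) with the refinement chromosome (0.5, 0.5, 170) — CutVal above
the breast base intensity so the window zooms onto lesions — and asserts
mean test AUOC clearly above the 50% chance line. The acceptance script
repeats the statistics reproduction, the counting invariants and the smoke
run from scratch under a caller-supplied seed.

## Known limitations

* The numpy CNN is single-threaded-friendly but slow by GPU standards;
  full 15 × 4-run campaigns at 50 epochs are hours-scale on one CPU.
* Pectoral removal assumes the wedge is the brightest connected structure
  at the top corner; heavily dense breasts violate this on real data.
* `initial_roi` treats any nonzero pixel as tissue; on noisy real images
  the IROI approaches the full frame and the burden of zooming falls on
  the chromosome refinement.
* The GA defaults (population 30, 20 generations) are small; they suffice
  for the three-gene space but are not tuned for classifier-based fitness.
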