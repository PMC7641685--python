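import numpy as np
import pytest

from mammocad.roi import (Chromosome, EmptyROIError, GAConfig,
                          UndecidableSideError, detect_side, extract_roi,
                          ga_optimize, initial_roi, refine_roi,
                          remove_artifacts, remove_pectoral)
from mammocad.synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


class TestDetectSide:
    def test_known_side_and_mirror(self, noisefree_phantom):
        rec, _ = noisefree_phantom
        assert detect_side(rec.pixels) == "left"
        assert detect_side(rec.pixels[:, ::-1]) == "right"

    def test_blank_image_undecidable(self):
        with pytest.raises(UndecidableSideError):
            detect_side(np.full((64, 64), 17, dtype=np.uint8))

    def test_intensity_shift_invariant(self, noisefree_phantom):
        rec, _ = noisefree_phantom
        shifted = np.clip(rec.pixels.astype(int) + 30, 0, 255)
        assert detect_side(shifted) == detect_side(rec.pixels)

    def test_50_random_phantoms_all_correct(self):
        hits = 0
        for i in range(50):
            side = "left" if i % 2 == 0 else "right"
            rec, _ = generate_phantom(PhantomSpec(side=side, image_size=128),
                                      seed=100 + i)
            hits += detect_side(rec.pixels) == side
        assert hits == 50


class TestRemoveArtifacts:
    def test_strip_zeroed_breast_untouched(self, noisefree_phantom):
        rec, truth = noisefree_phantom
        out = remove_artifacts(rec.pixels, "left")
        r0, r1, c0, c1 = truth.artifact_bounds
        assert out[r0:r1, c0:c1].max() == 0
        kept = truth.breast_mask | truth.pectoral_mask
        assert np.array_equal(out[kept], rec.pixels[kept])

    def test_no_artifact_noop(self):
        rec, _ = generate_phantom(PhantomSpec(noise_sd=0, artifact=False),
                                  seed=0)
        assert np.array_equal(remove_artifacts(rec.pixels, "left"), rec.pixels)

    def test_all_zero_image(self):
        z = np.zeros((64, 64), dtype=np.uint8)
        assert np.array_equal(remove_artifacts(z, "left"), z)


class TestRemovePectoral:
    def test_removed_set_equals_wedge_mask(self, noisefree_phantom):
        rec, truth = noisefree_phantom
        clean = remove_artifacts(rec.pixels, "left")
        out = remove_pectoral(clean, "left")
        removed = (out != clean)
        assert np.array_equal(removed, truth.pectoral_mask)

    def test_wedge_gone_breast_mostly_intact(self):
        rec, truth = generate_phantom(
            PhantomSpec(noise_sd=3, pectoral_intensity=240,
                        breast_intensity=150), seed=2)
        out = remove_pectoral(remove_artifacts(rec.pixels, "left"), "left")
        assert out[truth.pectoral_mask].max() == 0
        breast = truth.breast_mask
        unchanged = (out[breast] == rec.pixels[breast]).mean()
        assert unchanged >= 0.95

    def test_tiny_wedge_essentially_noop(self):
        rec, truth = generate_phantom(
            PhantomSpec(noise_sd=0, pectoral_fraction=0.02), seed=0)
        out = remove_pectoral(rec.pixels, "left")
        changed = (out != rec.pixels).sum()
        assert changed <= truth.pectoral_mask.sum()


class TestInitialROI:
    def test_known_block(self):
        img = np.zeros((80, 80), dtype=np.uint8)
        img[10:60, 20:50] = 90
        res = initial_roi(img)
        assert res.bounds == (10, 60, 20, 50)
        assert res.R == 50

    def test_single_pixel(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[5, 9] = 1
        res = initial_roi(img)
        assert res.bounds == (5, 6, 9, 10)
        assert res.R == 1

    def test_all_zero_raises(self):
        with pytest.raises(EmptyROIError):
            initial_roi(np.zeros((64, 64), dtype=np.uint8))

    def test_cohort_iroi_contains_lesions(self, noisefree_cohort_50):
        records, meta, truths = noisefree_cohort_50
        for rec, truth in zip(records, truths):
            if truth.lesion_center is None:
                continue
            side = detect_side(rec.pixels)
            clean = remove_pectoral(remove_artifacts(rec.pixels, side), side)
            r0, r1, c0, c1 = initial_roi(clean).bounds
            lr, lc = truth.lesion_center
            assert r0 <= lr < r1 and c0 <= lc < c1


class TestRefineROI:
    def test_identity_chromosome(self):
        img = np.zeros((80, 80), dtype=np.uint8)
        img[10:60, 20:50] = 90
        iroi = initial_roi(img)
        res = refine_roi(img, iroi, Chromosome(H=1, W=1, CutVal=0))
        assert res.bounds == iroi.bounds

    def test_bright_block_found_exactly(self):
        # exhaustive-search oracle: the only 20x20 window holding all the
        # bright pixels is the block itself
        img = np.full((100, 100), 50, dtype=np.uint8)
        img[40:60, 64:84] = 200
        iroi = initial_roi(img)
        assert iroi.R == 100
        res = refine_roi(img, iroi, Chromosome(H=0.2, W=0.2, CutVal=199),
                         stride=1)
        assert res.bounds == (40, 60, 64, 84)

    def test_refined_always_inside_iroi(self, rng):
        img = rng.integers(0, 255, (70, 90)).astype(np.uint8)
        iroi = initial_roi(img)
        for _ in range(20):
            chrom = Chromosome(H=float(rng.uniform(0.05, 1)),
                               W=float(rng.uniform(0.05, 1)),
                               CutVal=float(rng.uniform(0, 255)))
            r = refine_roi(img, iroi, chrom)
            assert r.bounds[0] >= iroi.bounds[0] and r.bounds[1] <= iroi.bounds[1]
            assert r.bounds[2] >= iroi.bounds[2] and r.bounds[3] <= iroi.bounds[3]

    def test_fallback_when_nothing_above_cutval(self):
        img = np.zeros((50, 50), dtype=np.uint8)
        img[10:40, 10:40] = 100
        iroi = initial_roi(img)
        res = refine_roi(img, iroi, Chromosome(H=0.5, W=0.5, CutVal=200))
        assert res.fallback and res.bounds == iroi.bounds


class TestPipeline:
    def test_bounds_never_escape_image(self, noisefree_cohort_50):
        records, _, _ = noisefree_cohort_50
        chrom = Chromosome(H=0.5, W=0.5, CutVal=160)
        for rec in records[:10]:
            crop, res = extract_roi(rec.pixels, chrom=chrom)
            r0, r1, c0, c1 = res.bounds
            n = rec.pixels.shape[0]
            assert 0 <= r0 < r1 <= n and 0 <= c0 < c1 <= n
            assert crop.shape == (r1 - r0, c1 - c0)


class TestGA:
    def test_recovers_target_on_convex_fitness(self):
        target = np.array([0.4, 0.7, 0.5])  # normalised genes

        def fitness(ch):
            g = np.array([ch.H, ch.W, ch.CutVal / 255.0])
            return -float(np.abs(g - target).sum())

        best = ga_optimize(fitness, GAConfig(seed=1))
        assert abs(best.H - 0.4) <= 0.05
        assert abs(best.W - 0.7) <= 0.05
        assert abs(best.CutVal / 255.0 - 0.5) <= 0.05

    def test_population_of_one(self):
        calls = []

        def fitness(ch):
            calls.append(ch)
            return 1.0

        best = ga_optimize(fitness, GAConfig(population=1, generations=1,
                                             seed=0))
        assert (best.H, best.W, best.CutVal) == \
            (calls[0].H, calls[0].W, calls[0].CutVal)

    def test_deterministic_under_seed(self):
        def fitness(ch):
            return -(ch.H - 0.3) ** 2 - (ch.W - 0.3) ** 2

        cfg = GAConfig(population=10, generations=5, seed=42)
        a = ga_optimize(fitness, cfg)
        b = ga_optimize(fitness, GAConfig(population=10, generations=5,
                                          seed=42))
        assert (a.H, a.W, a.CutVal) == (b.H, b.W, b.CutVal)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            ga_optimize(lambda ch: 0.0, GAConfig(population=0))
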