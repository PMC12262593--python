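"""Nucleus segmentation: thresholding, components, morphology, gates,
boundaries and 3D stacking."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import draw

import chromdom as cd
import oracles


def disk_mask(radius, shape=None, center=None):
    shape = shape or (2 * radius + 5, 2 * radius + 5)
    center = center or (shape[0] // 2, shape[1] // 2)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(center, radius, shape=shape)
    mask[rr, cc] = True
    return mask


class TestThreshold:
    def test_cutoff_is_strict(self):
        slide = np.array([[499, 500, 501]])
        np.testing.assert_array_equal(
            cd.threshold_dapi(slide, 500), [[False, False, True]]
        )

    def test_all_zero_slide_gives_empty_mask(self):
        assert not cd.threshold_dapi(np.zeros((5, 5))).any()

    def test_negative_cutoff_turns_everything_on(self):
        assert cd.threshold_dapi(np.zeros((3, 3)), cutoff=-1).all()


class TestCandidateComponents:
    def test_truncates_to_top_15_largest(self):
        # 30 disjoint blobs of strictly increasing size
        mask = np.zeros((40, 1000), dtype=bool)
        for i in range(30):
            mask[1 : 2 + i, 33 * i : 33 * i + 1] = True
        comps = cd.candidate_components(mask)
        assert len(comps) == 15
        sizes = [c.sum() for c in comps]
        assert sizes == sorted(sizes, reverse=True)
        assert min(sizes) == 16  # the 15 largest of sizes 1..30

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(cd.candidate_components(mask)) == 1

    def test_fewer_blobs_than_top_k(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[2, 2] = mask[5, 15] = mask[8, 25] = True
        assert len(cd.candidate_components(mask)) == 3


class TestRefineRegion:
    def test_annulus_becomes_grown_solid_disk(self):
        outer = disk_mask(12, shape=(50, 50))
        inner = disk_mask(6, shape=(50, 50))
        annulus = outer & ~inner
        refined = cd.refine_region(annulus)
        expected = oracles.dilate_2d(outer, 10)
        np.testing.assert_array_equal(refined, expected)

    @pytest.mark.parametrize("iterations", [1, 3, 10])
    def test_matches_bruteforce_dilation_oracle(self, iterations):
        rng = np.random.default_rng(7)
        blob = rng.random((30, 30)) > 0.8
        blob = ndimage.binary_closing(blob)
        labeled, n = ndimage.label(blob, structure=np.ones((3, 3)))
        comp = labeled == 1
        refined = cd.refine_region(comp, iterations=iterations)
        filled = ndimage.binary_fill_holes(comp)
        expected = ndimage.binary_fill_holes(oracles.dilate_2d(filled, iterations))
        np.testing.assert_array_equal(refined, expected)

    def test_output_contains_input(self):
        region = disk_mask(5)
        assert (cd.refine_region(region) & region).sum() == region.sum()


class TestAcceptNucleus:
    def test_large_disk_accepted_with_high_circularity(self):
        disk = disk_mask(200, shape=(420, 420))
        assert disk.sum() > 120_000
        assert 0.85 <= cd.circularity(disk) <= 1.1
        assert cd.accept_nucleus(disk)

    def test_area_below_100k_rejected_regardless_of_shape(self):
        disk = disk_mask(126, shape=(260, 260))  # ~49.9k px, circularity ~1
        assert disk.sum() < 100_000
        assert not cd.accept_nucleus(disk)

    def test_exact_area_boundary(self):
        rect = np.zeros((410, 260), dtype=bool)
        rect[5:405, 5:255] = True  # exactly 100,000 px
        assert rect.sum() == 100_000
        assert cd.accept_nucleus(rect)
        rect[5, 5] = False  # 99,999 px
        assert not cd.accept_nucleus(rect)

    def test_thin_line_rejected_by_shape_score(self):
        line = np.zeros((3, 2100), dtype=bool)
        line[1, 50:2050] = True
        assert cd.circularity(line) < 0.01
        assert not cd.accept_nucleus(line, min_px=1000)

    def test_empty_region_rejected(self):
        assert not cd.accept_nucleus(np.zeros((5, 5), dtype=bool), min_px=0)


class TestExtractBoundary:
    def test_single_pixel_region_yields_its_8_neighbourhood(self):
        region = np.zeros((5, 5), dtype=bool)
        region[2, 2] = True
        got = {tuple(p) for p in cd.extract_boundary(region)}
        ring = {(2 + dy, 2 + dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)} - {(2, 2)}
        assert got == ring

    def test_full_frame_mask_bounds_at_frame_border(self):
        region = np.ones((6, 6), dtype=bool)
        got = {tuple(p) for p in cd.extract_boundary(region)}
        border = {
            (y, x) for y in range(6) for x in range(6)
            if y in (0, 5) or x in (0, 5)
        }
        assert got == border

    def test_square_boundary_tracks_perimeter(self):
        region = np.zeros((20, 20), dtype=bool)
        region[5:15, 5:15] = True
        inner = {tuple(p) for p in cd.extract_boundary(region, within_region_only=True)}
        assert inner == oracles.inner_boundary_2d(region)

    @pytest.mark.parametrize("seed", range(5))
    def test_inner_boundary_matches_neighbour_oracle_on_blobs(self, seed):
        rng = np.random.default_rng(seed)
        blob = rng.random((24, 24)) > 0.7
        blob = oracles.dilate_2d(blob, 2)  # thick, no 1-px filaments
        if not blob.any():
            pytest.skip("empty draw")
        got = {tuple(p) for p in cd.extract_boundary(blob, within_region_only=True)}
        assert got == oracles.inner_boundary_2d(blob)


class TestStackNuclei:
    @staticmethod
    def region(mask, z):
        return cd.nucleus.SlideRegion(
            z=z, mask=mask, boundary=cd.extract_boundary(mask)
        ) if mask.any() else None

    def make(self, per_slide_masks):
        out = []
        for z, masks in enumerate(per_slide_masks):
            out.append([
                cd.nucleus.SlideRegion(z=z, mask=m, boundary=cd.extract_boundary(m))
                for m in masks
            ])
        return out

    def test_same_disk_on_all_slides_is_one_region(self):
        disk = disk_mask(5, shape=(20, 20))
        nuclei = cd.stack_nuclei(self.make([[disk]] * 12))
        assert len(nuclei) == 1
        assert nuclei[0].mask.sum() == 12 * disk.sum()
        assert set(nuclei[0].per_slide_areas) == set(range(12))

    def test_two_disjoint_disks_are_two_regions(self):
        a = disk_mask(4, shape=(40, 40), center=(10, 10))
        b = disk_mask(4, shape=(40, 40), center=(30, 30))
        nuclei = cd.stack_nuclei(self.make([[a, b]] * 5))
        assert len(nuclei) == 2

    def test_z_gap_separates_regions(self):
        a = disk_mask(4, shape=(40, 40), center=(10, 10))
        b = disk_mask(4, shape=(40, 40), center=(30, 30))
        slides = self.make([[a]] * 5 + [[]] * 2 + [[b]] * 5)
        nuclei = cd.stack_nuclei(slides)
        assert len(nuclei) == 2
        # verify against a 3D labeling oracle
        vol = np.zeros((12, 40, 40), dtype=bool)
        vol[:5] = a
        vol[7:] = b
        _, n = ndimage.label(vol, structure=np.ones((3, 3, 3)))
        assert n == 2

    def test_empty_input_gives_empty_output(self):
        assert cd.stack_nuclei([]) == []
        assert cd.stack_nuclei([[], []]) == []


class TestAcceptanceMonotonicity:
    def test_acceptance_monotone_in_area_at_fixed_shape(self):
        small = disk_mask(185, shape=(380, 380))
        big = disk_mask(260, shape=(530, 530))
        # same circularity, larger area: acceptance cannot flip off
        assert abs(cd.circularity(small) - cd.circularity(big)) < 0.02
        assert cd.accept_nucleus(small)
        assert cd.accept_nucleus(big)


def test_segmentation_recovers_true_nucleus_mask():
    """threshold -> components -> refine -> accept recovers the generated
    ellipsoid with Jaccard >= 0.9 on accepted slides (field large enough
    that the fixed 10-step dilation margin is small against the radius)."""
    spec = cd.ed_like_spec(n_domains_mean=5)
    stack, truth = cd.generate_stack(
        spec, grid_shape=(13, 600, 600), seed=3,
        nucleus_semiaxes=(5.0, 270.0, 270.0),
    )
    nuclei = cd.segment_nuclei(stack.channels["dapi"], min_px=140_000)
    assert len(nuclei) == 1
    det = nuclei[0].mask
    true = truth.nucleus_mask(stack.shape)
    accepted = sorted(nuclei[0].per_slide_areas)
    inter = (det[accepted] & true[accepted]).sum()
    union = (det[accepted] | true[accepted]).sum()
    assert inter / union >= 0.9
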