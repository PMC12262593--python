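"""Per-domain features: correlation, sphericity, boundary distance,
volume classes and the Gini index."""

import numpy as np
import pytest

import chromdom as cd
import oracles
from conftest import ball_voxels, capsule_voxels

ISO = (1.0, 1.0, 1.0)


def make_domain(voxels, h3=None, er=None):
    n = len(voxels)
    return cd.ChromatinDomain(
        label=1,
        voxels=np.asarray(voxels),
        h3k27ac_intensities=np.asarray(h3 if h3 is not None else np.ones(n), float),
        er_intensities=None if er is None else np.asarray(er, float),
        parent_nucleus=1,
    )


class TestDomainCorrelation:
    def test_increasing_affine_relation_gives_one(self):
        h = np.array([1.0, 5.0, 2.0, 9.0])
        d = make_domain(np.zeros((4, 3), int), h3=h, er=2 * h + 5)
        r, reason = cd.domain_correlation(d)
        assert reason is None
        assert r == pytest.approx(1.0)

    def test_negated_signal_gives_minus_one(self):
        h = np.array([1.0, 5.0, 2.0, 9.0])
        r, _ = cd.domain_correlation(make_domain(np.zeros((4, 3), int), h3=h, er=-h))
        assert r == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        h = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1.0, 2.0, 3.0, 100.0])
        r, _ = cd.domain_correlation(make_domain(np.zeros((4, 3), int), h3=h, er=e))
        assert r == pytest.approx(oracles.pearson_sums(h, e), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        h = rng.normal(size=n)
        e = rng.normal(size=n)
        r, _ = cd.domain_correlation(make_domain(np.zeros((n, 3), int), h3=h, er=e))
        assert r == pytest.approx(oracles.pearson_sums(h, e), abs=1e-10)

    def test_zero_variance_reported_as_missing(self):
        d = make_domain(np.zeros((5, 3), int), h3=np.ones(5), er=np.arange(5.0))
        r, reason = cd.domain_correlation(d)
        assert np.isnan(r) and reason == "zero variance"

    def test_nan_er_voxels_are_excluded(self):
        h = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([2.0, 4.0, 6.0, np.nan, np.nan])
        r, _ = cd.domain_correlation(make_domain(np.zeros((5, 3), int), h3=h, er=e))
        assert r == pytest.approx(1.0)


class TestSphericity:
    def test_digitized_ball_scores_one(self):
        phi = cd.domain_sphericity(ball_voxels(10), ISO)
        assert phi == pytest.approx(1.0, abs=0.05)

    def test_prolate_spheroid_matches_closed_form(self):
        a, b = 20.0, 5.0  # 4:1 polar : equatorial semi-axes
        zz, yy, xx = np.mgrid[-21:22, -6:7, -6:7]
        inside = (zz / a) ** 2 + (yy / b) ** 2 + (xx / b) ** 2 <= 1.0
        voxels = np.argwhere(inside)
        v_analytic = 4.0 / 3.0 * np.pi * a * b * b
        s_analytic = oracles.prolate_spheroid_area(a, b)
        phi_analytic = np.pi ** (1 / 3) * (6 * v_analytic) ** (2 / 3) / s_analytic
        phi = cd.domain_sphericity(voxels, ISO)
        assert phi == pytest.approx(phi_analytic, rel=0.05)

    def test_scale_invariance(self):
        phi10 = cd.domain_sphericity(ball_voxels(10), ISO)
        phi15 = cd.domain_sphericity(ball_voxels(15), ISO)
        assert phi10 == pytest.approx(phi15, abs=0.03)

    def test_decreases_with_capsule_elongation_at_fixed_volume(self):
        """phi is strictly monotone decreasing along capsules of equal
        volume and growing elongation: rounder means higher score."""
        volume = 6000.0
        phis = []
        for e in (1.0, 2.0, 4.0, 8.0):
            r = (volume / (np.pi * (2 * (e - 1) + 4.0 / 3.0))) ** (1.0 / 3.0)
            vox = capsule_voxels(r, r * (e - 1), axis=(0, 0, 1))
            phis.append(cd.domain_sphericity(vox, ISO))
        assert all(a > b for a, b in zip(phis, phis[1:]))
        assert phis[0] == pytest.approx(1.0, abs=0.05)

    def test_anisotropic_spacing_is_respected(self):
        # a voxel ellipsoid that is a true ball in physical units
        spacing = (3.0, 1.0, 1.0)
        zz, yy, xx = np.mgrid[-4:5, -12:13, -12:13]
        inside = (3.0 * zz) ** 2 + yy**2 + xx**2 <= 12.0**2
        phi = cd.domain_sphericity(np.argwhere(inside), spacing)
        assert phi == pytest.approx(1.0, abs=0.07)


class TestBoundaryDistance:
    @staticmethod
    def spherical_nucleus(radius=20, shape=(45, 45, 45)):
        c = np.array(shape) // 2
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        mask = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius**2
        inner = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= (radius - 1) ** 2
        boundary = np.argwhere(mask & ~inner)
        return cd.NucleusRegion(label=1, mask=mask, boundary=boundary), c

    def test_centered_domain_is_one_radius_from_wall(self):
        nuc, c = self.spherical_nucleus()
        d = make_domain(ball_voxels(2, center=c))
        dist = cd.boundary_distance(d, nuc, ISO)
        assert dist == pytest.approx(20.0, abs=1.0)

    def test_touching_domain_distance_near_zero(self):
        nuc, c = self.spherical_nucleus()
        d = make_domain(np.array([c + [0, 0, 19]]))
        assert cd.boundary_distance(d, nuc, ISO) <= 1.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nuc, c = self.spherical_nucleus(radius=10, shape=(25, 25, 25))
        offset = rng.integers(-5, 6, size=3)
        d = make_domain(ball_voxels(1, center=c + offset))
        spacing = (0.15, 0.06, 0.06)
        got = cd.boundary_distance(d, nuc, spacing)
        expected = oracles.min_boundary_distance(d.centroid, nuc.boundary, spacing)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_empty_boundary_raises(self):
        nuc = cd.NucleusRegion(
            label=1, mask=np.ones((3, 3, 3), bool), boundary=np.empty((0, 3), int)
        )
        with pytest.raises(ValueError, match="empty boundary"):
            cd.boundary_distance(make_domain(np.zeros((2, 3), int)), nuc, ISO)


class TestVolumeClasses:
    def test_quartile_mode_splits_evenly(self):
        classes = cd.assign_volume_classes(np.arange(1.0, 101.0))
        counts = np.bincount(classes)[1:]
        np.testing.assert_array_equal(counts, [25, 25, 25, 25])

    def test_all_equal_collapses_to_single_class(self):
        classes = cd.assign_volume_classes(np.full(8, 5.0))
        assert set(classes) == {1}

    def test_explicit_boundaries(self):
        classes = cd.assign_volume_classes(
            [5.0, 50.0, 500.0, 5000.0], boundaries=(10, 100, 1000)
        )
        np.testing.assert_array_equal(classes, [1, 2, 3, 4])

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            cd.assign_volume_classes([1.0, 2.0, 3.0, 4.0], boundaries=(10, 5, 100))

    def test_quantile_mode_needs_four_values(self):
        with pytest.raises(ValueError, match="at least 4"):
            cd.assign_volume_classes([1.0, 2.0, 3.0])


class TestGini:
    def test_perfect_equality_scores_zero(self):
        assert cd.gini_index([3.0, 3.0, 3.0, 3.0]) == pytest.approx(0.0)

    def test_single_nonzero_value(self):
        assert cd.gini_index([0.0, 0.0, 0.0, 1.0]) == pytest.approx(0.75)

    def test_two_values(self):
        assert cd.gini_index([1.0, 3.0]) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(rng.integers(2, 30)) * 10
        assert cd.gini_index(x) == pytest.approx(oracles.gini_pairwise(x), abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        assert cd.gini_index(3.7 * x) == pytest.approx(cd.gini_index(x), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cd.gini_index([0.0, 0.0])
        with pytest.raises(ValueError):
            cd.gini_index([-1.0, 2.0])
        with pytest.raises(ValueError):
            cd.gini_index([1.0])


def test_e2_exceeds_ed_in_volume_distance_but_not_sphericity(ed_analysis):
    """End-to-end directional contrast on single stacks: the elongated,
    central E2-like condition yields larger volume, larger boundary
    distance, and lower sphericity than the compact, peripheral ED-like
    condition."""
    e2_stack, _ = cd.generate_stack(cd.e2_like_spec(), grid_shape=(10, 256, 256), seed=21)
    cfg = cd.RunConfig(min_nucleus_px=5000, max_shift=6, alignment_max_slides=3)
    e2 = cd.analyze_stack(e2_stack, cfg).features
    ed = ed_analysis.features
    assert e2["volume_vox"].mean() > ed["volume_vox"].mean()
    assert e2["sphericity"].mean() < ed["sphericity"].mean()
    assert e2["boundary_distance_um"].mean() > ed["boundary_distance_um"].mean()
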