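"""Segmentation, morphometry and proximity classification."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from syribbon_quant.image import ImageStack
from syribbon_quant.spots import (
    DetectionParams,
    classify_by_proximity,
    detect_spots,
    filter_spots,
    measure_mask,
    measure_spot,
    subtract_background,
    surface_distance,
    volume_correlation,
    voxel_face_area,
)

from conftest import PAPER_VOXEL, digitize_cube, digitize_ellipsoid, digitize_sphere, mask_stack

ISO20 = (0.02, 0.02, 0.02)


def _spot_from_mask(mask, voxel_size, spot_id=0):
    """Build a SpotSurface directly from a binary mask (bypasses detection)."""
    stack = mask_stack(mask, voxel_size)
    spots = detect_spots(
        stack, 0,
        DetectionParams(surface_detail=0.0, background_sphere_diameter=None,
                        threshold_method=500.0, min_voxels=1),
        subtract_bg=False,
    )
    assert len(spots) == 1
    spots[0].id = spot_id
    return spots[0]


class TestBackgroundSubtraction:
    def test_flat_image_goes_to_zero(self):
        stack = ImageStack(np.full((1, 3, 40, 40), 37.0), PAPER_VOXEL, ["a"])
        out = subtract_background(stack, "a", 0.3)
        assert np.allclose(out, 0.0)

    def test_compact_punctum_survives_subtraction(self):
        """A bright peak much smaller than the ball keeps ≥95% of its mass."""
        img = np.zeros((1, 3, 60, 60))
        img[0, 1, 28:31, 28:31] = 800.0  # 3 px ≈ 0.24 µm ≪ 0.8 µm ball
        stack = ImageStack(img, PAPER_VOXEL, ["a"])
        out = subtract_background(stack, "a", 0.8)
        assert out.sum() >= 0.95 * img.sum()

    def test_smooth_gradient_mostly_removed(self):
        ramp = np.linspace(100, 200, 60)
        img = np.tile(ramp, (1, 3, 60, 1))
        stack = ImageStack(img, PAPER_VOXEL, ["a"])
        out = subtract_background(stack, "a", 0.3)
        assert out.max() < 0.05 * 100.0

    def test_subvoxel_ball_warns_and_returns_identity(self):
        img = np.random.default_rng(0).uniform(0, 100, (1, 2, 20, 20))
        stack = ImageStack(img, PAPER_VOXEL, ["a"])
        with pytest.warns(UserWarning, match="below one pixel"):
            out = subtract_background(stack, "a", 0.05)
        assert np.array_equal(out, img[0])


class TestDetection:
    def test_counts_only_components_above_min_voxels(self):
        """5 large spheres + 3 sub-10-voxel specks -> exactly 5 spots."""
        img = np.zeros((20, 120, 120))
        centers = [(10, 20, 20), (10, 20, 60), (10, 20, 100), (10, 70, 30), (10, 70, 90)]
        zz, yy, xx = np.indices(img.shape)
        for cz, cy, cx in centers:
            ball = ((zz - cz) * 0.2) ** 2 + ((yy - cy) * 0.08) ** 2 + ((xx - cx) * 0.08) ** 2 <= 0.3**2
            img[ball] = 1000.0
        img[3, 5, 5] = 1000.0                        # 1 voxel
        img[3, 110, 110:112] = 1000.0                # 2 voxels
        img[15, 110:112, 5:8] = 1000.0               # 6 voxels
        stack = ImageStack(img[None], PAPER_VOXEL, ["a"])
        spots = detect_spots(
            stack, "a",
            DetectionParams(surface_detail=0.0, background_sphere_diameter=None,
                            threshold_method=500.0),
            subtract_bg=False,
        )
        assert len(spots) == 5
        assert all(s.voxel_count >= 10 for s in spots)
        # sorted by descending volume
        vols = [s.volume for s in spots]
        assert vols == sorted(vols, reverse=True)

    @pytest.mark.parametrize("gap_vox,expected", [(2, 2), (0, 1)])
    def test_connectivity_merges_touching_components(self, gap_vox, expected):
        img = np.zeros((9, 30, 30))
        img[3:6, 3:6, 3:6] = 1000.0
        s = 6 + gap_vox
        img[3:6, 3:6, s:s + 3] = 1000.0
        stack = ImageStack(img[None], PAPER_VOXEL, ["a"])
        spots = detect_spots(
            stack, "a",
            DetectionParams(surface_detail=0.0, background_sphere_diameter=None,
                            threshold_method=500.0, min_voxels=1),
            subtract_bg=False,
        )
        assert len(spots) == expected

    def test_empty_stack_yields_empty_list(self):
        stack = ImageStack(np.zeros((1, 4, 20, 20)), PAPER_VOXEL, ["a"])
        assert detect_spots(stack, "a") == []


class TestMorphometry:
    def test_sphere_volume_and_sphericity_closed_form(self):
        """r = 0.5 µm at 20 nm isotropic: V within 2% of 4/3·π·r³, Ψ ≈ 1."""
        mask = digitize_sphere(0.5, ISO20)
        v, a, psi, _ = measure_mask(mask, ISO20)
        assert v == pytest.approx(4 / 3 * math.pi * 0.5**3, rel=0.02)
        assert psi == pytest.approx(1.0, abs=0.02)

    def test_cube_sphericity_closed_form(self):
        """Ψ(cube) = π^(1/3)(6a³)^(2/3)/(6a²) ≈ 0.806 at fine resolution."""
        mask = digitize_cube(1.4, ISO20)
        v, a, psi, _ = measure_mask(mask, ISO20)
        expected = math.pi ** (1 / 3) * 6 ** (2 / 3) / 6
        assert psi == pytest.approx(expected, abs=0.02)

    def test_single_voxel_volume_exact(self):
        lab = np.zeros((5, 5, 5), dtype=int)
        lab[2, 2, 2] = 1
        v, _, _, centroid = measure_spot(lab, 1, PAPER_VOXEL)
        assert v == pytest.approx(np.prod(PAPER_VOXEL))
        assert centroid == pytest.approx((0.5, 0.2, 0.2))

    def test_missing_label_raises(self):
        with pytest.raises(ValueError, match="label"):
            measure_spot(np.zeros((4, 4, 4), dtype=int), 3, PAPER_VOXEL)

    def test_volume_recovery_at_acquisition_voxel_size(self):
        """Median digitization error < 15% across 0.02–2 µm³ spheres."""
        rng = np.random.default_rng(42)
        vols = np.exp(rng.uniform(np.log(0.02), np.log(2.0), 100))
        errs = []
        for v_true in vols:
            r = (3 * v_true / (4 * math.pi)) ** (1 / 3)
            off = rng.uniform(-0.5, 0.5, 3) * PAPER_VOXEL
            mask = digitize_sphere(r, PAPER_VOXEL, center_offset=tuple(off))
            v_est = mask.sum() * np.prod(PAPER_VOXEL)
            errs.append(abs(v_est - v_true) / v_true)
        assert np.median(errs) < 0.15

    def test_sphericity_orders_sphere_ellipsoid_plate(self):
        """Equal-volume sphere > 3:1 prolate > plate, as for ribbon vs
        scaffold-plate shapes."""
        iso = (0.05, 0.05, 0.05)
        sphere = digitize_sphere(0.4, iso)
        prolate = digitize_ellipsoid((0.72, 0.3, 0.3), iso)   # ~3:1, same V
        plate = digitize_ellipsoid((0.12, 0.6, 0.6), iso)
        psis = [measure_mask(m, iso)[2] for m in (sphere, prolate, plate)]
        assert psis[0] > psis[1] > psis[2]

    def test_voxel_face_oracle_brackets_mesh_area(self):
        """Face counting overestimates smooth-surface area; the corrected
        mesh estimate must sit below it and near the analytic value."""
        mask = digitize_sphere(0.4, ISO20)
        _, a_mesh, _, _ = measure_mask(mask, ISO20)
        a_faces = voxel_face_area(mask, ISO20)
        a_true = 4 * math.pi * 0.4**2
        assert a_mesh < a_faces
        assert a_mesh == pytest.approx(a_true, rel=0.03)


class TestFilter:
    def _fake(self, volume):
        import dataclasses

        from syribbon_quant.spots import SpotSurface

        return SpotSurface(
            id=0, channel="a", voxel_count=1, volume=volume, surface_area=1.0,
            sphericity=1.0, centroid=(0, 0, 0), voxels=np.zeros((1, 3), int),
            boundary_voxels=np.zeros((1, 3), int), voxel_size_zyx=PAPER_VOXEL,
        )

    def test_bounds_are_inclusive(self):
        spots = [self._fake(v) for v in (0.01, 0.02, 1.0, 2.0, 2.5)]
        kept, rejected = filter_spots(spots)
        assert [s.volume for s in kept] == [0.02, 1.0, 2.0]
        assert [(s.volume, r) for s, r in rejected] == [(0.01, "too_small"), (2.5, "too_large")]

    def test_empty_and_all_kept(self):
        assert filter_spots([]) == ([], [])
        spots = [self._fake(v) for v in (0.1, 0.5)]
        kept, rejected = filter_spots(spots)
        assert len(kept) == 2 and rejected == []

    def test_idempotent(self):
        spots = [self._fake(v) for v in (0.01, 0.5, 3.0)]
        kept1, _ = filter_spots(spots)
        kept2, rej2 = filter_spots(kept1)
        assert kept2 == kept1 and rej2 == []


class TestDistances:
    def test_self_distance_zero_and_symmetry(self):
        mask = digitize_sphere(0.3, PAPER_VOXEL)
        a = _spot_from_mask(mask, PAPER_VOXEL, 0)
        assert surface_distance(a, a) == 0.0
        big = np.zeros((20, 60, 60), bool)
        big[4:10, 5:15, 5:15] = True
        other = np.zeros_like(big)
        other[4:10, 30:40, 30:40] = True
        s1 = _spot_from_mask(big, PAPER_VOXEL, 0)
        s2 = _spot_from_mask(other, PAPER_VOXEL, 1)
        assert surface_distance(s1, s2) == pytest.approx(surface_distance(s2, s1))

    def test_known_gap_recovered_within_voxel_diagonal(self):
        """Two spheres with an analytic 0.4 µm gap on a fine grid."""
        iso = (0.04, 0.04, 0.04)
        r, gap = 0.3, 0.4
        n = 40
        zz, yy, xx = np.indices((n, n, n))
        c1 = np.array([20, 20, 10])
        c2 = c1 + [0, 0, int((2 * r + gap) / 0.04)]
        m1 = (((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2) * 0.04**2) <= r**2
        m2 = (((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2) * 0.04**2) <= r**2
        s1 = _spot_from_mask(m1, iso, 0)
        s2 = _spot_from_mask(m2, iso, 1)
        diag = math.sqrt(3) * 0.04
        assert surface_distance(s1, s2) == pytest.approx(gap, abs=diag)


class TestProximityClassification:
    def _pair_fixture(self, gaps, iso=(0.03, 0.03, 0.03), r=0.12):
        """Query spheres at stated gaps from reference spheres."""
        n_pix_r = int(r / iso[0])
        queries, refs = [], []
        for i, gap in enumerate(gaps):
            n = 4 * n_pix_r + int(gap / iso[0]) + 12
            shape = (n, n, n)
            zz, yy, xx = np.indices(shape)
            cq = np.array([n // 2, n // 2, n_pix_r + 3])
            cr = cq + [0, 0, 2 * n_pix_r + int(round(gap / iso[0]))]
            mq = (((zz - cq[0]) ** 2 + (yy - cq[1]) ** 2 + (xx - cq[2]) ** 2) * iso[0] ** 2) <= r**2
            mr = (((zz - cr[0]) ** 2 + (yy - cr[1]) ** 2 + (xx - cr[2]) ** 2) * iso[0] ** 2) <= r**2
            queries.append(_spot_from_mask(mq, iso, i))
            refs.append(_spot_from_mask(mr, iso, i))
        return queries, refs

    def test_proximity_class_thresholds(self):
        """Gaps {0.03, 0.40} µm: only the 0.03 µm pair passes at 0.045 µm."""
        queries, refs = self._pair_fixture([0.03, 0.40])
        res = classify_by_proximity(queries, refs, threshold=0.045)
        assert [q for q, _, _ in res.paired] == [0]
        assert res.unpaired == [1]
        res06 = classify_by_proximity(queries, refs, threshold=0.06)
        assert [q for q, _, _ in res06.paired] == [0]

    def test_empty_reference_all_unpaired(self):
        queries, _ = self._pair_fixture([0.1])
        res = classify_by_proximity(queries, [], threshold=1.0)
        assert res.paired == [] and res.unpaired == [0]

    def test_overlapping_spots_pair_at_zero_threshold(self):
        mask = digitize_sphere(0.2, PAPER_VOXEL)
        a = _spot_from_mask(mask, PAPER_VOXEL, 0)
        b = _spot_from_mask(mask, PAPER_VOXEL, 0)
        res = classify_by_proximity([a], [b], threshold=0.0)
        assert res.paired == [(0, 0, 0.0)]

    def test_matches_brute_force_all_pairs_scan(self, rng):
        """Classification equals an exhaustive nearest-neighbour scan."""
        iso = (0.06, 0.06, 0.06)
        n = 46
        shape = (n, n, n)

        def rand_spot(i):
            zz, yy, xx = np.indices(shape)
            c = rng.integers(8, n - 8, 3)
            r = rng.uniform(0.1, 0.2)
            m = (((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) * iso[0] ** 2) <= r**2
            return _spot_from_mask(m, iso, i)

        queries = [rand_spot(i) for i in range(6)]
        refs = [rand_spot(i) for i in range(5)]
        threshold = 0.5
        res = classify_by_proximity(queries, refs, threshold)
        for q in queries:
            dists = np.array([surface_distance(q, r) for r in refs])
            if dists.min() <= threshold:
                assert res.partner_of(q.id) == int(np.argmin(dists))
            else:
                assert q.id in res.unpaired


class TestVolumeCorrelation:
    def _pairs(self, va, vb):
        fake = TestFilter()._fake
        return [(fake(a), fake(b)) for a, b in zip(va, vb)]

    def test_perfect_linear_scaling(self):
        v = [0.1, 0.3, 0.5, 0.9]
        r, p = volume_correlation(self._pairs(v, [2 * x for x in v]))
        assert r == pytest.approx(1.0)

    def test_anti_proportional(self):
        v = [0.1, 0.3, 0.5, 0.9]
        r, _ = volume_correlation(self._pairs(v, [1.0 - x for x in v]))
        assert r == pytest.approx(-1.0)

    def test_independent_volumes_near_zero(self, rng):
        va = rng.lognormal(-2, 1, 1000)
        vb = rng.lognormal(-2, 1, 1000)
        r, _ = volume_correlation(self._pairs(va, vb))
        assert abs(r) < 0.1

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError, match="3 pairs"):
            volume_correlation(self._pairs([1, 2], [1, 2]))
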