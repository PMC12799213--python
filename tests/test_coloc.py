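"""Cell geometry, peripherality, and pixel-intensity colocalization."""

import math

import numpy as np
import pytest

from syribbon_quant.coloc import (
    build_cell_geometry,
    costes_test,
    line_profile_correlation,
    manders,
    pearson_pixel,
    peripheral_ratio,
)
from syribbon_quant.synthetic import (
    GroundTruthSpot,
    generate_cell_stack,
    place_cytosolic_spot,
    place_membrane_spot,
)


@pytest.fixture
def membrane_stack(noiseless_config):
    stack, _ = generate_cell_stack(noiseless_config, [])
    return stack


class TestCellGeometry:
    def test_ring_area_matches_analytic_annulus(self, membrane_stack, noiseless_config):
        """Circular cross-section: ring area = π(R² − (R−t)²) within 5%."""
        geom = build_cell_geometry(membrane_stack, membrane_channel=0, ring_thickness=1.0)
        cfg = noiseless_config
        dz, dy, dx = cfg.voxel_size_zyx
        nz = cfg.stack_shape[0]
        z_mid = nz // 2
        assert z_mid in geom.central_planes
        # cell radius at the mid-plane (center plane of the ellipsoid)
        z_um = (z_mid + 0.5) * dz
        rel = (z_um - cfg.cell_center[2]) / cfg.cell_semi_axes[2]
        r_plane = cfg.cell_semi_axes[0] * math.sqrt(max(0.0, 1 - rel**2))
        r_outer = r_plane + cfg.membrane_thickness / 2  # mask includes the shell
        expected = math.pi * (r_outer**2 - (r_outer - 1.0) ** 2)
        measured = geom.ring_mask[z_mid].sum() * dy * dx
        assert measured == pytest.approx(expected, rel=0.05)

    def test_ring_and_interior_disjoint_and_cover_cell(self, membrane_stack):
        geom = build_cell_geometry(membrane_stack, membrane_channel=0)
        assert not np.any(geom.ring_mask & geom.interior_mask)
        assert np.array_equal(geom.ring_mask | geom.interior_mask, geom.cell_mask)

    def test_zero_ring_thickness_rejected(self, membrane_stack):
        with pytest.raises(ValueError, match="ring_thickness"):
            build_cell_geometry(membrane_stack, membrane_channel=0, ring_thickness=0.0)

    def test_open_contour_rejected(self, membrane_stack):
        img = membrane_stack.data.copy()
        nz = img.shape[1]
        img[0, nz // 2, :, : img.shape[3] // 2] = 0.0  # break the shell
        from syribbon_quant.image import ImageStack

        broken = ImageStack(img, membrane_stack.voxel_size_zyx, membrane_stack.channels)
        with pytest.raises(ValueError, match="open contour"):
            build_cell_geometry(broken, membrane_channel=0)

    def test_few_planes_warns(self, noiseless_config):
        from syribbon_quant.image import ImageStack

        thin = np.zeros((1, 3, 60, 60))
        yy, xx = np.indices((60, 60))
        ring2d = (np.hypot(yy - 30, xx - 30) <= 25) & (np.hypot(yy - 30, xx - 30) >= 23)
        thin[0, 1][ring2d] = 100.0
        stack = ImageStack(thin, (0.2, 0.08, 0.08), ["m"])
        with pytest.warns(UserWarning, match="central plane"):
            build_cell_geometry(stack, membrane_channel=0)


class TestPeripheralRatio:
    def test_uniform_image_ratio_one(self, membrane_stack):
        geom = build_cell_geometry(membrane_stack, membrane_channel=0)
        from syribbon_quant.image import ImageStack

        uni = ImageStack(np.full_like(membrane_stack.data, 50.0),
                         membrane_stack.voxel_size_zyx, membrane_stack.channels)
        assert peripheral_ratio(uni, 0, geom) == pytest.approx(1.0, abs=0.05)

    def test_ring_only_signal_gives_large_ratio(self, membrane_stack):
        geom = build_cell_geometry(membrane_stack, membrane_channel=0)
        from syribbon_quant.image import ImageStack

        img = np.zeros_like(membrane_stack.data)
        img[0][geom.ring_mask] = 100.0
        img[0][geom.interior_mask] = 0.1  # background epsilon
        stack = ImageStack(img, membrane_stack.voxel_size_zyx, membrane_stack.channels)
        assert peripheral_ratio(stack, 0, geom) > 100.0

    def test_membrane_puncta_score_higher_than_cytosolic(self, noiseless_config):
        """Same puncta moved from the membrane to the cell center drop the
        ratio — the logic behind the membrane-distribution comparisons."""
        cfg = noiseless_config
        directions = [(1, 0, 0), (-1, 0.3, 0), (0.2, 1, 0), (-0.4, -1, 0)]
        mem = [place_membrane_spot(cfg, "R", d, 0.25) for d in directions]
        cyt = [place_cytosolic_spot(cfg, "R", cfg.cell_center, 0.25)]
        stack_m, _ = generate_cell_stack(cfg, mem)
        stack_c, _ = generate_cell_stack(cfg, cyt)
        # small uniform background so the ratio is defined in every plane
        stack_m.data[1] += 1.0
        stack_c.data[1] += 1.0
        geom = build_cell_geometry(stack_m, membrane_channel=0)
        r_m = peripheral_ratio(stack_m, "R", geom)
        r_c = peripheral_ratio(stack_c, "R", geom)
        assert r_m > r_c

    def test_invariant_under_global_scaling(self, membrane_stack, rng):
        geom = build_cell_geometry(membrane_stack, membrane_channel=0)
        from syribbon_quant.image import ImageStack

        img = rng.uniform(10, 100, membrane_stack.data.shape)
        a = ImageStack(img, membrane_stack.voxel_size_zyx, membrane_stack.channels)
        b = ImageStack(3.7 * img, membrane_stack.voxel_size_zyx, membrane_stack.channels)
        assert peripheral_ratio(a, 0, geom) == pytest.approx(peripheral_ratio(b, 0, geom))


class TestPearsonManders:
    def test_identity_and_inversion(self, rng):
        img = rng.uniform(0, 100, (20, 20))
        mask = np.ones_like(img, bool)
        assert pearson_pixel(img, img, mask) == pytest.approx(1.0)
        assert pearson_pixel(img, 200.0 - img, mask) == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self, rng):
        a = rng.normal(50, 10, (100, 100))
        b = rng.normal(50, 10, (100, 100))
        assert abs(pearson_pixel(a, b, np.ones_like(a, bool))) < 0.05

    def test_affine_rescaling_invariance(self, rng):
        a = rng.uniform(0, 100, (30, 30))
        b = rng.uniform(0, 100, (30, 30))
        mask = np.ones_like(a, bool)
        r0 = pearson_pixel(a, b, mask)
        assert pearson_pixel(2.5 * a + 7, b, mask) == pytest.approx(r0)

    def test_minimum_voxels_enforced(self):
        a = np.ones((2, 2))
        with pytest.raises(ValueError, match="10"):
            pearson_pixel(a, a, np.ones_like(a, bool))

    def test_manders_identical_images(self, rng):
        img = np.zeros((40, 40))
        img[10:20, 10:20] = rng.uniform(50, 100, (10, 10))
        m1, m2 = manders(img, img, np.ones_like(img, bool))
        assert m1 == pytest.approx(1.0, abs=0.02)
        assert m2 == pytest.approx(1.0, abs=0.02)

    def test_manders_disjoint_supports(self):
        a = np.zeros((30, 30))
        b = np.zeros((30, 30))
        a[5:10, 5:10] = 100.0
        b[20:25, 20:25] = 100.0
        m1, m2 = manders(a, b, np.ones_like(a, bool), thresholds=(10.0, 10.0))
        assert m1 == 0.0 and m2 == 0.0

    def test_manders_nested_supports_fixed_thresholds(self):
        """A ⊂ B: M1 = 1, M2 = overlapped fraction of B."""
        a = np.zeros((30, 30))
        b = np.zeros((30, 30))
        b[5:15, 5:25] = 100.0   # 200 px
        a[5:15, 5:15] = 100.0   # 100 px inside B's support
        m1, m2 = manders(a, b, np.ones_like(a, bool), thresholds=(10.0, 10.0))
        assert m1 == pytest.approx(1.0)
        assert m2 == pytest.approx(0.5)


class TestCostes:
    def _ring_mask(self, n=64, r_out=28, r_in=16):
        yy, xx = np.indices((n, n))
        rr = np.hypot(yy - n / 2, xx - n / 2)
        return (rr <= r_out) & (rr >= r_in)

    def test_positive_control_shared_puncta(self, rng):
        """Channels sharing puncta beat all 100 scrambles (p = 0)."""
        n = 64
        base = np.zeros((n, n))
        for _ in range(25):
            cy, cx = rng.integers(8, n - 8, 2)
            base[cy - 2:cy + 2, cx - 2:cx + 2] += 100.0
        a = base + rng.normal(0, 5, base.shape)
        b = 0.8 * base + rng.normal(0, 5, base.shape)
        res = costes_test(a, b, self._ring_mask(), n=100, rng=rng)
        assert res.costes_p == 0.0
        assert res.pearson_r > 0.8

    def test_null_images_rarely_significant(self, rng):
        """Independent noise: p ≥ 0.05 in the vast majority of cells."""
        ok = 0
        n_cells = 40
        mask = self._ring_mask()
        for _ in range(n_cells):
            a = rng.normal(50, 10, mask.shape)
            b = rng.normal(50, 10, mask.shape)
            if costes_test(a, b, mask, n=100, rng=rng).costes_p >= 0.05:
                ok += 1
        assert ok >= 0.9 * n_cells

    def test_zero_repetitions_rejected(self, rng):
        a = rng.uniform(0, 1, (20, 20))
        with pytest.raises(ValueError, match="repetitions"):
            costes_test(a, a, np.ones_like(a, bool), n=0)

    def test_block_larger_than_mask_rejected(self, rng):
        a = rng.uniform(0, 1, (10, 10))
        with pytest.raises(ValueError, match="block"):
            costes_test(a, a, np.ones_like(a, bool), n=10, block_size=20)


class TestLineProfiles:
    def test_identical_channels_correlate_perfectly(self, rng):
        img = rng.uniform(0, 100, (40, 40))
        line = np.array([[5.0, 5.0], [30.0, 30.0]])
        ta, tb, r = line_profile_correlation(img, img, line)
        assert r == pytest.approx(1.0)
        assert len(ta) == len(tb)

    def test_coaligned_hotspots_high_offset_hotspots_low(self):
        """Hotspots at the same arc positions correlate; shifted far apart
        they do not — the tangential line-scan logic."""
        n = 120
        a = np.zeros((20, n))
        b = np.zeros((20, n))
        pos = [15, 45, 75, 105]
        for p in pos:
            a[8:12, p - 3:p + 3] = 100.0
            b[8:12, p - 3:p + 3] = 80.0
        line = np.array([[10.0, 2.0], [10.0, n - 3.0]])
        _, _, r_co = line_profile_correlation(a, b, line)
        b_off = np.roll(b, 15, axis=1)
        _, _, r_off = line_profile_correlation(a, b_off, line)
        assert r_co > 0.8
        assert abs(r_off) < 0.3

    def test_constant_trace_undefined(self):
        img = np.full((20, 20), 5.0)
        line = np.array([[2.0, 2.0], [15.0, 15.0]])
        _, _, r = line_profile_correlation(img, img, line)
        assert math.isnan(r)

    def test_polyline_outside_image_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="outside"):
            line_profile_correlation(img, img, np.array([[0.0, 0.0], [20.0, 5.0]]))
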