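"""Surface-extraction operations: contour interpolation, physical erosion,
surface/subsurface splitting, projections, and reslicing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import rosettex as rx
from rosettex.stack import ContourError, ContourSet
from rosettex.surface import InteriorMask

from conftest import circle_polygon


def make_stack(data, vz=2.0, vxy=0.5):
    return rx.VoxelStack(np.asarray(data, dtype=np.float32), vz, vxy)


# ---------------------------------------------------------------------------
# interpolate_contours
# ---------------------------------------------------------------------------


class TestInterpolateContours:
    def test_dense_input_is_pure_rasterization(self):
        cs = ContourSet({k: [circle_polygon(30, 30, 10 + k)] for k in range(5)})
        out = rx.interpolate_contours(cs, 5, (64, 64))
        for k in range(5):
            assert np.array_equal(out[k], cs.rasterize_slice(k, (64, 64)))

    def test_constant_shape_fills_gap(self):
        poly = circle_polygon(30, 30, 12)
        cs = ContourSet({0: [poly], 10: [poly]})
        out = rx.interpolate_contours(cs, 11, (64, 64))
        ref = cs.rasterize_slice(0, (64, 64))
        for k in range(11):
            assert np.array_equal(out[k], ref)

    def test_concentric_circles_grow_linearly(self):
        cs = ContourSet({0: [circle_polygon(40.5, 40.25, 10)], 10: [circle_polygon(40.5, 40.25, 20)]})
        out = rx.interpolate_contours(cs, 11, (80, 80))
        for k in range(11):
            expected = np.pi * (10 + k) ** 2
            assert out[k].sum() == pytest.approx(expected, rel=0.02)

    def test_outside_range_copies_nearest(self):
        poly = circle_polygon(30, 30, 8)
        cs = ContourSet({3: [poly], 6: [circle_polygon(30, 30, 14)]})
        out = rx.interpolate_contours(cs, 10, (64, 64))
        assert np.array_equal(out[0], out[3])
        assert np.array_equal(out[9], out[6])

    def test_self_intersecting_polygon_rejected_with_slice_index(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
        with pytest.raises(ContourError, match="slice 4"):
            ContourSet({4: [bowtie]})

    def test_nestedness_of_interpolated_slices(self):
        """If contour A lies inside contour B, interpolates stay between them."""
        a = circle_polygon(40, 40, 8)
        b = circle_polygon(40, 40, 20)
        cs = ContourSet({0: [a], 8: [b]})
        out = rx.interpolate_contours(cs, 9, (80, 80))
        mask_a = cs.rasterize_slice(0, (80, 80))
        mask_b = cs.rasterize_slice(8, (80, 80))
        for k in range(9):
            assert (mask_a & ~out[k]).sum() == 0  # contains A
            assert (out[k] & ~mask_b).sum() == 0  # inside B


# ---------------------------------------------------------------------------
# erode_physical
# ---------------------------------------------------------------------------


def brute_force_erode(mask, depth_um, vz, vxy):
    """Independent oracle: all-pairs voxel-center distances in micrometers."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        return mask.copy()
    scale = np.array([vz, vxy, vxy])
    out = np.zeros_like(mask)
    for i in range(0, len(fg), 512):
        chunk = fg[i:i + 512]
        d2 = (((chunk[:, None, :] - bg[None, :, :]) * scale) ** 2).sum(-1).min(1)
        keep = np.sqrt(d2) > depth_um
        out[tuple(chunk[keep].T)] = True
    return out


class TestErodePhysical:
    def test_zero_depth_is_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((8, 16, 16)) > 0.4
        assert np.array_equal(rx.erode_physical(mask, 0.0, 2.0, 1.0), mask)

    def test_depth_beyond_inscribed_radius_annihilates(self):
        mask = np.zeros((16, 32, 32), dtype=bool)
        mask[4:12, 8:24, 8:24] = True  # inscribed radius 8 um at 1 um voxels
        assert not rx.erode_physical(mask, 20.0, 1.0, 1.0).any()

    def test_sphere_oracle(self):
        """Eroding a 30 um sphere by 10 um leaves the analytic (20/30)^3 core."""
        n = 64
        zz, yy, xx = np.mgrid[:n, :n, :n] - n / 2
        mask = zz**2 + yy**2 + xx**2 <= 30.0**2
        out = rx.erode_physical(mask, 10.0, 1.0, 1.0)
        assert out.sum() / mask.sum() == pytest.approx((20.0 / 30.0) ** 3, rel=0.05)
        # surviving boundary voxels sit 10 um (within a voxel diagonal) from
        # the original boundary
        dist = ndimage.distance_transform_edt(mask)
        boundary = out & ~ndimage.binary_erosion(out)
        diag = np.sqrt(3.0)
        assert dist[boundary].min() >= 10.0 - diag
        assert dist[boundary].max() <= 10.0 + 2 * diag

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            shape = tuple(rng.integers(5, 14, size=3))
            mask = ndimage.binary_closing(rng.random(shape) > 0.4)
            depth = float(rng.uniform(0.3, 5.0))
            got = rx.erode_physical(mask, depth, 2.0, 1.0)
            want = brute_force_erode(mask, depth, 2.0, 1.0)
            assert np.array_equal(got, want)

    def test_monotone_in_depth(self):
        rng = np.random.default_rng(3)
        mask = ndimage.binary_closing(rng.random((10, 20, 20)) > 0.35)
        prev = mask
        for depth in (1.0, 2.5, 4.0, 8.0):
            cur = rx.erode_physical(mask, depth, 2.0, 1.0)
            assert not (cur & ~prev).any()  # never adds voxels
            prev = cur

    def test_2d_mode_ignores_z(self):
        mask = np.zeros((3, 21, 21), dtype=bool)
        mask[1, 2:19, 2:19] = True
        out = rx.erode_physical(mask, 3.0, 1.0, 1.0, mode="2d")
        assert out.any()  # survives per-slice erosion
        assert not rx.erode_physical(mask, 3.0, 1.0, 1.0, mode="3d").any()


# ---------------------------------------------------------------------------
# split_surface / project_surface
# ---------------------------------------------------------------------------


class TestSplitSurface:
    def test_full_interior_puts_everything_subsurface(self):
        stack = make_stack(np.random.default_rng(0).random((1, 4, 8, 8)))
        interior = InteriorMask(np.ones((4, 8, 8), dtype=bool), 0.0, 2.0, 0.5)
        split = rx.split_surface(stack, interior, sigma_um=2.0, mode="soft")
        assert np.allclose(split.surface.data, 0.0, atol=1e-6)
        assert np.allclose(split.subsurface.data, stack.data, atol=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), sigma=st.floats(0.0, 5.0))
    def test_soft_mode_conserves_signal(self, seed, sigma):
        rng = np.random.default_rng(seed)
        stack = make_stack(rng.random((2, 4, 10, 10), dtype=np.float64))
        interior = InteriorMask(rng.random((4, 10, 10)) > 0.5, 0.0, 2.0, 0.5)
        split = rx.split_surface(stack, interior, sigma_um=sigma, mode="soft")
        total = split.surface.data + split.subsurface.data
        assert np.abs(total - stack.data).max() <= 1e-6

    def test_fiji_mode_sigma_zero_partitions_nonzero_voxels(self):
        rng = np.random.default_rng(1)
        data = (rng.random((1, 6, 12, 12)).astype(np.float32) * 0.9) + 0.05
        stack = make_stack(data)
        interior = InteriorMask(rng.random((6, 12, 12)) > 0.5, 0.0, 2.0, 0.5)
        split = rx.split_surface(stack, interior, sigma_um=0.0, mode="fiji_subtract")
        in_surface = split.surface.data > 0
        in_subsurface = split.subsurface.data > 0
        nonzero = stack.data > 0
        assert np.array_equal(in_surface ^ in_subsurface, nonzero)

    def test_blur_never_sharpens_weight(self):
        rng = np.random.default_rng(2)
        stack = make_stack(rng.random((1, 8, 24, 24)))
        interior = InteriorMask(rng.random((8, 24, 24)) > 0.5, 0.0, 2.0, 0.5)
        grads = []
        for sigma in (0.5, 1.0, 2.0, 4.0):
            w = rx.split_surface(stack, interior, sigma_um=sigma).weight
            grads.append(max(np.abs(np.diff(w, axis=a)).max() for a in range(3)))
        assert all(a >= b - 1e-6 for a, b in zip(grads, grads[1:]))

    def test_negative_sigma_rejected(self):
        stack = make_stack(np.zeros((1, 2, 4, 4)))
        interior = InteriorMask(np.zeros((2, 4, 4), dtype=bool), 0.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            rx.split_surface(stack, interior, sigma_um=-1.0)

    def test_projection_of_single_slice_is_that_slice(self):
        data = np.random.default_rng(0).random((1, 1, 6, 6)).astype(np.float32)
        stack = make_stack(data)
        interior = InteriorMask(np.zeros((1, 6, 6), dtype=bool), 0.0, 2.0, 0.5)
        split = rx.split_surface(stack, interior, 0.0, "soft")
        assert np.allclose(rx.project_surface(split, "surface")[0], data[0, 0])

    def test_projection_of_zero_stack_is_zero(self):
        stack = make_stack(np.zeros((1, 4, 6, 6)))
        interior = InteriorMask(np.ones((4, 6, 6), dtype=bool), 0.0, 2.0, 0.5)
        split = rx.split_surface(stack, interior, 1.0, "soft")
        assert not rx.project_surface(split, "subsurface").any()


# ---------------------------------------------------------------------------
# slab_projections / reslice
# ---------------------------------------------------------------------------


class TestSlabProjections:
    def test_ten_five_micron_slabs_over_fifty(self):
        stack = make_stack(np.zeros((1, 40, 4, 4)), vz=2.0)
        slabs = rx.slab_projections(stack, 5.0, 50.0, np.zeros((4, 4)))
        assert len(slabs) == 10

    def test_single_slab_equals_max_projection_of_range(self):
        rng = np.random.default_rng(0)
        data = rng.random((1, 20, 6, 6)).astype(np.float32)
        stack = make_stack(data, vz=2.0)
        (slab,) = rx.slab_projections(stack, 40.0, 40.0, np.zeros((6, 6)))
        assert np.allclose(slab, data[0, :20].max(axis=0))

    def test_point_source_lands_in_correct_slab(self):
        stack = make_stack(np.zeros((1, 40, 8, 8)), vz=2.0)
        ref = np.full((8, 8), 1.0)  # surface 1 um above the grid
        stack.data[0, 12, 3, 3] = 1.0  # z = 24 um -> depth 23 um -> slab 4
        slabs = rx.slab_projections(stack, 5.0, 50.0, ref)
        hits = [k for k, s in enumerate(slabs) if s.any()]
        assert hits == [4]

    def test_indivisible_slab_rejected(self):
        stack = make_stack(np.zeros((1, 10, 4, 4)))
        with pytest.raises(ValueError):
            rx.slab_projections(stack, 7.0, 50.0, np.zeros((4, 4)))


class TestReslice:
    def test_constant_stack_stays_constant(self):
        stack = make_stack(np.full((1, 8, 10, 12), 0.3), vz=2.0, vxy=0.5)
        out = rx.reslice(stack, "transverse")
        assert np.allclose(out.data, 0.3)
        assert out.voxel_size_z == stack.voxel_size_xy

    def test_involution_on_isotropic_stack(self):
        rng = np.random.default_rng(0)
        stack = make_stack(rng.random((1, 6, 6, 6)), vz=1.0, vxy=1.0)
        twice = rx.reslice(rx.reslice(stack, "transverse"), "transverse")
        assert np.array_equal(twice.data, stack.data)

    def test_ellipsoid_cross_section_semi_axes(self):
        """Transverse mid-section of a planted ellipsoid keeps its um axes."""
        vz, vxy = 2.0, 0.5
        nz, ny, nx = 32, 96, 96
        az, ay, ax = 14.0, 18.0, 10.0  # um semi-axes
        zz = (np.arange(nz) * vz - 32.0)[:, None, None]
        yy = (np.arange(ny) * vxy - 24.0)[None, :, None]
        xx = (np.arange(nx) * vxy - 24.0)[None, None, :]
        vol = ((zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax) ** 2 <= 1.0).astype(np.float32)
        stack = make_stack(vol[None], vz=vz, vxy=vxy)
        out = rx.reslice(stack, "transverse")
        mid = out.data[0, ny // 2]  # xz plane at the ellipsoid center
        rows = np.nonzero(mid.any(axis=1))[0]
        cols = np.nonzero(mid.any(axis=0))[0]
        z_extent = (rows[-1] - rows[0] + 1) * out.voxel_size_z / 2.0
        x_extent = (cols[-1] - cols[0] + 1) * out.voxel_size_xy / 2.0
        assert z_extent == pytest.approx(az, abs=2 * vz)
        assert x_extent == pytest.approx(ax, abs=2 * vxy)
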