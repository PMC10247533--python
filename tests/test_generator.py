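"""Synthetic embryo generator: determinism, ground-truth consistency,
seed-replay of the documented RNG draw order, and contour annotation."""

import numpy as np
import pytest

import rosettex as rx
from rosettex import PlacementError


class TestParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            rx.EmbryoParams(voxel_size_z=0.0)
        with pytest.raises(ValueError):
            rx.EmbryoParams(lumen_probability=1.5)
        with pytest.raises(ValueError):
            rx.EmbryoParams(n_cells_per_rosette=4)
        with pytest.raises(ValueError):
            rx.EmbryoParams(rosette_depth_range=(0.0, 1e4))

    def test_dict_round_trip(self):
        p = rx.EmbryoParams(seed=9, n_rosettes=3)
        assert rx.EmbryoParams.from_dict(p.to_dict()) == p


class TestStaticStack:
    def test_deterministic_given_seed(self):
        params = rx.EmbryoParams(seed=5, stack_shape=(32, 240, 240),
                                 n_emerged_clusters=1, n_rosettes=2)
        s1, t1 = rx.generate_static_stack(params)
        s2, t2 = rx.generate_static_stack(params)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.cell_label_volume, t2.cell_label_volume)
        assert [r.to_json_dict() for r in t1.rosettes] == [
            r.to_json_dict() for r in t2.rosettes
        ]

    def test_no_rosettes_leaves_subsurface_dark(self):
        params = rx.EmbryoParams(seed=2, n_rosettes=0, n_emerged_clusters=0,
                                 noise_sd=0.0, stack_shape=(32, 192, 192))
        stack, truth = rx.generate_static_stack(params)
        assert truth.rosettes == []
        depth = (np.arange(32)[:, None, None] * 2.0) - truth.surface_height_map[None]
        below = depth > params.shell_thickness + 1.0
        junc = stack.channel("junctional")
        assert junc[below].max() <= params.background_level + 3 * params.noise_sd + 1e-6

    def test_lumen_count_matches_seed_replay_oracle(self, default_embryo):
        """Replays the documented child-3 draw order independently."""
        params, _, truth = default_embryo
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(8)[3])
        expected = [bool(rng.random() < params.lumen_probability)
                    for _ in range(params.n_rosettes)]
        got = [r.has_lumen for r in truth.rosettes]
        assert got == expected
        assert sum(got) == sum(expected)

    def test_exact_rosette_count(self, default_embryo):
        params, _, truth = default_embryo
        assert len(truth.rosettes) == params.n_rosettes

    def test_infeasible_placement_raises(self):
        params = rx.EmbryoParams(seed=0, stack_shape=(32, 200, 200),
                                 n_emerged_clusters=0, n_rosettes=60)
        with pytest.raises(PlacementError):
            rx.generate_static_stack(params)

    def test_rosette_members_within_depth_range(self, default_embryo):
        params, _, truth = default_embryo
        lo, hi = params.rosette_depth_range
        ids = {i for r in truth.rosettes for i in r.cell_label_ids}
        sel = np.isin(truth.cell_label_volume, list(ids))
        zz, yy, xx = np.nonzero(sel)
        depth = zz * params.voxel_size_z - truth.surface_height_map[yy, xx]
        assert depth.min() >= lo - params.voxel_size_z
        assert depth.max() <= hi + params.voxel_size_z

    def test_planted_junctional_signal_detectable(self, basal_embryo):
        """Mean planted junctional intensity clears background + 5 sigma."""
        params, stack, truth = basal_embryo
        junc = stack.channel("junctional")
        for mask in (truth.shell_junction_mask, truth.basal_junction_mask):
            assert junc[mask].mean() >= params.background_level + 5 * params.noise_sd

    def test_emerged_label_consistent_with_height_map(self, default_embryo):
        params, _, truth = default_embryo
        assert truth.emerged_label_mask.shape == truth.surface_height_map.shape
        assert set(np.unique(truth.emerged_label_mask)) <= {0, 1, 2}
        # every labelled cluster pixel is emerged mesoderm
        assert np.all(truth.emerged_label_mask[truth.emerged_cluster_labels > 0] == 2)

    def test_lumen_geometry_has_positive_analytic_volume(self, default_embryo):
        _, _, truth = default_embryo
        for r in truth.rosettes:
            assert r.has_lumen == (r.lumen is not None)
            if r.lumen:
                assert r.lumen["volume_um3"] > 0


class TestLumenRasterization:
    @pytest.mark.parametrize("kind,radius,length", [
        ("sphere", 3.0, None), ("sphere", 4.0, None), ("sphere", 5.0, None),
        ("tube", 3.0, 18.0), ("tube", 4.0, 20.0),
    ])
    def test_voxelized_volume_near_analytic(self, kind, radius, length):
        """Rasterised negative space tracks the analytic primitive volume."""
        stack, truth = rx.generate_lumen_phantom(
            kind, radius, length_um=length or 20.0, voxel_size_z=1.0,
            voxel_size_xy=0.5)
        lum = rx.analyze_lumen(stack.data[0], truth["center_um"], 1.0, 0.5)
        assert lum.has_lumen
        assert lum.volume_um3 == pytest.approx(truth["analytic_volume_um3"], rel=0.10)


class TestContours:
    def test_stride_arithmetic(self):
        params = rx.EmbryoParams(seed=1, n_rosettes=0, n_emerged_clusters=0,
                                 stack_shape=(32, 192, 192))
        _, truth = rx.generate_static_stack(params)
        cs = rx.generate_contours(truth, stride_near=3, stride_deep=3, jitter_um=0.0)
        assert cs.annotated_slices == sorted(set(range(0, 32, 3)) | {31})

    def test_dense_contours_reproduce_interior_exactly(self):
        params = rx.EmbryoParams(seed=2, n_rosettes=0, n_emerged_clusters=0,
                                 stack_shape=(32, 192, 192))
        _, truth = rx.generate_static_stack(params)
        cs = rx.generate_contours(truth, stride_near=1, stride_deep=1, jitter_um=0.0)
        filled = rx.interpolate_contours(cs, 32, truth.interior_mask.shape[1:])
        assert np.array_equal(filled, truth.interior_mask)

    def test_strides_below_one_rejected(self, default_embryo):
        _, _, truth = default_embryo
        with pytest.raises(ValueError):
            rx.generate_contours(truth, stride_near=0)
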