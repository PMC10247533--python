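"""Rosette analysis: location classes, lumens, junctional staging, granule
detection, and marker-distribution calls."""

import numpy as np
import pytest

import rosettex as rx
from rosettex.patches import render_stage_pattern
from rosettex.rosettes import MARKER_CATEGORIES


def flat_geometry(nz=30, ny=60, nx=60, vz=1.0, vxy=0.5, shell_um=3.0):
    """Flat surface at z = 0 with an endoderm shell; hand-built masks."""
    h = np.zeros((ny, nx))
    z_um = np.arange(nz)[:, None, None] * vz
    endoderm = (z_um >= 0) & (z_um < shell_um)
    endoderm = np.broadcast_to(endoderm, (nz, ny, nx)).copy()
    return h, endoderm, vz, vxy


class TestRosetteLocation:
    def test_deep_rosette_is_basal(self):
        h, endo, vz, vxy = flat_geometry()
        apical = np.zeros(endo.shape, dtype=bool)
        apical[20:24, 28:32, 28:32] = True  # 20 um down, far from the shell
        cls = rx.classify_rosette_location((22.0, 15.0, 15.0), apical, h, endo, vz, vxy,
                                           cell_diameter_um=10.0)
        assert cls == "basal"

    def test_surface_breach_is_partially_emerged(self):
        h, endo, vz, vxy = flat_geometry()
        apical = np.zeros(endo.shape, dtype=bool)
        apical[0:8, 28:32, 28:32] = True  # open to the exterior surface
        cls = rx.classify_rosette_location((3.0, 15.0, 15.0), apical, h, endo, vz, vxy)
        assert cls == "partially_emerged"

    def test_single_voxel_adjacency_is_endoderm_contacting(self):
        """One apical voxel touching the shell flips basal to contacting,
        matching the closest-region precedence rule."""
        h, endo, vz, vxy = flat_geometry()
        apical = np.zeros(endo.shape, dtype=bool)
        apical[8:14, 28:32, 28:32] = True  # deep body...
        cls = rx.classify_rosette_location((11.0, 15.0, 15.0), apical, h, endo, vz, vxy)
        assert cls == "basal"
        apical[3, 29, 29] = True  # ...plus one voxel adjacent to the shell
        cls = rx.classify_rosette_location((11.0, 15.0, 15.0), apical, h, endo, vz, vxy)
        assert cls == "endoderm_contacting"

    def test_center_outside_stack_rejected(self):
        h, endo, vz, vxy = flat_geometry()
        with pytest.raises(ValueError):
            rx.classify_rosette_location((500.0, 0.0, 0.0), endo, h, endo, vz, vxy)

    def test_planted_classes_recovered_exactly(self, default_embryo):
        """100% agreement with generator location labels at zero noise."""
        params, stack, truth = default_embryo
        apical = stack.channel("apical")
        mask = apical > params.background_level + 0.5 * params.signal_level
        for r in truth.rosettes:
            cls = rx.classify_rosette_location(
                r.center_um, mask, truth.surface_height_map, truth.shell_mask,
                params.voxel_size_z, params.voxel_size_xy,
                params.mesoderm_cell_diameter)
            assert cls == r.location_class


class TestLumen:
    def test_solid_focus_has_no_lumen(self):
        vol = np.full((20, 40, 40), 0.1, dtype=np.float32)
        vol[8:13, 16:24, 16:24] = 0.9  # solid apical focus
        lum = rx.analyze_lumen(vol, (10.0, 10.0, 10.0), 1.0, 0.5)
        assert not lum.has_lumen
        assert lum.volume_um3 == 0.0

    def test_sphere_volume_tracks_four_thirds_pi_r_cubed(self):
        stack, truth = rx.generate_lumen_phantom("sphere", 4.0)
        lum = rx.analyze_lumen(stack.data[0], truth["center_um"], 1.0, 0.5)
        assert lum.has_lumen
        assert lum.volume_um3 == pytest.approx(268.08, rel=0.10)
        assert not lum.elongated

    def test_tube_volume_and_elongation(self):
        stack, truth = rx.generate_lumen_phantom("tube", 3.0, length_um=20.0)
        lum = rx.analyze_lumen(stack.data[0], truth["center_um"], 1.0, 0.5)
        assert lum.has_lumen
        assert lum.volume_um3 == pytest.approx(565.49, rel=0.10)
        assert lum.elongated

    def test_volume_monotone_in_radius(self):
        vols = []
        for r in (3.0, 4.0, 5.0):
            stack, truth = rx.generate_lumen_phantom("sphere", r)
            vols.append(rx.analyze_lumen(stack.data[0], truth["center_um"], 1.0, 0.5).volume_um3)
        assert vols == sorted(vols)

    def test_planted_lumen_presence_recovered(self, default_embryo):
        params, stack, truth = default_embryo
        apical = stack.channel("apical")
        for r in truth.rosettes:
            lum = rx.analyze_lumen(apical, r.center_um, params.voxel_size_z,
                                   params.voxel_size_xy)
            assert lum.has_lumen == r.has_lumen


class TestStaging:
    @pytest.mark.parametrize("stage", ["spot", "edge", "early_rosette", "late_rosette"])
    def test_rendered_patterns_recover_their_stage(self, stage):
        rng = np.random.default_rng(0)
        img, meta = render_stage_pattern(stage, n_cells=6, rng=rng)
        got = rx.stage_junctional_region(img, meta["cell_vertex_count"],
                                         meta["pixel_size_um"])
        assert got == stage

    def test_six_cell_vertex_blob_is_early_rosette(self):
        """Uninterrupted central signal at a >= 5-cell vertex."""
        img, meta = render_stage_pattern("early_rosette", n_cells=6,
                                         rng=np.random.default_rng(1))
        assert rx.stage_junctional_region(img, 6, 0.5) == "early_rosette"

    def test_micron_punctum_is_spot(self):
        img = np.zeros((40, 40))
        img[19:21, 19:21] = 1.0  # 1 um Feret at 0.5 um/px
        assert rx.stage_junctional_region(img, 2, 0.5) == "spot"

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            rx.stage_junctional_region(np.zeros((20, 20)), 5, 0.5)

    def test_planted_stages_recovered_exactly(self, default_embryo):
        """Generator-labelled stages agree 100% at zero noise."""
        params, stack, truth = default_embryo
        junc = stack.channel("junctional")
        vz, vxy = params.voxel_size_z, params.voxel_size_xy
        for r in truth.rosettes:
            cz, cy, cx = r.center_um
            kc, iy, ix = int(round(cz / vz)), int(round(cy / vxy)), int(round(cx / vxy))
            w = 20
            patch = junc[kc, iy - w: iy + w, ix - w: ix + w].copy()
            yy, xx = np.mgrid[-w:w, -w:w]
            patch[(yy**2 + xx**2) > (8.0 / vxy) ** 2] = 0.0
            assert rx.stage_junctional_region(patch, r.n_cells, vxy) == r.stage


class TestGranules:
    def test_empty_channel_yields_no_granules(self):
        vol = np.full((20, 30, 30), 0.1, dtype=np.float32)
        gs = rx.detect_granules(vol, 0.5, 0.5, background=0.1, noise_sd=0.02)
        assert len(gs) == 0

    def test_default_band_is_one_to_two_microns(self):
        vol = np.full((10, 10, 10), 0.1, dtype=np.float32)
        gs = rx.detect_granules(vol, 0.5, 0.5, background=0.1, noise_sd=0.02)
        assert gs.diameter_band_um == (1.0, 2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_granules_found_exactly(self, seed):
        """Perfect precision and recall at SNR 10, centers within 1 um."""
        stack, truth = rx.generate_granule_field(n_granules=12, diameter_um=1.5,
                                                 snr=10.0, seed=seed)
        gs = rx.detect_granules(stack.channel("granule"), 0.5, 0.5,
                                background=0.1, noise_sd=0.02)
        assert len(gs) == 12
        det = gs.centers_um
        used = set()
        for p in truth["centers_um"]:
            d = np.linalg.norm(det - p, axis=1)
            j = int(np.argmin(d))
            assert d[j] <= 1.0 and j not in used
            used.add(j)

    def test_cofluor_positivity_flags(self):
        stack, truth = rx.generate_granule_field(n_granules=8, diameter_um=1.5,
                                                 snr=12.0, seed=4,
                                                 cofluor_fraction=0.5)
        gs = rx.detect_granules(stack.channel("granule"), 0.5, 0.5,
                                background=0.1, noise_sd=0.02,
                                cofluor={"apkc": stack.channel("cofluor")})
        det = gs.df
        for p, co in zip(truth["centers_um"], truth["cofluor"]):
            d = np.linalg.norm(det[["z_um", "y_um", "x_um"]].to_numpy() - p, axis=1)
            assert bool(det.iloc[int(np.argmin(d))]["co_apkc"]) == bool(co)


class TestMarkerDistribution:
    def _scene(self, granular, membranous):
        shape = (16, 40, 40)
        marker = np.full(shape, 0.1, dtype=np.float32)
        region = np.zeros(shape, dtype=bool)
        region[2:14, 5:35, 5:35] = True
        memb = np.zeros(shape, dtype=bool)
        memb[7:9, 15:25, 15:25] = True
        junc = np.zeros(shape, dtype=bool)
        junc[8, 19:21, 19:21] = True
        import pandas as pd

        rows = []
        if granular:
            marker[4:6, 10:12, 10:12] = 0.8
            rows.append(dict(z_um=2.5, y_um=5.5, x_um=5.5, diameter_um=1.5))
        if membranous:
            marker[memb] = 0.8
        granules = rx.GranuleSet(df=pd.DataFrame(rows, columns=["z_um", "y_um", "x_um", "diameter_um"]),
                                 diameter_band_um=(1.0, 2.0))
        return granules, marker, memb, junc, region

    def test_category_vocabulary(self):
        assert MARKER_CATEGORIES == ("none", "granular", "transitional", "apical",
                                     "junctional")

    def test_all_zero_marker_is_none(self):
        granules, marker, memb, junc, region = self._scene(False, False)
        got = rx.classify_marker_distribution(granules, marker, memb, junc, region,
                                              background=0.1, noise_sd=0.02)
        assert got == "none"

    @pytest.mark.parametrize("granular,membranous,expected", [
        (True, False, "granular"),
        (False, True, "apical"),
        (True, True, "transitional"),
    ])
    def test_channel_compositions(self, granular, membranous, expected):
        granules, marker, memb, junc, region = self._scene(granular, membranous)
        got = rx.classify_marker_distribution(granules, marker, memb, junc, region,
                                              background=0.1, noise_sd=0.02)
        assert got == expected

    def test_junctional_colocalization_call(self):
        granules, marker, memb, junc, region = self._scene(False, False)
        marker[junc] = 0.8
        got = rx.classify_marker_distribution(granules, marker, memb, junc, region,
                                              background=0.1, noise_sd=0.02)
        assert got == "junctional"
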