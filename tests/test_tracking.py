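"""Region tracking and the epithelial event taxonomy."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

import rosettex as rx
from rosettex.morphometrics import RegionTable


def table_from_disks(disks, shape=(64, 64), px=1.0):
    """Build a RegionTable from (cy, cx, r, emerged, state) tuples."""
    label = np.zeros(shape, dtype=np.int32)
    rows = []
    for i, (cy, cx, r, emerged, state) in enumerate(disks, start=1):
        rr, cc = draw_disk((cy, cx), r, shape=shape)
        label[rr, cc] = i
        rows.append(dict(region_id=i, emerged=emerged, area_um2=len(rr) * px * px,
                         centroid_x_um=cx * px, centroid_y_um=cy * px,
                         state=state, border_touch=False))
    cols = ["region_id", "emerged", "area_um2", "centroid_x_um", "centroid_y_um",
            "state", "border_touch"]
    return RegionTable(df=pd.DataFrame(rows, columns=cols), label_image=label,
                       pixel_size_um=px)


class TestClassifyState:
    def test_filled_disk_is_pre_cluster(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = draw_disk((20, 20), 6, shape=mask.shape)
        mask[rr, cc] = True
        assert rx.classify_state(mask, 1.0) == "pre_cluster"

    def test_annulus_with_ten_um2_hole_is_cluster(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = draw_disk((20, 20), 8, shape=mask.shape)
        mask[rr, cc] = True
        rr, cc = draw_disk((20, 20), 1.8, shape=mask.shape)  # ~10 um^2 hole
        mask[rr, cc] = False
        assert rx.classify_state(mask, 1.0) == "cluster"

    def test_sub_minimum_patch_ignored(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        assert rx.classify_state(mask, 1.0, min_area_um2=5.0) is None


class TestBuildTracks:
    def test_static_region_yields_one_track(self):
        tabs = [table_from_disks([(20, 20, 5, False, "pre_cluster")]) for _ in range(5)]
        g = rx.build_tracks(tabs)
        assert len(g.tracks) == 1
        assert len(g.edges) == 4
        assert not g.merges

    def test_gap_closing_bridges_one_missing_frame(self):
        present = table_from_disks([(20, 20, 5, False, "pre_cluster")])
        absent = table_from_disks([])
        g = rx.build_tracks([present, present, absent, present, present])
        assert len(g.tracks) == 1

    def test_converging_regions_create_merge_node(self, movie_run):
        g = movie_run["graph"]
        sched = [e for e in movie_run["schedule"] if e.kind == "coalescence"]
        assert len(g.merges) == len(sched)
        assert sorted(m["frame"] for m in g.merges) == sorted(e.frame for e in sched)

    def test_every_observation_in_exactly_one_track(self, movie_run):
        g = movie_run["graph"]
        seen = [k for keys in g.tracks.values() for k in keys]
        assert len(seen) == len(set(seen)) == len(g.nodes)


class TestPreclusterOutcomes:
    def _graph(self, states_per_track, n_frames):
        """Build a TrackGraph directly from per-frame state sequences."""
        tabs = []
        for f in range(n_frames):
            disks = []
            for i, states in enumerate(states_per_track):
                if f < len(states) and states[f] is not None:
                    disks.append((10 + 14 * i, 20, 5, False, states[f]))
            tabs.append(table_from_disks(disks, shape=(80, 64)))
        return rx.build_tracks(tabs)

    def test_everlasting_pre_cluster_is_persistence(self):
        g = self._graph([["pre_cluster"] * 6], 6)
        log = rx.detect_precluster_outcomes(g)
        assert log.counts() == {"persistence": 1}

    def test_transition_to_cluster_is_expansion_at_that_frame(self):
        states = ["pre_cluster"] * 4 + ["cluster"] * 4
        g = self._graph([states], 8)
        log = rx.detect_precluster_outcomes(g)
        (ev,) = log.events
        assert ev["kind"] == "expansion"
        assert ev["frame"] == 4

    def test_early_disappearance_is_disassembly(self):
        states = ["pre_cluster"] * 3 + [None] * 5
        g = self._graph([states], 8)
        log = rx.detect_precluster_outcomes(g)
        assert log.counts() == {"disassembly": 1}

    def test_outcomes_partition_pre_cluster_tracks(self, movie_run):
        g = movie_run["graph"]
        log = rx.detect_precluster_outcomes(g)
        n_pre = sum(1 for keys in g.tracks.values()
                    if g.nodes[keys[0]]["state"] == "pre_cluster")
        assert sum(log.counts().values()) == n_pre

    def test_planted_outcome_counts_recovered(self, movie_run):
        from rosettex.movie import expected_outcome_counts

        log = rx.detect_precluster_outcomes(movie_run["graph"])
        expected = expected_outcome_counts(movie_run["schedule"], movie_run["roster"])
        got = log.counts()
        for kind, n in expected.items():
            assert got.get(kind, 0) == n


class TestCoalescence:
    def test_no_merges_counts_zero(self):
        tabs = [table_from_disks([(20, 20, 5, False, "pre_cluster")]) for _ in range(3)]
        n, recs = rx.count_coalescence(rx.build_tracks(tabs))
        assert n == 0 and recs == []

    def test_three_way_merge_counts_once(self):
        before = table_from_disks([
            (20, 16, 3.5, False, "pre_cluster"),
            (20, 24, 3.5, False, "pre_cluster"),
            (20, 32, 3.5, False, "pre_cluster"),
        ])
        after = table_from_disks([(20, 24, 12, False, "pre_cluster")])
        graph = rx.build_tracks([before, before, after, after], link_min_iou=0.05)
        n, recs = rx.count_coalescence(graph)
        assert n == 1
        assert recs[0]["n_participants"] == 3

    def test_state_pair_recorded_at_merge_time(self, movie_run):
        _, recs = rx.count_coalescence(movie_run["graph"])
        for r in recs:
            assert r["state_pair"] == ("pre_cluster", "pre_cluster")


class TestEmergence:
    def _two_frame_graph(self, emerged_seq):
        tabs = [table_from_disks([(20, 20, 5, e, "pre_cluster")]) for e in emerged_seq]
        return rx.build_tracks(tabs)

    def test_emerged_at_both_endpoints_remains_emerged(self):
        g = self._two_frame_graph([True, True, True])
        assert rx.classify_emergence(g, 0) == "remains_emerged"

    def test_unemerged_throughout_does_not_emerge(self):
        g = self._two_frame_graph([False, False, False])
        assert rx.classify_emergence(g, 0) == "does_not_emerge"

    def test_submergence_is_not_emergence(self):
        """Time-reversal asymmetry: ending below the surface is never scored
        as emerging, whatever happened in between."""
        g = self._two_frame_graph([True, True, False])
        assert rx.classify_emergence(g, 0) == "does_not_emerge"

    def test_planted_emergence_frames_recovered(self, movie_run):
        g = movie_run["graph"]
        counts = {}
        for tid in g.tracks:
            c = rx.classify_emergence(g, tid)
            counts[c] = counts.get(c, 0) + 1
        n_emerge = sum(1 for e in movie_run["schedule"] if e.kind == "emergence")
        assert counts.get("emerges", 0) == n_emerge
        assert counts.get("remains_emerged", 0) == 1  # one planted surface region


class TestApicalSeries:
    def test_default_sample_times(self):
        df = pd.DataFrame(dict(cell_id=[1] * 20, frame=range(1, 21),
                               area_um2=np.linspace(5, 25, 20)))
        out = rx.apical_area_series(df, 12.0)
        assert sorted(out.time_min.unique()) == [12.0, 36.0, 180.0]

    def test_constant_area_gives_flat_series(self):
        df = pd.DataFrame(dict(cell_id=[1] * 20, frame=range(1, 21),
                               area_um2=[7.0] * 20))
        out = rx.apical_area_series(df, 12.0)
        assert np.allclose(out.area_um2.dropna(), 7.0)

    def test_linear_expansion_slope_recovered(self):
        """1 um^2 per 12-min frame is recovered within 10% from the samples."""
        frames = np.arange(1, 31)
        df = pd.DataFrame(dict(cell_id=[1] * 30, frame=frames,
                               area_um2=5.0 + 1.0 * (frames - 1)))
        out = rx.apical_area_series(df, 12.0, sample_times_min=(12.0, 36.0, 180.0))
        t = out.time_min.to_numpy()
        a = out.area_um2.to_numpy()
        slope_per_min = np.polyfit(t, a, 1)[0]
        assert slope_per_min * 12.0 == pytest.approx(1.0, rel=0.10)

    def test_times_beyond_track_life_flagged_missing(self):
        df = pd.DataFrame(dict(cell_id=[1] * 3, frame=[4, 5, 6], area_um2=[1., 2., 3.]))
        out = rx.apical_area_series(df, 12.0)
        assert not out[out.time_min == 180.0].available.iloc[0]
        assert np.isnan(out[out.time_min == 180.0].area_um2.iloc[0])

    def test_non_multiple_sample_time_rejected(self):
        df = pd.DataFrame(dict(cell_id=[1], frame=[0], area_um2=[1.0]))
        with pytest.raises(ValueError):
            rx.apical_area_series(df, 12.0, sample_times_min=(10.0,))
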