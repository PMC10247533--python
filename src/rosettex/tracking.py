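"""Tracking of junctional regions through time-lapse projections.

Regions segmented per frame (on surface and subsurface projections) are
linked by mask overlap into a :class:`TrackGraph`, from which the event
taxonomy of epithelial assembly is derived: pre-cluster outcomes
(expansion / persistence / disassembly), coalescence events (two or more
regions merging into one), and emergence classes over the imaging window.

State vocabulary: a *pre-cluster* is a solid junctional domain; a
*cluster* encloses at least one background hole (a visible apical
domain).  Linking is greedy by intersection-over-union with 1-frame gap
closing — an operationalisation of the manual tracking it automates, with
the synthetic generator as arbiter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .morphometrics import RegionTable
from .surface import InteriorMask, erode_physical, project_surface, split_surface

__all__ = [
    "TrackGraph",
    "EventLog",
    "classify_state",
    "segment_movie_frames",
    "build_tracks",
    "detect_precluster_outcomes",
    "count_coalescence",
    "classify_emergence",
    "apical_area_series",
]


def classify_state(
    region_mask: np.ndarray,
    pixel_size_um: float,
    hole_min_um2: float = 3.0,
    min_area_um2: float = 5.0,
) -> str | None:
    """Classify a 2D region mask as ``pre_cluster`` or ``cluster``.

    A region is a cluster when it encloses at least one background hole of
    area >= ``hole_min_um2``; otherwise it is a solid pre-cluster.
    Regions below ``min_area_um2`` are ignored (returns ``None``).
    """
    mask = np.asarray(region_mask, dtype=bool)
    px2 = pixel_size_um**2
    if mask.sum() * px2 < min_area_um2:
        return None
    holes = sk_label(~mask, connectivity=1)
    ny, nx = mask.shape
    for p in regionprops(holes):
        r0, c0, r1, c1 = p.bbox
        if r0 == 0 or c0 == 0 or r1 == ny or c1 == nx:
            continue
        if p.area * px2 >= hole_min_um2:
            return "cluster"
    return "pre_cluster"


def _segment_blobs(proj, pixel_size_um, threshold, min_region_um2, emerged,
                   label_img, rows, next_id, hole_min_um2):
    mask = proj > threshold
    if not mask.any():
        return next_id
    labels = sk_label(mask, connectivity=2)
    ny, nx = mask.shape
    for p in regionprops(labels):
        area = p.area * pixel_size_um**2
        if area < min_region_um2:
            continue
        m = labels == p.label
        state = classify_state(m, pixel_size_um, hole_min_um2=hole_min_um2,
                               min_area_um2=min_region_um2)
        cy, cx = p.centroid
        r0, c0, r1, c1 = p.bbox
        rows.append(dict(
            region_id=next_id, emerged=emerged, area_um2=area,
            centroid_x_um=cx * pixel_size_um, centroid_y_um=cy * pixel_size_um,
            state=state,
            border_touch=bool(r0 == 0 or c0 == 0 or r1 == ny or c1 == nx),
        ))
        label_img[m] = next_id
        next_id += 1
    return next_id


def segment_movie_frames(
    frames,
    interior: InteriorMask,
    sigma_um: float = 2.0,
    threshold: float | None = None,
    min_region_um2: float = 5.0,
    hole_min_um2: float = 3.0,
) -> list[RegionTable]:
    """Per-frame region tables from a movie of junctional stacks.

    The interior mask is computed once (movie geometry is static; see
    :func:`movie_interior`); each frame is surface-split against it and its
    surface/subsurface projections are thresholded and labelled.  Regions
    from the surface projection are flagged emerged, regions from the
    subsurface projection unemerged.
    """
    if len(frames) < 2:
        raise ValueError("need >= 2 frames")
    if interior is None:
        raise ValueError("segment_movie_frames requires an InteriorMask")
    tables = []
    for stack in frames:
        split = split_surface(stack, interior, sigma_um=sigma_um, mode="soft")
        surf = project_surface(split, "surface")[0]
        sub = project_surface(split, "subsurface")[0]
        if threshold is None:
            both = np.concatenate([surf.ravel(), sub.ravel()])
            thr = threshold_otsu(both) if both.max() > both.min() else np.inf
        else:
            thr = threshold
        rows: list[dict] = []
        label_img = np.zeros(surf.shape, dtype=np.int32)
        nid = 1
        nid = _segment_blobs(surf, stack.voxel_size_xy, thr, min_region_um2, True,
                             label_img, rows, nid, hole_min_um2)
        nid = _segment_blobs(sub, stack.voxel_size_xy, thr, min_region_um2, False,
                             label_img, rows, nid, hole_min_um2)
        cols = ["region_id", "emerged", "area_um2", "centroid_x_um",
                "centroid_y_um", "state", "border_touch"]
        tables.append(RegionTable(df=pd.DataFrame(rows, columns=cols),
                                  label_image=label_img,
                                  pixel_size_um=stack.voxel_size_xy))
    return tables


def movie_interior(height_map: np.ndarray, stack, erode_um: float = 10.0) -> InteriorMask:
    """Interior mask for a movie with static geometry, from its height map."""
    nz = stack.shape_zyx[0]
    z_um = np.arange(nz)[:, None, None] * stack.voxel_size_z
    filled = z_um >= np.asarray(height_map)[None]
    eroded = erode_physical(filled, erode_um, stack.voxel_size_z, stack.voxel_size_xy)
    return InteriorMask(eroded, erode_um, stack.voxel_size_z, stack.voxel_size_xy)


@dataclass
class TrackGraph:
    """Linked region observations over time.

    ``nodes`` maps ``(frame, region_id)`` to its observation dict (area,
    state, emerged, track).  ``edges`` link consecutive (or 1-gap) frames.
    ``merges`` record nodes with >= 2 predecessors.  ``tracks`` maps track
    id to its ordered node keys; a merge continues the largest
    predecessor's track and records the absorbed tracks.
    """

    nodes: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)
    tracks: dict = field(default_factory=dict)
    merges: list = field(default_factory=list)
    merged_into: dict = field(default_factory=dict)  # absorbed track -> surviving track
    n_frames: int = 0

    def track_nodes(self, track_id):
        return [self.nodes[k] for k in self.tracks[track_id]]


def _iou_matrix(lab_a: np.ndarray, lab_b: np.ndarray):
    ids_a = np.unique(lab_a[lab_a > 0])
    ids_b = np.unique(lab_b[lab_b > 0])
    if len(ids_a) == 0 or len(ids_b) == 0:
        return ids_a, ids_b, np.zeros((len(ids_a), len(ids_b)))
    na = ids_a.max() + 1
    nb = ids_b.max() + 1
    joint = lab_a.astype(np.int64) * nb + lab_b.astype(np.int64)
    counts = np.bincount(joint.ravel(), minlength=na * nb).reshape(na, nb)
    area_a = counts.sum(axis=1)
    area_b = counts.sum(axis=0)
    inter = counts[np.ix_(ids_a, ids_b)].astype(float)
    union = area_a[ids_a, None] + area_b[None, ids_b] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return ids_a, ids_b, iou


def build_tracks(tables: list[RegionTable], link_min_iou: float = 0.25,
                 gap_closing: bool = True) -> TrackGraph:
    """Greedy overlap linking of per-frame regions into a track graph.

    Each region links forward to the region (in the next frame, or the one
    after when gap closing) with which its mask IoU is largest, provided
    it reaches ``link_min_iou``.  Many-to-one links become merge nodes.
    Every region observation belongs to exactly one track node.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 frames to track")
    g = TrackGraph(n_frames=len(tables))
    for f, tab in enumerate(tables):
        for _, row in tab.df.iterrows():
            g.nodes[(f, int(row.region_id))] = dict(
                frame=f, region_id=int(row.region_id),
                area_um2=float(row.area_um2),
                state=row.get("state"),
                emerged=bool(row.emerged),
                border_touch=bool(row.get("border_touch", False)),
                track=None,
            )
    # forward links
    out_link: dict = {}
    incoming: dict = {}
    for f in range(len(tables) - 1):
        targets = [(f + 1, tables[f + 1])]
        if gap_closing and f + 2 < len(tables):
            targets.append((f + 2, tables[f + 2]))
        linked_now = set()
        for tf, ttab in targets:
            ids_a, ids_b, iou = _iou_matrix(tables[f].label_image, ttab.label_image)
            for ai, a in enumerate(ids_a):
                if (f, int(a)) in out_link or (f, int(a)) in linked_now:
                    continue
                if iou.shape[1] == 0:
                    continue
                bi = int(np.argmax(iou[ai]))
                if iou[ai, bi] >= link_min_iou:
                    src, dst = (f, int(a)), (tf, int(ids_b[bi]))
                    out_link[src] = dst
                    incoming.setdefault(dst, []).append(src)
                    g.edges.append((src, dst))
                    linked_now.add(src)
    # track assignment, frame by frame
    next_track = 0
    for f in range(len(tables)):
        for key, node in ((k, v) for k, v in g.nodes.items() if k[0] == f):
            preds = incoming.get(key, [])
            if not preds:
                node["track"] = next_track
                g.tracks[next_track] = [key]
                next_track += 1
            elif len(preds) == 1:
                t = g.nodes[preds[0]]["track"]
                node["track"] = t
                g.tracks[t].append(key)
            else:
                preds_sorted = sorted(
                    preds, key=lambda p: g.nodes[p]["area_um2"], reverse=True
                )
                t = g.nodes[preds_sorted[0]]["track"]
                node["track"] = t
                g.tracks[t].append(key)
                absorbed = [g.nodes[p]["track"] for p in preds_sorted[1:]]
                for a in absorbed:
                    g.merged_into[a] = t
                g.merges.append(dict(
                    frame=f, node=key,
                    predecessors=preds,
                    predecessor_states=[g.nodes[p]["state"] for p in preds],
                    surviving_track=t, absorbed_tracks=absorbed,
                ))
    return g


@dataclass
class EventLog:
    """Derived events: pre-cluster outcomes, coalescences, emergences."""

    events: list = field(default_factory=list)

    def of_kind(self, kind: str) -> list:
        return [e for e in self.events if e["kind"] == kind]

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for e in self.events:
            out[e["kind"]] = out.get(e["kind"], 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)


def detect_precluster_outcomes(graph: TrackGraph,
                               suppress_border: bool = False) -> EventLog:
    """Assign each pre-cluster track exactly one outcome.

    Expansion at the first pre-cluster -> cluster transition; disassembly
    when the track ends before the final frame without merging into
    another region; persistence otherwise.  With ``suppress_border``,
    disappearance of a border-touching region is not called disassembly
    (regions can leave a real field of view; synthetic movies never do).
    """
    log = EventLog()
    for tid, keys in graph.tracks.items():
        first = graph.nodes[keys[0]]
        if first["state"] != "pre_cluster":
            continue
        nodes = [graph.nodes[k] for k in keys]
        expansion_frame = None
        for prev, cur in zip(nodes, nodes[1:]):
            if prev["state"] == "pre_cluster" and cur["state"] == "cluster":
                expansion_frame = cur["frame"]
                break
        if nodes[0]["state"] == "pre_cluster" and expansion_frame is None and \
                any(n["state"] == "cluster" for n in nodes):
            expansion_frame = next(n["frame"] for n in nodes if n["state"] == "cluster")
        if expansion_frame is not None:
            log.events.append(dict(kind="expansion", frame=expansion_frame,
                                   track_ids=(tid,)))
            continue
        last = nodes[-1]
        ended_early = last["frame"] < graph.n_frames - 1
        merged = tid in graph.merged_into
        if ended_early and not merged and not (suppress_border and last["border_touch"]):
            log.events.append(dict(kind="disassembly", frame=last["frame"] + 1,
                                   track_ids=(tid,)))
        else:
            log.events.append(dict(kind="persistence", frame=last["frame"],
                                   track_ids=(tid,)))
    return log


def count_coalescence(graph: TrackGraph):
    """One event per merge node, however many regions participate at once."""
    records = []
    for m in graph.merges:
        records.append(dict(
            kind="coalescence", frame=m["frame"],
            track_ids=tuple(sorted({graph.nodes[p]["track"] for p in m["predecessors"]}
                                   | set(m["absorbed_tracks"]) | {m["surviving_track"]})),
            n_participants=len(m["predecessors"]),
            state_pair=tuple(sorted(s or "?" for s in m["predecessor_states"])),
        ))
    return len(records), records


def classify_emergence(graph: TrackGraph, track_id: int,
                       t_start: int = 0, t_end: int | None = None) -> str:
    """Endpoint emergence class of one track.

    Below the surface at both endpoints: ``does_not_emerge``; on the
    surface at both: ``remains_emerged``; below at the start (or first
    detection) and on the surface at the end: ``emerges``.  Only monotone
    "increasingly emerged" progress counts as emerging, so a track that
    emerges and then submerges again by the end is ``does_not_emerge``
    under the endpoint rule (a documented asymmetry under time reversal).
    """
    keys = graph.tracks[track_id]
    nodes = [graph.nodes[k] for k in keys]
    if t_end is None:
        t_end = graph.n_frames - 1
    window = [n for n in nodes if t_start <= n["frame"] <= t_end]
    if not window:
        raise ValueError(f"track {track_id} has no observations in the window")
    start_emerged = window[0]["emerged"]
    end_emerged = window[-1]["emerged"]
    if start_emerged and end_emerged:
        return "remains_emerged"
    if not start_emerged and end_emerged:
        return "emerges"
    return "does_not_emerge"


def apical_area_series(
    cell_areas: pd.DataFrame,
    frame_interval_min: float,
    sample_times_min=(12.0, 36.0, 180.0),
) -> pd.DataFrame:
    """Per-cell apical areas at fixed times after first visibility.

    ``cell_areas`` has columns ``cell_id, frame, area_um2``; t = 0 is the
    frame before a cell's apical domain is first visible, so the first
    sample (default 12 min, one frame) is the first visible observation.
    Sample times must be multiples of the frame interval; samples beyond a
    cell's record are missing values, flagged in ``available``.
    """
    times = sorted(sample_times_min)
    if any(t < 0 for t in times) or len(set(times)) != len(times):
        raise ValueError("sample times must be unique and nonnegative")
    for t in times:
        if abs(t / frame_interval_min - round(t / frame_interval_min)) > 1e-9:
            raise ValueError(f"sample time {t} min is not a frame-interval multiple")
    rows = []
    for cid, grp in cell_areas.groupby("cell_id"):
        grp = grp.sort_values("frame")
        f0 = int(grp.frame.iloc[0])  # first visibility; t=0 is the frame before
        lookup = dict(zip(grp.frame.astype(int), grp.area_um2))
        for t in times:
            f = f0 - 1 + int(round(t / frame_interval_min))
            area = lookup.get(f)
            rows.append(dict(cell_id=cid, time_min=float(t),
                             area_um2=np.nan if area is None else float(area),
                             available=area is not None))
    return pd.DataFrame(rows, columns=["cell_id", "time_min", "area_um2", "available"])
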