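"""Time-lapse synthetic movies with a scheduled epithelial event taxonomy.

Movies emulate junctional-reporter time-lapse imaging of the distal embryo
surface at 12-minute frame intervals: solid pre-cluster domains and
apex-enclosing cluster domains sit on or below a gently curved surface and
realise a ground-truth :class:`Event` schedule —

* ``expansion``: a solid pre-cluster becomes a discontinuous (hole-
  enclosing) cluster at the scheduled frame;
* ``disassembly``: a pre-cluster disappears at the scheduled frame;
* ``coalescence``: two regions approach over the preceding frames and
  merge into a single region at the scheduled frame;
* ``emergence``: a subsurface region relocates to the surface at the
  scheduled frame (it switches from the subsurface to the surface side of
  the split).

Regions not referenced by any event persist unchanged, providing the
persistence baseline.  The per-frame state, position, depth, and aliveness
of every region are recorded in ``GroundTruth.region_tracks``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as draw_disk

from ._geometry import PlacementError
from .generator import EmbryoParams, GroundTruth, _height_map
from .stack import VoxelStack

__all__ = [
    "Event",
    "movie_params",
    "default_event_schedule",
    "generate_timelapse",
    "expected_outcome_counts",
]

EVENT_KINDS = ("emergence", "coalescence", "expansion", "disassembly")

PRE_RADIUS_UM = 3.0
CLUSTER_OUTER_UM = 4.5
CLUSTER_HOLE_UM = 1.2
MERGED_RADIUS_UM = 3.8
SUBSURFACE_DEPTH_UM = 20.0
SURFACE_DEPTH_UM = 1.0
APPROACH_FRAMES = 6
MERGE_GAP_UM = 1.5


@dataclass(frozen=True)
class Event:
    """One scheduled epithelial event."""

    kind: str
    frame: int
    region_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "coalescence" and len(self.region_ids) < 2:
            raise ValueError("coalescence needs >= 2 participating regions")

    def to_json_dict(self) -> dict:
        return {"kind": self.kind, "frame": self.frame,
                "region_ids": list(self.region_ids)}


def movie_params(seed: int = 0, **overrides) -> EmbryoParams:
    """Movie-sized study conditions: a flatter, shallower field at 12 min/frame."""
    kw = dict(
        stack_shape=(20, 256, 256),
        voxel_size_z=2.0,
        voxel_size_xy=0.5,
        surface_cap_radius=2000.0,
        surface_apex_offset_um=2.0,
        n_rosettes=0,
        n_emerged_clusters=0,
        rosette_depth_range=(0.0, 30.0),
        n_frames=36,
        seed=seed,
    )
    kw.update(overrides)
    return EmbryoParams(**kw)


def default_event_schedule(
    params: EmbryoParams,
    n_coalescence: int = 3,
    n_expansion: int = 2,
    n_disassembly: int = 1,
    n_emergence: int = 2,
    n_static_unemerged: int = 2,
    n_static_emerged: int = 1,
    rng=None,
):
    """A seed-determined schedule plus the region roster it references.

    Returns ``(events, roster)`` where ``roster`` maps region id to its
    role dict.  Event frames are drawn (RNG child 6 of the params seed)
    from the interior of the movie so every outcome is observable.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(8)[6])
    nf = params.n_frames
    lo = APPROACH_FRAMES + 2
    hi = nf - 4
    if hi <= lo:
        raise ValueError("movie too short for the default schedule")
    roster: dict[int, dict] = {}
    events: list[Event] = []
    rid = 0

    def new_region(role, emerged=False):
        nonlocal rid
        roster[rid] = {"role": role, "emerged0": emerged}
        rid += 1
        return rid - 1

    for _ in range(n_static_unemerged):
        new_region("static")
    for _ in range(n_static_emerged):
        new_region("static", emerged=True)
    for _ in range(n_expansion):
        r = new_region("expand")
        events.append(Event("expansion", int(rng.integers(lo, hi)), (r,)))
    for _ in range(n_disassembly):
        r = new_region("disassemble")
        events.append(Event("disassembly", int(rng.integers(lo, hi)), (r,)))
    for _ in range(n_emergence):
        r = new_region("emerge")
        events.append(Event("emergence", int(rng.integers(lo, hi)), (r,)))
    for _ in range(n_coalescence):
        a = new_region("coalesce")
        b = roster[a]["partner"] = new_region("coalesce")
        roster[b]["partner"] = a
        events.append(Event("coalescence", int(rng.integers(lo, hi)), (a, b)))
    return events, roster


def _validate_schedule(events, n_frames: int) -> None:
    for ev in events:
        if not 0 <= ev.frame < n_frames:
            raise ValueError(f"event {ev} references frame >= n_frames ({n_frames})")
        if ev.kind == "disassembly" and ev.frame >= n_frames:
            raise ValueError("disassembly after the final frame is unobservable")


def generate_timelapse(
    params: EmbryoParams,
    schedule=None,
    roster=None,
    n_static_regions: int = 3,
):
    """Render a movie realising an event schedule, with full ground truth.

    With ``schedule=None`` a default seed-determined schedule is used.  An
    explicit empty schedule yields a static movie: every region present in
    frame 0 persists unchanged to the last frame.  Returns
    ``(frames, truth)`` where ``frames`` is a list of single-channel
    junctional stacks (``frame_interval_min`` set from the params).
    """
    if params.n_frames < 2:
        raise ValueError("a movie needs n_frames >= 2")
    if schedule is None and roster is None:
        schedule, roster = default_event_schedule(params)
    elif roster is None:
        roster = {i: {"role": "static", "emerged0": False} for i in range(n_static_regions)}
        nxt = n_static_regions
        for ev in schedule:
            for r in ev.region_ids:
                if r not in roster:
                    roster[r] = {"role": "event", "emerged0": False}
        for ev in schedule:
            if ev.kind == "coalescence":
                a, b = ev.region_ids[0], ev.region_ids[1]
                roster[a]["partner"] = b
                roster[b]["partner"] = a
    _validate_schedule(schedule, params.n_frames)

    nz, ny, nx = params.stack_shape
    vz, vxy = params.voxel_size_z, params.voxel_size_xy
    _, ey, ex = params.extent_um
    h = _height_map(params)
    z_um = np.arange(nz)[:, None, None] * vz
    interior = z_um >= h[None]
    max_depth = (nz - 1) * vz - h.max()
    if SUBSURFACE_DEPTH_UM + 4 > max_depth:
        raise ValueError("stack too shallow for subsurface regions")

    # assign one lattice slot per region (coalescence partners share one)
    slot_pitch = 24.0
    margin = 14.0
    ys = np.arange(margin, ey - margin + 1e-6, slot_pitch)
    xs = np.arange(margin, ex - margin + 1e-6, slot_pitch)
    slots = [(y, x) for y in ys for x in xs]
    primaries = []
    seen = set()
    for r, info in roster.items():
        p = info.get("partner")
        if p is not None and p in seen:
            continue
        primaries.append(r)
        seen.add(r)
    if len(primaries) > len(slots):
        raise PlacementError(
            f"{len(primaries)} region slots requested but only {len(slots)} fit"
        )
    slot_of = {r: slots[i] for i, r in enumerate(primaries)}

    nf = params.n_frames
    ev_by_region: dict[int, Event] = {}
    for ev in schedule:
        for r in ev.region_ids:
            ev_by_region[r] = ev

    # per-region per-frame truth
    tracks: dict[int, dict] = {}
    for r, info in roster.items():
        ev = ev_by_region.get(r)
        emerged0 = bool(info.get("emerged0", False))
        alive = np.ones(nf, dtype=bool)
        emerged = np.full(nf, emerged0)
        state = np.full(nf, "pre_cluster", dtype=object)
        shape = np.full(nf, "disk", dtype=object)
        if r in slot_of:
            cy0, cx0 = slot_of[r]
        else:
            cy0, cx0 = slot_of[roster[r]["partner"]]
        pos = np.tile([cy0, cx0], (nf, 1)).astype(float)
        if ev is not None:
            f = ev.frame
            if ev.kind == "expansion":
                state[f:] = "cluster"
                shape[f:] = "annulus"
            elif ev.kind == "disassembly":
                alive[f:] = False
            elif ev.kind == "emergence":
                emerged[f:] = True
            elif ev.kind == "coalescence":
                sign = +1.0 if ev.region_ids.index(r) == 0 else -1.0
                d_far = 2 * PRE_RADIUS_UM + MERGE_GAP_UM + (APPROACH_FRAMES - 1)
                d_merge = 2 * PRE_RADIUS_UM + MERGE_GAP_UM
                for t in range(f):
                    d = d_merge + max(f - 1 - t, 0) if t > f - APPROACH_FRAMES else d_far
                    pos[t, 1] = cx0 + sign * min(d, d_far) / 2.0
                # from the merge frame the merged pseudo-region takes over
                alive[f:] = False
        tracks[r] = dict(alive=alive, emerged=emerged, state=state, shape=shape,
                         pos=pos, role=info.get("role"))
    # merged products
    merged_id = max(roster) + 1 if roster else 0
    for ev in schedule:
        if ev.kind != "coalescence":
            continue
        cy0, cx0 = slot_of[ev.region_ids[0]] if ev.region_ids[0] in slot_of else slot_of[
            roster[ev.region_ids[0]]["partner"]]
        alive = np.zeros(nf, dtype=bool)
        alive[ev.frame:] = True
        d_merge = 2 * PRE_RADIUS_UM + MERGE_GAP_UM
        tracks[merged_id] = dict(
            alive=alive,
            emerged=np.full(nf, False),
            state=np.full(nf, "pre_cluster", dtype=object),
            shape=np.full(nf, "dumbbell", dtype=object),
            pos=np.tile([cy0, cx0], (nf, 1)).astype(float),
            role="merged",
            parents=tuple(ev.region_ids),
            half_sep_um=d_merge / 2.0,
        )
        merged_id += 1

    # --- render ----------------------------------------------------------
    rng_noise = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(8)[7])
    bg = params.background_level
    frames: list[VoxelStack] = []
    for t in range(nf):
        img2d = {}  # depth -> 2D paint buffer
        for r, tr in tracks.items():
            if not tr["alive"][t]:
                continue
            depth = SURFACE_DEPTH_UM if tr["emerged"][t] else SUBSURFACE_DEPTH_UM
            buf = img2d.setdefault(depth, np.zeros((ny, nx), dtype=np.float32))
            cy, cx = tr["pos"][t]
            iy, ix = cy / vxy, cx / vxy
            if tr["shape"][t] == "disk":
                rr, cc = draw_disk((iy, ix), PRE_RADIUS_UM / vxy, shape=(ny, nx))
                buf[rr, cc] = 1.0
            elif tr["shape"][t] == "annulus":
                rr, cc = draw_disk((iy, ix), CLUSTER_OUTER_UM / vxy, shape=(ny, nx))
                buf[rr, cc] = 1.0
                rr, cc = draw_disk((iy, ix), CLUSTER_HOLE_UM / vxy, shape=(ny, nx))
                buf[rr, cc] = 0.0
            else:  # dumbbell
                half = tr["half_sep_um"]
                for sgn in (-1.0, +1.0):
                    rr, cc = draw_disk((iy, ix + sgn * half / vxy),
                                       MERGED_RADIUS_UM / vxy, shape=(ny, nx))
                    buf[rr, cc] = 1.0
        vol = np.zeros((nz, ny, nx), dtype=np.float32)
        for depth, buf in img2d.items():
            by, bx = np.nonzero(buf)
            kz = np.clip(np.ceil((h[by, bx] + depth) / vz - 1e-9).astype(int), 0, nz - 1)
            vol[kz, by, bx] = buf[by, bx] * params.signal_level
        vol *= interior
        vol += bg
        if params.noise_sd > 0:
            noise = rng_noise.standard_normal(vol.shape, dtype=np.float32)
            vol += noise * params.noise_sd * np.sqrt(vol / bg)
        np.clip(vol, 0.0, 1.0, out=vol)
        frames.append(VoxelStack(vol[None], vz, vxy, ("junctional",),
                                 frame_interval_min=params.frame_interval_min))

    truth = GroundTruth(
        params=params,
        surface_height_map=h,
        interior_mask=interior,
        shell_mask=np.zeros_like(interior),
        emerged_label_mask=np.zeros((ny, nx), dtype=np.uint8),
        emerged_cluster_labels=np.zeros((ny, nx), dtype=np.int32),
        emerged_cluster_areas_um2={},
        event_schedule=list(schedule),
        region_tracks=tracks,
    )
    return frames, truth


def expected_outcome_counts(schedule, roster) -> dict[str, int]:
    """Planted pre-cluster outcome counts implied by a schedule.

    Every rostered region starts as a solid pre-cluster; expansion and
    disassembly events claim their regions, and everything else (statics,
    coalescence partners, emergence regions) persists.
    """
    n_exp = sum(1 for e in schedule if e.kind == "expansion")
    n_dis = sum(1 for e in schedule if e.kind == "disassembly")
    return {
        "expansion": n_exp,
        "disassembly": n_dis,
        "persistence": len(roster) - n_exp - n_dis,
    }
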