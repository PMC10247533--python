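"""Synthetic embryo stacks with complete ground truth.

The generator emulates the distal cap of a gastrulating mouse embryo as
seen in a confocal z-stack mounted distal side down: a distally convex
squamous endoderm shell with polygonal cell outlines, discrete emerged
axial-mesoderm clusters with small apical domains, subsurface multicellular
rosettes (basal, endoderm-contacting, or partially emerged; early or late
junctional stage; optionally enclosing a spherical or tunnel-like lumen),
1-2 um cytoplasmic granules, and — in movies — scheduled emergence and
coalescence events.  Every structure is recorded in a
:class:`GroundTruth` twin so downstream measurements can be validated.

Geometry.  Axis order is ``(channel, z, y, x)``; z index 0 is the
distal-most slice.  The embryo surface is a spherical-cap height map
``h(y, x)`` (um); the embryo interior is ``z_um >= h``.  x is the
mediolateral axis, y the anterior-posterior axis (tunnel lumens elongate
along y).  Intensities are fractional; noise is additive Gaussian with a
per-voxel Poisson-like scaling ``sd = noise_sd * sqrt(I / background)``.

RNG draw order (seed-replay contract).  All randomness derives from
``numpy.random.SeedSequence(seed).spawn(8)``; the children are used, in
order, for:

0. endoderm surface tessellation points;
1. emerged-cluster placement, radii, and apex tessellation points;
2. rosette location classes, stages, lateral placement, and basal depths
   (interleaved, in rosette index order);
3. lumens — first exactly ``n_rosettes`` uniform draws in rosette index
   order, compared against ``lumen_probability`` (the Bernoulli lumen
   calls), then, for each lumen-positive rosette in index order: radius
   (uniform in ``lumen_radius_range``), one uniform tunnel draw compared
   against ``tunnel_fraction``, and, for tunnels, a length factor;
4. granule counts and positions;
5. static-stack noise (per channel, in channel order);
6. movie event scheduling;
7. movie noise (per frame, then per channel).

A rosette that receives a lumen is rendered at late stage (an expanded
apical domain implies a maturing rosette); the Bernoulli draw sequence
above is unaffected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np
import tifffile
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.measure import find_contours
from shapely.geometry import Polygon

from ._geometry import PlacementError, hex_points, paint_ball, paint_cylinder_y, place_separated
from .patches import render_stage_pattern
from .stack import ContourSet, VoxelStack

__all__ = [
    "EmbryoParams",
    "GroundTruth",
    "RosetteTruth",
    "PlacementError",
    "generate_static_stack",
    "generate_contours",
]

CHANNELS = ("membrane", "junctional", "nuclear", "apical", "granule")
LOCATION_CLASSES = ("basal", "endoderm_contacting", "partially_emerged")


@dataclass(frozen=True)
class EmbryoParams:
    """Study conditions for one synthetic embryo stack or movie.

    Defaults follow the imaging conditions the analysis is designed for:
    128 um deep stacks (20x acquisition: 2 um z-steps, here 0.5 um pixels),
    ~8 rosettes per embryo built from >=5 cells, 1-2 um granules at about
    one per cell, and 12-minute movie frames.  The axial-mesoderm cell
    diameter (10 um) is a free simulation parameter, not a measured value;
    the emerged apical-domain diameter (5 um, ~20 um^2 apices) is kept
    separate from it because emerged apices are constricted relative to
    the cell body.
    """

    stack_shape: tuple[int, int, int] = (64, 560, 384)  # (z, y, x) voxels
    voxel_size_z: float = 2.0  # um
    voxel_size_xy: float = 0.5  # um
    surface_cap_radius: float = 400.0  # um, curvature of the distal surface
    surface_apex_offset_um: float = 4.0  # free space above the distal tip
    shell_thickness: float = 5.0  # um, squamous endoderm
    endoderm_cell_diameter: float = 20.0  # um
    mesoderm_cell_diameter: float = 10.0  # um, basal-distance rule unit
    mesoderm_apex_diameter: float = 5.0  # um, emerged apical domains
    n_emerged_clusters: int = 5
    emerged_cluster_radius_range: tuple[float, float] = (12.0, 20.0)  # um
    n_rosettes: int = 8
    rosette_depth_range: tuple[float, float] = (0.0, 45.0)  # um below surface
    n_cells_per_rosette: int = 6
    rosette_location_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    rosette_stage_probs: tuple[float, float] = (0.6, 0.4)  # early, late
    lumen_probability: float = 0.3
    lumen_radius_range: tuple[float, float] = (2.5, 4.5)  # um
    tunnel_fraction: float = 0.3
    granule_diameter_range: tuple[float, float] = (1.0, 2.0)  # um
    granules_per_cell: float = 1.0
    signal_level: float = 0.8
    noise_sd: float = 0.02
    background_level: float = 0.1
    frame_interval_min: float = 12.0
    n_frames: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        pos = (
            "voxel_size_z voxel_size_xy surface_cap_radius shell_thickness "
            "endoderm_cell_diameter mesoderm_cell_diameter mesoderm_apex_diameter "
            "frame_interval_min".split()
        )
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("lumen_probability", "tunnel_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells_per_rosette < 5:
            raise ValueError("n_cells_per_rosette must be >= 5 (rosette definition)")
        lo, hi = self.rosette_depth_range
        if not 0.0 <= lo <= hi:
            raise ValueError("rosette_depth_range must be ordered and nonnegative")
        if hi > self.stack_shape[0] * self.voxel_size_z:
            raise ValueError("rosette_depth_range exceeds stack depth")
        if abs(sum(self.rosette_location_probs) - 1.0) > 1e-6:
            raise ValueError("rosette_location_probs must sum to 1")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        nz, ny, nx = self.stack_shape
        return nz * self.voxel_size_z, ny * self.voxel_size_xy, nx * self.voxel_size_xy

    def with_(self, **kw) -> "EmbryoParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, doc: dict) -> "EmbryoParams":
        kw = dict(doc)
        for name in kw:
            val = kw[name]
            if isinstance(val, list):
                kw[name] = tuple(val)
        return cls(**kw)


@dataclass
class RosetteTruth:
    """Ground truth for one planted rosette."""

    rosette_id: int
    center_um: tuple[float, float, float]  # (z, y, x)
    depth_um: float  # below local surface
    location_class: str
    stage: str
    has_lumen: bool
    lumen: dict | None  # kind, radius_um, length_um, volume_um3
    cell_label_ids: tuple[int, ...]
    n_cells: int
    pattern_area_um2: float  # projected junctional-pattern area

    def to_json_dict(self) -> dict:
        return {
            "rosette_id": self.rosette_id,
            "center_um": list(self.center_um),
            "depth_um": self.depth_um,
            "location_class": self.location_class,
            "stage": self.stage,
            "has_lumen": self.has_lumen,
            "lumen": self.lumen,
            "cell_label_ids": list(self.cell_label_ids),
            "n_cells": self.n_cells,
            "pattern_area_um2": self.pattern_area_um2,
        }


@dataclass
class GroundTruth:
    """Complete ground truth for one generated stack or movie."""

    params: EmbryoParams
    surface_height_map: np.ndarray  # (y, x) um
    interior_mask: np.ndarray  # bool (z, y, x)
    shell_mask: np.ndarray  # bool, endoderm shell voxels
    emerged_label_mask: np.ndarray  # (y, x): 0 background, 1 endoderm, 2 emerged mesoderm
    emerged_cluster_labels: np.ndarray  # (y, x) int, 0 = none
    emerged_cluster_areas_um2: dict[int, float]
    rosettes: list[RosetteTruth] = field(default_factory=list)
    granule_centers_um: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    granule_diameters_um: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cell_label_volume: np.ndarray | None = None
    shell_junction_mask: np.ndarray | None = None  # junctional voxels of the shell lattice
    basal_junction_mask: np.ndarray | None = None  # junctional voxels of basal rosettes
    event_schedule: list = field(default_factory=list)
    region_tracks: dict | None = None  # movies: per-region per-frame truth

    # -- derived quantities ---------------------------------------------
    def emerged_area_um2(self) -> float:
        return float(sum(self.emerged_cluster_areas_um2.values()))

    def unemerged_area_um2(self) -> float:
        return float(sum(r.pattern_area_um2 for r in self.rosettes
                         if r.location_class == "basal"))

    def emerged_fraction(self) -> float:
        e, u = self.emerged_area_um2(), self.unemerged_area_um2()
        return e / (e + u) if e + u > 0 else float("nan")

    # -- I/O -------------------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "emerged_cluster_areas_um2": {str(k): v for k, v in self.emerged_cluster_areas_um2.items()},
            "rosettes": [r.to_json_dict() for r in self.rosettes],
            "granule_centers_um": self.granule_centers_um.tolist(),
            "granule_diameters_um": self.granule_diameters_um.tolist(),
            "event_schedule": [e.to_json_dict() if hasattr(e, "to_json_dict") else e
                               for e in self.event_schedule],
        }

    def save(self, json_path, labels_tiff_path=None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)
        if labels_tiff_path is not None and self.cell_label_volume is not None:
            tifffile.imwrite(labels_tiff_path, self.cell_label_volume.astype(np.int32))


# ---------------------------------------------------------------------------
# static stack generation
# ---------------------------------------------------------------------------


def _height_map(params: EmbryoParams) -> np.ndarray:
    _, ey, ex = params.extent_um
    vxy = params.voxel_size_xy
    ny, nx = params.stack_shape[1:]
    yy = (np.arange(ny) * vxy - ey / 2.0)[:, None]
    xx = (np.arange(nx) * vxy - ex / 2.0)[None, :]
    r2 = yy**2 + xx**2
    R = params.surface_cap_radius
    if r2.max() >= R**2:
        raise ValueError("surface_cap_radius too small for the lateral field")
    return params.surface_apex_offset_um + R - np.sqrt(R**2 - r2)


def _surface_index(h: np.ndarray, params: EmbryoParams) -> np.ndarray:
    """First z index at or below the surface for each column."""
    k = np.ceil(h / params.voxel_size_z - 1e-9).astype(int)
    return np.clip(k, 0, params.stack_shape[0] - 1)


def _boundary_2d(labels: np.ndarray) -> np.ndarray:
    b = np.zeros(labels.shape, dtype=bool)
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    return b


def _choice(rng, probs) -> int:
    u = rng.random()
    c = np.cumsum(probs)
    return int(np.searchsorted(c, u, side="right").clip(0, len(probs) - 1))


def generate_static_stack(params: EmbryoParams):
    """Render one calibrated multi-channel embryo stack plus ground truth.

    Returns ``(stack, truth)``.  Deterministic given ``params.seed``
    (bit-identical across calls).  Raises :class:`PlacementError` when the
    requested structure counts cannot be placed with the required
    separations.
    """
    nz, ny, nx = params.stack_shape
    vz, vxy = params.voxel_size_z, params.voxel_size_xy
    _, ey, ex = params.extent_um
    children = np.random.SeedSequence(params.seed).spawn(8)
    rng_tess = np.random.default_rng(children[0])
    rng_clus = np.random.default_rng(children[1])
    rng_ros = np.random.default_rng(children[2])
    rng_lum = np.random.default_rng(children[3])
    rng_gran = np.random.default_rng(children[4])
    rng_noise = np.random.default_rng(children[5])

    h = _height_map(params)
    k_surf = _surface_index(h, params)
    z_um = np.arange(nz)[:, None, None] * vz
    interior = z_um >= h[None]
    shell = interior & (z_um < (h + params.shell_thickness)[None])

    # --- surface tessellation (child 0) --------------------------------
    endo_pts = hex_points(-5.0, ey + 5.0, -5.0, ex + 5.0,
                          params.endoderm_cell_diameter, rng_tess)

    # --- emerged clusters (child 1) -------------------------------------
    margin = 40.0
    r_lo, r_hi = params.emerged_cluster_radius_range
    radii = rng_clus.uniform(r_lo, r_hi, params.n_emerged_clusters)
    cluster_centers = place_separated(
        params.n_emerged_clusters,
        (margin, ey - margin, margin, ex - margin),
        lambda i, j: radii[i] + radii[j] + 24.0,
        rng_clus,
    ) if params.n_emerged_clusters else np.zeros((0, 2))
    # a cluster converts whole endoderm cells into fields of small mesoderm
    # apices: endoderm centers within the cluster radius are selected, and
    # mesoderm apex points subdivide exactly the selected Voronoi cells (so
    # the emerged footprint is bounded by pre-existing cell boundaries and
    # every emerged apex stays small)
    selected = np.zeros(len(endo_pts), dtype=bool)
    sel_cluster = np.full(len(endo_pts), -1)
    for ci, (cyc, cxc) in enumerate(cluster_centers):
        d = np.hypot(endo_pts[:, 0] - cyc, endo_pts[:, 1] - cxc)
        inside = d <= radii[ci]
        if not inside.any():
            inside[np.argmin(d)] = True  # always convert at least one cell
        sel_cluster[inside & ~selected] = ci
        selected |= inside
    meso_pts = []
    meso_cluster_of = []
    if selected.any():
        endo_tree = cKDTree(endo_pts)
        pad = params.endoderm_cell_diameter
        for ci, (cyc, cxc) in enumerate(cluster_centers):
            r = radii[ci] + pad
            cand = hex_points(cyc - r, cyc + r, cxc - r, cxc + r,
                              params.mesoderm_apex_diameter, rng_clus, jitter_frac=0.15)
            owner = endo_tree.query(cand)[1]
            keep = selected[owner] & (sel_cluster[owner] == ci)
            cand = cand[keep]
            meso_pts.append(cand)
            meso_cluster_of.extend([ci] * len(cand))
        endo_pts = endo_pts[~selected]
    meso_pts = np.concatenate(meso_pts) if meso_pts else np.zeros((0, 2))
    centers = np.concatenate([endo_pts, meso_pts]) if len(meso_pts) else endo_pts
    is_meso = np.zeros(len(centers), dtype=bool)
    is_meso[len(endo_pts):] = True
    cluster_of = np.full(len(centers), -1)
    cluster_of[len(endo_pts):] = meso_cluster_of

    yy_um = np.arange(ny) * vxy
    xx_um = np.arange(nx) * vxy
    grid = np.stack(np.meshgrid(yy_um, xx_um, indexing="ij"), axis=-1).reshape(-1, 2)
    # mesoderm assignment is capped at one apex diameter so edge apices stay
    # small instead of bulging halfway toward the (sparser) endoderm centers
    d_endo, i_endo = cKDTree(endo_pts).query(grid)
    if len(meso_pts):
        d_meso, i_meso = cKDTree(meso_pts).query(grid)
        cap = 0.8 * params.mesoderm_apex_diameter
        use_meso = d_meso <= np.minimum(d_endo, cap)
        label2d = np.where(use_meso, len(endo_pts) + i_meso, i_endo).reshape(ny, nx)
    else:
        label2d = i_endo.reshape(ny, nx)
    meso2d = is_meso[label2d]
    cluster2d = np.where(meso2d, cluster_of[label2d], -1)

    # --- rosette planning (child 2, then child 3 for lumens) ------------
    n_ros = params.n_rosettes
    ros_class = []
    ros_stage = []
    ros_depth_u = []
    for _ in range(n_ros):
        ros_class.append(LOCATION_CLASSES[_choice(rng_ros, params.rosette_location_probs)])
        ros_stage.append(("early_rosette", "late_rosette")[_choice(rng_ros, params.rosette_stage_probs)])
        ros_depth_u.append(rng_ros.random())
    existing = [tuple(c) for c in cluster_centers]

    def _sep(i, j):
        if j < len(cluster_centers):
            return radii[j] + 16.0
        return 26.0

    ros_pos = place_separated(
        n_ros, (margin, ey - margin, margin, ex - margin), _sep, rng_ros,
        existing=existing,
    ) if n_ros else np.zeros((0, 2))

    # lumen draws (child 3): Bernoulli pass first, then geometry pass
    lumen_flags = [bool(rng_lum.random() < params.lumen_probability) for _ in range(n_ros)]
    lumens: list[dict | None] = []
    l_lo, l_hi = params.lumen_radius_range
    for i in range(n_ros):
        if not lumen_flags[i]:
            lumens.append(None)
            continue
        r = float(rng_lum.uniform(l_lo, l_hi))
        is_tube = bool(rng_lum.random() < params.tunnel_fraction)
        if is_tube:
            length = float(r * rng_lum.uniform(4.5, 6.0))
            vol = float(np.pi * r**2 * length)
            lumens.append({"kind": "tube", "radius_um": r, "length_um": length,
                           "volume_um3": vol})
        else:
            lumens.append({"kind": "sphere", "radius_um": r, "length_um": None,
                           "volume_um3": float(4.0 / 3.0 * np.pi * r**3)})

    # --- geometry of each rosette ---------------------------------------
    depth_lo, depth_hi = params.rosette_depth_range
    basal_lo = max(depth_lo, 25.0)
    basal_hi = max(basal_lo, min(depth_hi, 45.0) - 10.0)
    apical_focus_r = 2.0
    shell_um = max(1.5, vz)  # apical wall; >= one z step so it cannot vanish between slices
    rosettes: list[RosetteTruth] = []
    gap2d = np.zeros((ny, nx), dtype=bool)
    plan = []
    for i in range(n_ros):
        lum = lumens[i]
        stage = "late_rosette" if lum is not None else ros_stage[i]
        r_ap = (lum["radius_um"] + shell_um) if lum else apical_focus_r + shell_um
        cls = ros_class[i]
        if cls == "basal":
            depth = basal_lo + ros_depth_u[i] * (basal_hi - basal_lo)
        elif cls == "endoderm_contacting":
            depth = params.shell_thickness + r_ap - 1.0
        elif lum is not None:
            # partially emerged with a lumen: the cavity sits fully below the
            # surface and the apical domain reaches it through a solid neck,
            # so the central domain is open to the surface while the lumen
            # itself stays enclosed
            # margin covers the height-map variation across the structure's
            # footprint so the top wall is never clipped by the surface
            depth = lum["radius_um"] + shell_um + 3.0
        else:
            depth = max(r_ap - 2.0, 1.0)
        cy, cx = ros_pos[i]
        iy = int(np.clip(round(cy / vxy), 0, ny - 1))
        ix = int(np.clip(round(cx / vxy), 0, nx - 1))
        cz = h[iy, ix] + depth
        if cls == "partially_emerged":
            # the emergence mouth: surface endoderm is cleared well past the
            # cup so the rosette pattern is unobstructed by the lattice
            rr, cc = draw_disk((iy, ix), (r_ap + 6.0) / vxy, shape=(ny, nx))
            gap2d[rr, cc] = True
        plan.append((i, cls, stage, lum, r_ap, depth, (cz, cy, cx)))

    # --- paint surface structures ---------------------------------------
    sig = {name: np.zeros((nz, ny, nx), dtype=np.float32) for name in CHANNELS}
    boundary = _boundary_2d(label2d) & ~gap2d
    by, bx = np.nonzero(boundary)
    sig["junctional"][k_surf[by, bx], by, bx] = 1.0
    shell_junction = np.zeros((nz, ny, nx), dtype=bool)
    shell_junction[k_surf[by, bx], by, bx] = True
    n_layers = int(np.ceil(params.shell_thickness / vz)) + 1
    for j in range(n_layers):
        kj = np.clip(k_surf[by, bx] + j, 0, nz - 1)
        ok = kj * vz < h[by, bx] + params.shell_thickness
        sig["membrane"][kj[ok], by[ok], bx[ok]] = 1.0
    nuc2d = np.zeros((ny, nx), dtype=bool)
    for (cy, cx), meso in zip(centers, is_meso):
        iy, ix = round(cy / vxy), round(cx / vxy)
        if not (0 <= iy < ny and 0 <= ix < nx) or gap2d[iy % ny, ix % nx]:
            continue
        d = params.mesoderm_apex_diameter if meso else params.endoderm_cell_diameter
        rr, cc = draw_disk((iy, ix), max(min(0.25 * d, 3.0) / vxy, 1.0), shape=(ny, nx))
        nuc2d[rr, cc] = True
    ky, kx = np.nonzero(nuc2d)
    sig["nuclear"][np.clip(k_surf[ky, kx] + 1, 0, nz - 1), ky, kx] = 1.0

    emerged_label = np.ones((ny, nx), dtype=np.uint8)
    emerged_label[meso2d] = 2
    emerged_label[gap2d] = 0
    cluster_labels = np.where((cluster2d >= 0) & ~gap2d, cluster2d + 1, 0).astype(np.int32)
    px_area = vxy * vxy
    cluster_areas = {
        int(cid): float((cluster_labels == cid).sum() * px_area)
        for cid in range(1, params.n_emerged_clusters + 1)
    }

    cell_labels = np.where(shell & ~gap2d[None], label2d[None] + 1, 0).astype(np.int32)
    next_label = len(centers) + 1

    # --- paint rosettes --------------------------------------------------
    basal_junction = np.zeros((nz, ny, nx), dtype=bool)
    granule_centers = []
    granule_diams = []
    for i, cls, stage, lum, r_ap, depth, (cz, cy, cx) in plan:
        center = (cz, cy, cx)
        # apical domain
        if lum is None:
            paint_ball(sig["apical"], center, r_ap, vz, vxy, 1.0)
        elif lum["kind"] == "sphere":
            paint_ball(sig["apical"], center, lum["radius_um"] + shell_um, vz, vxy,
                       1.0, inner_radius_um=lum["radius_um"])
        else:
            paint_cylinder_y(sig["apical"], center, lum["radius_um"], lum["length_um"],
                             vz, vxy, 1.0, shell_um=shell_um)
        if cls == "partially_emerged" and lum is not None:
            # apical neck from the lumen wall up to the embryo surface
            rr, cc = draw_disk((round(cy / vxy), round(cx / vxy)), 1.5 / vxy,
                               shape=(ny, nx))
            k_hi = int(np.floor((cz - lum["radius_um"] - 0.5 * vz) / vz))
            k_lo = k_surf[rr, cc]
            for k in range(int(k_lo.min()), max(k_hi, int(k_lo.min())) + 1):
                sel = k >= k_lo
                sig["apical"][k, rr[sel], cc[sel]] = 1.0
        # junctional stage pattern in the equatorial plane
        ring_r = (lum["radius_um"] + shell_um / 2.0) if lum else None
        patch_um = 2 * (r_ap + 10.0)
        img, _meta = render_stage_pattern(
            stage, params.n_cells_per_rosette, vxy, patch_um, rng_ros,
            ring_radius_um=ring_r,
        )
        kc = int(np.clip(round(cz / vz), 0, nz - 1))
        iy = int(round(cy / vxy)) - img.shape[0] // 2
        ix = int(round(cx / vxy)) - img.shape[1] // 2
        ys = slice(max(iy, 0), min(iy + img.shape[0], ny))
        xs = slice(max(ix, 0), min(ix + img.shape[1], nx))
        sub = img[ys.start - iy: ys.stop - iy, xs.start - ix: xs.stop - ix]
        target = sig["junctional"][kc, ys, xs]
        np.maximum(target, sub, out=target)
        if cls == "basal":
            basal_junction[kc, ys, xs] |= sub > 0
        pattern_area = float((img > 0).sum() * px_area)
        # radially elongated cell bodies: sector labels around the apical domain
        ids = _paint_rosette_cells(
            cell_labels, sig["membrane"], center, r_ap, params, next_label, h
        )
        next_label += len(ids)
        # granules in the apical cytoplasm (child 4)
        n_g = int(rng_gran.poisson(params.granules_per_cell * params.n_cells_per_rosette))
        g_lo, g_hi = params.granule_diameter_range
        for _ in range(n_g):
            vec = rng_gran.standard_normal(3)
            vec /= np.linalg.norm(vec) + 1e-12
            dist = rng_gran.uniform(r_ap + 1.0, r_ap + 3.0)
            gz, gy, gx = np.array(center) + vec * dist
            diam = rng_gran.uniform(g_lo, g_hi)
            iyg, ixg = int(gy / vxy), int(gx / vxy)
            if not (0 <= iyg < ny and 0 <= ixg < nx):
                continue
            if gz < h[iyg, ixg] + 0.5 or gz > (nz - 1) * vz:
                continue
            paint_ball(sig["granule"], (gz, gy, gx), diam / 2.0, vz, vxy, 1.0)
            granule_centers.append((gz, gy, gx))
            granule_diams.append(diam)
        rosettes.append(RosetteTruth(
            rosette_id=i,
            center_um=(float(cz), float(cy), float(cx)),
            depth_um=float(depth),
            location_class=cls,
            stage=stage,
            has_lumen=lum is not None,
            lumen=lum,
            cell_label_ids=ids,
            n_cells=params.n_cells_per_rosette,
            pattern_area_um2=pattern_area,
        ))

    # --- compose intensities ---------------------------------------------
    data = np.empty((len(CHANNELS), nz, ny, nx), dtype=np.float32)
    bg = params.background_level
    for c, name in enumerate(CHANNELS):
        clean = sig[name] * params.signal_level
        clean *= interior
        clean += bg
        if params.noise_sd > 0:
            noise = rng_noise.standard_normal(clean.shape, dtype=np.float32)
            noise *= params.noise_sd * np.sqrt(clean / bg)
            clean += noise
        np.clip(clean, 0.0, 1.0, out=clean)
        data[c] = clean
    stack = VoxelStack(data, vz, vxy, CHANNELS,
                       frame_interval_min=None)
    truth = GroundTruth(
        params=params,
        surface_height_map=h,
        interior_mask=interior,
        shell_mask=shell,
        emerged_label_mask=emerged_label,
        emerged_cluster_labels=cluster_labels,
        emerged_cluster_areas_um2=cluster_areas,
        rosettes=rosettes,
        granule_centers_um=np.asarray(granule_centers).reshape(-1, 3),
        granule_diameters_um=np.asarray(granule_diams),
        cell_label_volume=cell_labels,
        shell_junction_mask=shell_junction,
        basal_junction_mask=basal_junction,
    )
    return stack, truth


def _paint_rosette_cells(cell_labels, membrane, center_um, r_ap, params: EmbryoParams,
                         base_label: int, height_map) -> tuple[int, ...]:
    """Angular sector labels for the radially elongated rosette cells."""
    nz, ny, nx = cell_labels.shape
    vz, vxy = params.voxel_size_z, params.voxel_size_xy
    cz, cy, cx = center_um
    r_out = r_ap + 0.8 * params.mesoderm_cell_diameter
    half_z = min(5.0, r_out)
    z0 = max(int(np.floor((cz - half_z) / vz)), 0)
    z1 = min(int(np.ceil((cz + half_z) / vz)) + 1, nz)
    y0 = max(int(np.floor((cy - r_out) / vxy)), 0)
    y1 = min(int(np.ceil((cy + r_out) / vxy)) + 1, ny)
    x0 = max(int(np.floor((cx - r_out) / vxy)), 0)
    x1 = min(int(np.ceil((cx + r_out) / vxy)) + 1, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return ()
    dz = (np.arange(z0, z1) * vz - cz)[:, None, None]
    dy = (np.arange(y0, y1) * vxy - cy)[None, :, None]
    dx = (np.arange(x0, x1) * vxy - cx)[None, None, :]
    r = np.sqrt(dz**2 + dy**2 + dx**2)
    body = (r > r_ap) & (r <= r_out) & (np.abs(dz) <= half_z)
    # clip to the embryo interior (partially emerged rosettes sit at the surface)
    z_abs = (np.arange(z0, z1) * vz)[:, None, None]
    body &= z_abs >= height_map[y0:y1, x0:x1][None]
    n = params.n_cells_per_rosette
    ang = np.arctan2(np.broadcast_to(dy, body.shape), np.broadcast_to(dx, body.shape))
    sector = ((ang + np.pi) / (2 * np.pi) * n).astype(int) % n
    region = cell_labels[z0:z1, y0:y1, x0:x1]
    region[body] = base_label + sector[body]
    # membrane walls between sectors (thin azimuthal planes)
    wall = body & (np.abs((ang + np.pi) % (2 * np.pi / n)) * r < 0.6)
    membrane[z0:z1, y0:y1, x0:x1][wall] = 1.0
    return tuple(range(base_label, base_label + n))


# ---------------------------------------------------------------------------
# contour annotation surrogate
# ---------------------------------------------------------------------------


def _slice_contours(mask2d: np.ndarray, jitter_um: float, vxy: float, rng) -> list[np.ndarray]:
    padded = np.pad(mask2d, 1).astype(np.float32)
    polys = []
    for c in find_contours(padded, 0.5):
        xy = c[:, ::-1] - 1.0  # (x, y) pixel coords, unpadded
        if jitter_um > 0:
            step = max(int(round(2.0 / vxy / 0.7)), 1)  # ~2 um vertex spacing
            sub = xy[::step]
            if len(sub) < 4:
                sub = xy
            j = jitter_um / vxy
            for attempt in range(6):
                cand = sub + rng.normal(0.0, j * 0.5**attempt, sub.shape)
                if len(cand) >= 3 and Polygon(cand).is_valid:
                    xy = cand
                    break
            else:
                pass  # fall back to the exact contour
        if len(xy) >= 3:
            polys.append(xy)
    return polys


def generate_contours(
    truth: GroundTruth,
    stride_near: int = 3,
    stride_deep: int = 10,
    jitter_um: float = 0.0,
    seed: int = 0,
) -> ContourSet:
    """Sparse per-slice outline polygons of the true embryo exterior.

    Annotations are placed every ``stride_near`` slices through the curved
    surface region (up to one shell thickness past the deepest point of the
    height map), every ``stride_deep`` slices beyond it, always including
    slice 0 and the last slice.  ``jitter_um`` adds Gaussian vertex noise
    emulating hand-drawn outlines (vertices resampled to ~2 um spacing
    first; jitter is reduced if it would self-intersect).
    """
    if stride_near < 1 or stride_deep < 1:
        raise ValueError("strides must be >= 1")
    params = truth.params
    nz = params.stack_shape[0]
    vz = params.voxel_size_z
    k_near = int(np.ceil((truth.surface_height_map.max() + params.shell_thickness) / vz))
    ks = {k for k in range(0, nz, stride_near) if k <= k_near}
    ks |= {k for k in range(0, nz, stride_deep) if k > k_near}
    ks |= {0, nz - 1}
    rng = np.random.default_rng(seed)
    contours = {}
    for k in sorted(ks):
        contours[k] = _slice_contours(truth.interior_mask[k], jitter_um,
                                      params.voxel_size_xy, rng)
    return ContourSet(contours)
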