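"""Synthetic sub-fields: junctional stage patterns, granule fields, and
lumen phantoms.

These renderers produce the small, fully ground-truthed inputs that the
rosette classifiers are validated against, and are also used by the embryo
generator to stamp per-rosette junctional morphology into full stacks.

Stage morphology vocabulary (tight-junction marker):

* ``spot`` — compact punctum (max Feret below ~1.5 um);
* ``edge`` — short linear junctional segment between two cells;
* ``early_rosette`` — uninterrupted central signal at a vertex of five or
  more converging cells (solid focus plus radial junctions);
* ``late_rosette`` — discontinuous, webbed/reticular central signal: a
  ring with an enclosed gap around the expanding apical domain, with
  radial spokes.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from ._geometry import paint_ball, paint_cylinder_y
from .stack import VoxelStack

__all__ = [
    "render_stage_pattern",
    "generate_granule_field",
    "generate_lumen_phantom",
]

STAGES = ("spot", "edge", "early_rosette", "late_rosette")


def _spokes(img, cy, cx, r_in_px, r_out_px, n, rng, value=1.0):
    angles = rng.uniform(0, 2 * np.pi) + np.arange(n) * (2 * np.pi / n)
    for a in angles:
        r0 = np.array([cy + r_in_px * np.sin(a), cx + r_in_px * np.cos(a)])
        r1 = np.array([cy + r_out_px * np.sin(a), cx + r_out_px * np.cos(a)])
        rr, cc = draw_line(*np.round(r0).astype(int), *np.round(r1).astype(int))
        keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
        img[rr[keep], cc[keep]] = value


def render_stage_pattern(
    stage: str,
    n_cells: int = 6,
    pixel_size_um: float = 0.5,
    patch_um: float = 16.0,
    rng=None,
    ring_radius_um: float | None = None,
    value: float = 1.0,
):
    """Render one junctional maturation pattern onto a square patch.

    Returns ``(image, meta)`` where ``meta`` records the ground-truth stage,
    the cell vertex count, and geometric parameters.  ``ring_radius_um``
    overrides the late-rosette ring radius (used when the ring wraps a
    lumen of known size).
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    rng = np.random.default_rng(0) if rng is None else rng
    n_px = int(round(patch_um / pixel_size_um)) | 1  # odd size, centered
    img = np.zeros((n_px, n_px), dtype=np.float32)
    c = n_px // 2
    px = pixel_size_um

    if stage == "spot":
        rr, cc = draw_disk((c, c), max(0.5 / px, 1.0), shape=img.shape)
        img[rr, cc] = value
        vertex_count = 2
    elif stage == "edge":
        half = 2.0 / px
        a = rng.uniform(0, np.pi)
        d = np.array([np.sin(a), np.cos(a)]) * half
        rr, cc = draw_line(*np.round([c - d[0], c - d[1]]).astype(int),
                           *np.round([c + d[0], c + d[1]]).astype(int))
        img[rr, cc] = value
        # widen the stroke to ~0.6 um
        it = int(round(0.3 / px))
        if it:
            from scipy.ndimage import binary_dilation

            img[:] = binary_dilation(img > 0, iterations=it).astype(np.float32) * value
        vertex_count = 2
    elif stage == "early_rosette":
        vertex_count = max(int(n_cells), 5)
        rr, cc = draw_disk((c, c), 2.0 / px, shape=img.shape)
        img[rr, cc] = value
        _spokes(img, c, c, 2.0 / px, 5.5 / px, vertex_count, rng, value)
    else:  # late_rosette
        vertex_count = max(int(n_cells), 5)
        r_ring = (ring_radius_um if ring_radius_um is not None else 3.0) / px
        r_hole = max(r_ring - 1.6 / px, 1.2 / px)
        rr, cc = draw_disk((c, c), r_ring, shape=img.shape)
        img[rr, cc] = value
        rr, cc = draw_disk((c, c), r_hole, shape=img.shape)
        img[rr, cc] = 0.0
        _spokes(img, c, c, r_ring, r_ring + 3.0 / px, vertex_count, rng, value)

    meta = {
        "stage": stage,
        "cell_vertex_count": vertex_count,
        "pixel_size_um": pixel_size_um,
        "center_px": (c, c),
    }
    return img, meta


def generate_granule_field(
    n_granules: int = 12,
    diameter_um: float = 1.5,
    shape=(48, 96, 96),
    voxel_size_z: float = 0.5,
    voxel_size_xy: float = 0.5,
    snr: float = 10.0,
    noise_sd: float = 0.02,
    background_level: float = 0.1,
    min_separation_um: float = 4.0,
    seed: int = 0,
    cofluor_fraction: float = 0.0,
):
    """A calibrated volume of cytoplasmic granules with known centers.

    Granule amplitude is ``snr * noise_sd`` above background.  Returns a
    two-channel :class:`~rosettex.stack.VoxelStack` (``granule`` plus a
    ``cofluor`` channel marking a fraction of granules) and a ground-truth
    dict with centers (z, y, x in um), diameters, and co-positivity flags.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    ext_z, ext_xy = nz * voxel_size_z, ny * voxel_size_xy
    margin = diameter_um + 2.0
    centers = []
    for _ in range(10000):
        if len(centers) == n_granules:
            break
        cand = np.array(
            [
                rng.uniform(margin, ext_z - margin),
                rng.uniform(margin, ext_xy - margin),
                rng.uniform(margin, nx * voxel_size_xy - margin),
            ]
        )
        if all(np.linalg.norm(cand - p) >= min_separation_um for p in centers):
            centers.append(cand)
    if len(centers) != n_granules:
        raise RuntimeError("granule placement failed; enlarge the field")
    centers = np.asarray(centers)
    amp = snr * noise_sd
    gran = np.zeros(shape, dtype=np.float32)
    co = np.zeros(shape, dtype=np.float32)
    co_flags = rng.random(n_granules) < cofluor_fraction
    for i, ctr in enumerate(centers):
        paint_ball(gran, ctr, diameter_um / 2.0, voxel_size_z, voxel_size_xy, amp)
        if co_flags[i]:
            paint_ball(co, ctr, diameter_um / 2.0, voxel_size_z, voxel_size_xy, amp)
    data = np.stack([gran, co]) + background_level
    if noise_sd > 0:
        data = data + rng.standard_normal(data.shape, dtype=np.float32) * noise_sd
    stack = VoxelStack(
        np.clip(data, 0.0, 1.0),
        voxel_size_z=voxel_size_z,
        voxel_size_xy=voxel_size_xy,
        channel_names=("granule", "cofluor"),
    )
    truth = {
        "centers_um": centers,
        "diameters_um": np.full(n_granules, diameter_um),
        "cofluor": co_flags,
    }
    return stack, truth


def generate_lumen_phantom(
    kind: str = "sphere",
    radius_um: float = 4.0,
    length_um: float = 20.0,
    shell_um: float = 1.5,
    voxel_size_z: float = 1.0,
    voxel_size_xy: float = 0.5,
    pad_um: float = 6.0,
    signal: float = 0.8,
    background_level: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """An apical-marker patch enclosing a dark lumen of known geometry.

    ``sphere`` renders a spherical shell around a ball of negative space;
    ``tube`` renders a closed shell around a y-axis cylinder (analytic
    volume ``pi r^2 L``).  Returns ``(stack, truth)`` with the analytic
    volume and the rosette-center coordinate.
    """
    if kind not in ("sphere", "tube"):
        raise ValueError("kind must be 'sphere' or 'tube'")
    half_y = radius_um if kind == "sphere" else length_um / 2.0
    ez = radius_um + shell_um + pad_um
    ey = half_y + shell_um + pad_um
    ex = radius_um + shell_um + pad_um
    shape = (
        int(np.ceil(2 * ez / voxel_size_z)) + 1,
        int(np.ceil(2 * ey / voxel_size_xy)) + 1,
        int(np.ceil(2 * ex / voxel_size_xy)) + 1,
    )
    center = (
        (shape[0] // 2) * voxel_size_z,
        (shape[1] // 2) * voxel_size_xy,
        (shape[2] // 2) * voxel_size_xy,
    )
    vol = np.zeros(shape, dtype=np.float32)
    if kind == "sphere":
        paint_ball(vol, center, radius_um + shell_um, voxel_size_z, voxel_size_xy,
                   signal, inner_radius_um=radius_um)
        analytic = 4.0 / 3.0 * np.pi * radius_um**3
    else:
        paint_cylinder_y(vol, center, radius_um, length_um, voxel_size_z,
                         voxel_size_xy, signal, shell_um=shell_um)
        analytic = np.pi * radius_um**2 * length_um
    rng = np.random.default_rng(seed)
    data = vol + background_level
    if noise_sd > 0:
        data = data + rng.standard_normal(data.shape, dtype=np.float32) * noise_sd
    stack = VoxelStack(
        np.clip(data, 0.0, 1.0),
        voxel_size_z=voxel_size_z,
        voxel_size_xy=voxel_size_xy,
        channel_names=("apical",),
    )
    truth = {"kind": kind, "center_um": center, "radius_um": radius_um,
             "length_um": length_um if kind == "tube" else None,
             "analytic_volume_um3": analytic}
    return stack, truth
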