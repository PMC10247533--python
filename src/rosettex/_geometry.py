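"""Internal voxel-painting and sampling helpers for the synthetic generator."""

from __future__ import annotations

import numpy as np

__all__ = [
    "PlacementError",
    "hex_points",
    "place_separated",
    "paint_ball",
    "paint_cylinder_y",
    "ball_mask_local",
]


class PlacementError(RuntimeError):
    """Structure placement is infeasible for the requested volume/counts."""


def hex_points(y0: float, y1: float, x0: float, x1: float, spacing: float, rng, jitter_frac: float = 0.2) -> np.ndarray:
    """Jittered hexagonal lattice of (y, x) points covering a rectangle (um)."""
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = np.arange(y0, y1 + dy, dy)
    pts = []
    for i, yy in enumerate(rows):
        off = 0.0 if i % 2 == 0 else spacing / 2.0
        xs = np.arange(x0 + off, x1 + spacing, spacing)
        pts.append(np.column_stack([np.full_like(xs, yy), xs]))
    pts = np.concatenate(pts)
    pts = pts + rng.normal(0.0, jitter_frac * spacing, pts.shape)
    return pts


def place_separated(n: int, bounds, min_dist, rng, existing=None, max_tries: int = 5000) -> np.ndarray:
    """Rejection-sample ``n`` (y, x) points with pairwise separation.

    ``min_dist`` may be a scalar or a callable ``(i, j) -> um`` on indices of
    the combined (existing + new) list.  Raises :class:`PlacementError` when
    the budget of attempts is exhausted — placement failures are explicit,
    never silently truncated.
    """
    y0, y1, x0, x1 = bounds
    placed = [] if existing is None else [np.asarray(p, dtype=float) for p in existing]
    n_existing = len(placed)
    for i in range(n):
        for _ in range(max_tries):
            cand = np.array([rng.uniform(y0, y1), rng.uniform(x0, x1)])
            ok = True
            for j, p in enumerate(placed):
                d = min_dist if np.isscalar(min_dist) else min_dist(n_existing + i, j)
                if np.hypot(*(cand - p)) < d:
                    ok = False
                    break
            if ok:
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place structure {i + 1}/{n} with required separation"
            )
    return np.asarray(placed[n_existing:])


def _local_grid(shape, center_um, extent_um, vz, vxy):
    """Bounding-box slice plus um-offset coordinate grids around a center."""
    nz, ny, nx = shape
    cz, cy, cx = center_um
    z0 = max(int(np.floor((cz - extent_um) / vz)), 0)
    z1 = min(int(np.ceil((cz + extent_um) / vz)) + 1, nz)
    y0 = max(int(np.floor((cy - extent_um) / vxy)), 0)
    y1 = min(int(np.ceil((cy + extent_um) / vxy)) + 1, ny)
    x0 = max(int(np.floor((cx - extent_um) / vxy)), 0)
    x1 = min(int(np.ceil((cx + extent_um) / vxy)) + 1, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return None, None
    dz = np.arange(z0, z1) * vz - cz
    dy = np.arange(y0, y1) * vxy - cy
    dx = np.arange(x0, x1) * vxy - cx
    sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
    return sl, (dz[:, None, None], dy[None, :, None], dx[None, None, :])


def ball_mask_local(shape, center_um, radius_um, vz, vxy):
    """Slice + boolean mask of a ball (voxel-center inclusion)."""
    sl, grids = _local_grid(shape, center_um, radius_um, vz, vxy)
    if sl is None:
        return None, None
    dz, dy, dx = grids
    return sl, dz**2 + dy**2 + dx**2 <= radius_um**2


def paint_ball(volume, center_um, radius_um, vz, vxy, value=1.0, inner_radius_um=0.0):
    """Paint a solid ball (or spherical shell if inner_radius_um > 0)."""
    sl, grids = _local_grid(volume.shape, center_um, radius_um, vz, vxy)
    if sl is None:
        return
    dz, dy, dx = grids
    r2 = dz**2 + dy**2 + dx**2
    mask = r2 <= radius_um**2
    if inner_radius_um > 0:
        mask &= r2 > inner_radius_um**2
    volume[sl][mask] = value


def paint_cylinder_y(volume, center_um, radius_um, length_um, vz, vxy, value=1.0,
                     shell_um: float = 0.0):
    """Paint a y-axis-aligned solid cylinder, or its enclosing shell.

    With ``shell_um > 0`` paints the closed shell of thickness ``shell_um``
    around the cylinder (radial wall plus end caps) instead of the interior.
    """
    extent = max(radius_um, length_um / 2.0) + shell_um
    sl, grids = _local_grid(volume.shape, center_um, extent, vz, vxy)
    if sl is None:
        return
    dz, dy, dx = grids
    rad = np.sqrt(dz**2 + dx**2)
    ay = np.abs(dy)
    inner = (rad <= radius_um) & (ay <= length_um / 2.0)
    if shell_um <= 0:
        volume[sl][inner] = value
        return
    outer = (rad <= radius_um + shell_um) & (ay <= length_um / 2.0 + shell_um)
    volume[sl][outer & ~inner] = value
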