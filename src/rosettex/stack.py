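"""Calibrated image containers: voxel stacks and sparse contour annotations.

A :class:`VoxelStack` is the universal carrier for multi-channel 3D (or
3D+time) fluorescence volumes.  Axis order is fixed as ``(t, channel, z, y,
x)`` with the time axis optional, and z index 0 is the distal-most slice
(embryos are mounted distal side down, so low z is closest to the
objective).  Intensities are fractional values in ``[0, 1]``; integer bit
depths appear only at file I/O.

A :class:`ContourSet` holds sparse per-slice embryo-outline polygons, the
stand-in for manually drawn regions of interest.  Polygon vertices are
``(x, y)`` pairs in 0-based pixel coordinates, where integer coordinates
are pixel centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from shapely import contains_xy
from shapely.geometry import Polygon

__all__ = ["VoxelStack", "ContourSet", "ContourError", "rasterize_polygons"]


class ContourError(ValueError):
    """Raised for invalid contour annotations (e.g. self-intersections)."""


@dataclass
class VoxelStack:
    """Calibrated intensity volume with axes ``(channel, z, y, x)``.

    Parameters
    ----------
    data
        Float array in ``[0, 1]`` of shape ``(c, z, y, x)``.  A bare
        ``(z, y, x)`` array is promoted to a single channel.
    voxel_size_z, voxel_size_xy
        Voxel spacing in micrometers.  Voxel centers sit at
        ``index * spacing``.
    channel_names
        One name per channel.
    frame_interval_min
        Frame spacing in minutes for stacks that are one frame of a movie.
    """

    data: np.ndarray
    voxel_size_z: float
    voxel_size_xy: float
    channel_names: tuple[str, ...] | None = None
    frame_interval_min: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected (c, z, y, x) data, got shape {self.data.shape}")
        if not (self.voxel_size_z > 0 and self.voxel_size_xy > 0):
            raise ValueError("voxel sizes must be positive")
        if self.channel_names is None:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        else:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.data.shape[0]:
                raise ValueError("channel_names length must match channel axis")

    # -- convenience -----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.data[idx]

    def z_coords_um(self) -> np.ndarray:
        return np.arange(self.shape_zyx[0]) * self.voxel_size_z

    def with_data(self, data: np.ndarray, channel_names=None) -> "VoxelStack":
        return replace(
            self,
            data=data,
            channel_names=tuple(channel_names) if channel_names is not None else self.channel_names,
        )

    # -- I/O -------------------------------------------------------------
    def to_tiff(self, path, dtype=np.float32) -> None:
        """Write as a multi-page TIFF with voxel sizes in ImageJ metadata."""
        data = self.data.astype(dtype)
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            data = np.clip(self.data, 0.0, 1.0) * info.max
            data = data.round().astype(dtype)
        tifffile.imwrite(
            path,
            np.swapaxes(data, 0, 1)[None],  # ImageJ hyperstack order TZCYX
            imagej=True,
            resolution=(1.0 / self.voxel_size_xy, 1.0 / self.voxel_size_xy),
            metadata={
                "spacing": self.voxel_size_z,
                "unit": "um",
                "axes": "TZCYX",
                "Labels": list(self.channel_names),
                "channel_names": ",".join(self.channel_names),
            },
        )

    @classmethod
    def from_tiff(cls, path, voxel_size_z=None, voxel_size_xy=None, channel_names=None) -> "VoxelStack":
        """Read a multi-page TIFF, recovering calibration from metadata.

        Explicit ``voxel_size_*`` arguments override file metadata; they are
        required when the file carries none.
        """
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            axes = tf.series[0].axes
            meta = tf.imagej_metadata or {}
            if voxel_size_z is None:
                voxel_size_z = meta.get("spacing")
            if voxel_size_xy is None:
                page = tf.pages[0]
                res = page.tags.get("XResolution")
                if res is not None:
                    num, den = res.value
                    if num:
                        voxel_size_xy = den / num
            if channel_names is None and meta.get("channel_names"):
                channel_names = tuple(meta["channel_names"].split(","))
        if voxel_size_z is None or voxel_size_xy is None:
            raise ValueError(f"{path}: no voxel-size metadata; pass voxel_size_z/voxel_size_xy")
        # normalise axes to (c, z, y, x)
        arr = np.asarray(arr)
        axes = axes.replace("S", "C")
        # unknown page axes of plain TIFF stacks are the z axis
        for unknown in ("Q", "I"):
            if unknown in axes:
                axes = axes.replace(unknown, "Z" if "Z" not in axes else "T", 1)
        while "T" in axes:
            arr = arr.take(0, axis=axes.index("T"))
            axes = axes.replace("T", "", 1)
        if "C" not in axes:
            arr = arr[None]
            axes = "C" + axes
        if "Z" not in axes:
            arr = arr[:, None] if axes.startswith("C") else arr[None]
            axes = axes.replace("C", "CZ", 1)
        order = [axes.index(a) for a in "CZYX"]
        arr = np.transpose(arr, order)
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
        return cls(
            data=arr.astype(np.float32),
            voxel_size_z=float(voxel_size_z),
            voxel_size_xy=float(voxel_size_xy),
            channel_names=channel_names,
        )


def _as_polygon(vertices, slice_index: int) -> Polygon:
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ContourError(f"slice {slice_index}: polygon needs >=3 (x, y) vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ContourError(f"slice {slice_index}: self-intersecting or invalid polygon")
    return poly


def rasterize_polygons(polygons, shape_yx) -> np.ndarray:
    """Rasterize a list of shapely polygons onto a pixel grid.

    A pixel belongs to the mask when its center ``(x=col, y=row)`` lies
    inside (or on the boundary of) any polygon.
    """
    ny, nx = shape_yx
    mask = np.zeros((ny, nx), dtype=bool)
    for poly in polygons:
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.floor(minx)) - 1, 0)
        c1 = min(int(np.ceil(maxx)) + 2, nx)
        r0 = max(int(np.floor(miny)) - 1, 0)
        r1 = min(int(np.ceil(maxy)) + 2, ny)
        if c0 >= c1 or r0 >= r1:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = contains_xy(poly, cols.ravel(), rows.ravel()) | contains_xy(
            poly.boundary, cols.ravel(), rows.ravel()
        )
        mask[r0:r1, c0:c1] |= inside.reshape(rows.shape)
    return mask


@dataclass
class ContourSet:
    """Sparse per-slice embryo-outline polygons.

    ``contours`` maps an annotated slice index to a list of closed simple
    polygons, each an ``(n, 2)`` array of ``(x, y)`` pixel coordinates.  An
    annotated slice with an empty list is an explicit "nothing here"
    annotation (used above the distal tip of the embryo).
    """

    contours: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, list[np.ndarray]] = {}
        for k in sorted(self.contours):
            polys = [np.asarray(v, dtype=float) for v in self.contours[k]]
            for v in polys:
                _as_polygon(v, int(k))
            clean[int(k)] = polys
        self.contours = clean

    @property
    def annotated_slices(self) -> list[int]:
        return sorted(self.contours)

    def polygons(self, slice_index: int) -> list[Polygon]:
        return [_as_polygon(v, slice_index) for v in self.contours[slice_index]]

    def rasterize_slice(self, slice_index: int, shape_yx) -> np.ndarray:
        return rasterize_polygons(self.polygons(slice_index), shape_yx)

    # -- I/O -------------------------------------------------------------
    def to_json(self, path) -> None:
        doc = {str(k): [np.asarray(v).tolist() for v in vs] for k, vs in self.contours.items()}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ContourSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls({int(k): [np.asarray(v, dtype=float) for v in vs] for k, vs in doc.items()})
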