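"""Morphometrics of the emerged axial-mesoderm epithelium.

Works on surface/subsurface maximum-intensity projections produced by
surface extraction.  Emerged axial-mesoderm regions are recognised by
their small apical domains relative to the squamous surface endoderm: the
junctional lattice is binarised, its enclosed apices (cell apical domains)
are measured, and connected groups of small apices form candidate
mesoderm regions.  A region qualifies when its median enclosed-apex area
falls below ``small_apex_threshold_um2`` — an explicit operationalisation
of the qualitative "smaller apical surfaces" criterion (the threshold is a
package default, not a measured value).  Regions found on the surface
projection are flagged emerged, regions on the subsurface projection
unemerged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk

__all__ = [
    "FieldOfView",
    "RegionTable",
    "crop_field_of_view",
    "segment_epithelial_regions",
    "summarize_clusters",
]


@dataclass(frozen=True)
class FieldOfView:
    """Physical crop window: mediolateral width x anterior-posterior height."""

    width_um: float  # x extent
    height_um: float  # y extent
    center_x_um: float
    center_y_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("field of view extents must be positive")


@dataclass
class RegionTable:
    """Segmented epithelial regions plus the label image they came from.

    ``df`` columns: region_id, emerged, area_um2, centroid_x_um,
    centroid_y_um, median_apex_um2, n_cells, mean_cell_area_um2, state,
    border_touch.  ``label_image`` assigns each pixel its region_id (0 =
    none); emerged and unemerged regions share one id namespace.
    """

    df: pd.DataFrame
    label_image: np.ndarray
    pixel_size_um: float
    apex_areas_um2: dict[int, list[float]] = field(default_factory=dict)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.label_image == region_id

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def crop_field_of_view(image: np.ndarray, fov: FieldOfView, pixel_size_um: float) -> np.ndarray:
    """Crop a projection to an exact physical field of view.

    The pixel count is the physical extent divided by the pixel size,
    rounded to the nearest whole pixel; the window start is the rounded
    pixel of ``center - extent/2``.  A window exceeding the image bounds is
    rejected.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    ny, nx = image.shape[-2:]
    w_px = int(round(fov.width_um / pixel_size_um))
    h_px = int(round(fov.height_um / pixel_size_um))
    x0 = int(round(fov.center_x_um / pixel_size_um - w_px / 2.0))
    y0 = int(round(fov.center_y_um / pixel_size_um - h_px / 2.0))
    if x0 < 0 or y0 < 0 or x0 + w_px > nx or y0 + h_px > ny:
        raise ValueError(
            f"field of view [{y0}:{y0 + h_px}, {x0}:{x0 + w_px}] px exceeds image {image.shape}"
        )
    return image[..., y0: y0 + h_px, x0: x0 + w_px]


def _binarize(proj: np.ndarray, threshold: float | None) -> np.ndarray:
    if threshold is None:
        if proj.max() <= proj.min():
            return np.zeros(proj.shape, dtype=bool)
        threshold = threshold_otsu(proj)
        # junctional signal is sparse; an Otsu split landing inside the
        # background mode is re-run on the upper population
        for _ in range(3):
            frac = (proj > threshold).mean()
            if frac <= 0.3:
                break
            upper = proj[proj > threshold]
            if upper.max() <= upper.min():
                break
            threshold = threshold_otsu(upper)
    return proj > threshold


def segment_epithelial_regions(
    surface_proj: np.ndarray,
    subsurface_proj: np.ndarray,
    pixel_size_um: float,
    small_apex_threshold_um2: float = 50.0,
    min_region_um2: float = 20.0,
    counting_min_apex_um2: float = 2.0,
    threshold: float | None = None,
    closing_radius_um: float = 1.0,
) -> RegionTable:
    """Segment emerged and unemerged epithelial regions from a projection pair.

    Surface projection: the junctional lattice is binarised and its
    4-connected complement components (apices) measured; apices touching
    the image border are ignored (truncated endoderm apices).  Small apices
    (< ``small_apex_threshold_um2``) are unioned, closed across the
    junction lines, and labelled into candidate regions; a region is kept
    when its median apex area stays below the threshold and its area
    reaches ``min_region_um2``.  Apices below ``counting_min_apex_um2`` are
    excluded from cell counts (constricted perimeter cells).

    Subsurface projection: connected junctional-signal components above
    ``min_region_um2`` are reported directly as unemerged regions.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("projections must carry a positive pixel size")
    px_area = pixel_size_um**2
    rows = []
    label_img = np.zeros(surface_proj.shape, dtype=np.int32)
    apex_areas: dict[int, list[float]] = {}
    next_id = 1

    lattice = _binarize(np.asarray(surface_proj, dtype=float), threshold)
    if lattice.any():
        apices = sk_label(~lattice, connectivity=1)
        props = regionprops(apices)
        ny, nx = lattice.shape
        small = np.zeros(lattice.shape, dtype=bool)
        apex_area_of = {}
        for p in props:
            r0, c0, r1, c1 = p.bbox
            if r0 == 0 or c0 == 0 or r1 == ny or c1 == nx:
                continue  # border-truncated apex
            a = p.area * px_area
            apex_area_of[p.label] = a
            if a < small_apex_threshold_um2:
                small[apices == p.label] = True
        if small.any():
            selem = disk(max(int(round(closing_radius_um / pixel_size_um)), 1))
            merged = ndimage.binary_closing(small, structure=selem)
            regions = sk_label(merged, connectivity=2)
            for p in regionprops(regions):
                mask_p = regions == p.label
                # the junction line bordering the apices is shared with the
                # neighbouring cells: an annotator's outline runs through its
                # middle, so half of it belongs to the region
                rim = ndimage.binary_dilation(mask_p) & lattice & ~merged
                area = (p.area + 0.5 * rim.sum()) * px_area
                if area < min_region_um2:
                    continue
                mask = mask_p
                ids = np.unique(apices[mask & (apices > 0)])
                areas = [apex_area_of[i] for i in ids if i in apex_area_of]
                areas_small = [a for a in areas if a < small_apex_threshold_um2]
                if not areas_small or np.median(areas_small) >= small_apex_threshold_um2:
                    continue
                n_cells = sum(1 for a in areas_small if a >= counting_min_apex_um2)
                cy, cx = p.centroid
                r0, c0, r1, c1 = p.bbox
                rows.append(dict(
                    region_id=next_id, emerged=True, area_um2=area,
                    centroid_x_um=cx * pixel_size_um, centroid_y_um=cy * pixel_size_um,
                    median_apex_um2=float(np.median(areas_small)),
                    n_cells=n_cells,
                    mean_cell_area_um2=area / n_cells if n_cells else np.nan,
                    border_touch=bool(r0 == 0 or c0 == 0 or r1 == ny or c1 == nx),
                ))
                label_img[mask] = next_id
                apex_areas[next_id] = areas_small
                next_id += 1
        # solid junctional domains (no enclosed apices) are nascent emerged
        # regions too: compact components of the binarised signal that carry
        # no apices qualify; the extended endoderm lattice network fails the
        # solidity test and is never swallowed
        comps = sk_label(lattice, connectivity=2)
        for p in regionprops(comps):
            area = p.area * px_area
            if area < min_region_um2 or p.solidity < 0.5:
                continue
            mask = comps == p.label
            if (label_img[ndimage.binary_dilation(mask)] > 0).any():
                continue  # belongs to an apex-bearing region already found
            touched = np.unique(apices[ndimage.binary_dilation(mask) & (apices > 0)])
            if any(t in apex_area_of for t in touched):
                continue  # part of the open lattice, not a solid domain
            cy, cx = p.centroid
            r0, c0, r1, c1 = p.bbox
            rows.append(dict(
                region_id=next_id, emerged=True, area_um2=area,
                centroid_x_um=cx * pixel_size_um, centroid_y_um=cy * pixel_size_um,
                median_apex_um2=np.nan, n_cells=np.nan, mean_cell_area_um2=np.nan,
                border_touch=bool(r0 == 0 or c0 == 0 or r1 == ny or c1 == nx),
            ))
            label_img[mask] = next_id
            next_id += 1

    sub = _binarize(np.asarray(subsurface_proj, dtype=float), threshold)
    if sub.any():
        labels = sk_label(sub, connectivity=2)
        ny, nx = sub.shape
        for p in regionprops(labels):
            area = p.area * px_area
            if area < min_region_um2:
                continue
            cy, cx = p.centroid
            r0, c0, r1, c1 = p.bbox
            rows.append(dict(
                region_id=next_id, emerged=False, area_um2=area,
                centroid_x_um=cx * pixel_size_um, centroid_y_um=cy * pixel_size_um,
                median_apex_um2=np.nan, n_cells=np.nan, mean_cell_area_um2=np.nan,
                border_touch=bool(r0 == 0 or c0 == 0 or r1 == ny or c1 == nx),
            ))
            label_img[labels == p.label] = next_id
            next_id += 1

    columns = ["region_id", "emerged", "area_um2", "centroid_x_um", "centroid_y_um",
               "median_apex_um2", "n_cells", "mean_cell_area_um2", "border_touch"]
    df = pd.DataFrame(rows, columns=columns)
    return RegionTable(df=df, label_image=label_img, pixel_size_um=pixel_size_um,
                       apex_areas_um2=apex_areas)


def summarize_clusters(table: RegionTable, cell_counts: dict[int, int] | None = None) -> dict:
    """Cluster-level summary: counts, areas, emerged fraction, cell areas.

    ``cell_counts`` optionally overrides the automatic per-region cell
    counts (mirroring manual counting).  The mean cell area of a region
    with zero cells is reported as ``None`` (explicitly undefined), never a
    division.  Emerged fraction is emerged area over total epithelial area
    and always lies in [0, 1].
    """
    df = table.df
    emerged = df[df.emerged]
    unemerged = df[~df.emerged]
    e_area = float(emerged.area_um2.sum())
    u_area = float(unemerged.area_um2.sum())
    total = e_area + u_area
    per_region = {}
    for _, row in emerged.iterrows():
        rid = int(row.region_id)
        n = cell_counts.get(rid) if cell_counts is not None else row.n_cells
        if n is None or (isinstance(n, float) and np.isnan(n)) or n == 0:
            per_region[rid] = None
        else:
            if n < 0:
                raise ValueError(f"region {rid}: negative cell count")
            per_region[rid] = float(row.area_um2) / float(n)
    return {
        "n_emerged_clusters": int(len(emerged)),
        "n_unemerged_regions": int(len(unemerged)),
        "emerged_area_um2": e_area,
        "unemerged_area_um2": u_area,
        "emerged_fraction": e_area / total if total > 0 else float("nan"),
        "mean_cell_area_um2": per_region,
    }
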