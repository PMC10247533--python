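"""Rosette-level analysis: location classes, lumens, junctional staging,
granules, and apical-marker distributions.

Rosette centers are inputs (annotations or ground truth), mirroring manual
identification of centers by junctional/F-actin enrichment.  The location
classifier applies the stated precedence ``partially_emerged ->
endoderm_contacting -> basal``: a rosette whose central domain breaches
the embryo surface is partially emerged regardless of any deeper parts,
one whose apical domain touches the surface endoderm is
endoderm-contacting, and anything else is basal (the basal definition —
apical center at least one axial-mesoderm cell diameter from the surface
endoderm — is the complement of the two contact rules; composite
morphologies resolve by the region closest to the surface).

Lumen presence is operationalised as a connected pocket of negative space
(intensity below background + k*noise) enclosed by apical-marker signal
and not connected to the exterior; enclosure is evaluated in 3D by
default, with a per-transverse-plane 2D mode available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "LumenMeasure",
    "GranuleSet",
    "classify_rosette_location",
    "analyze_lumen",
    "stage_junctional_region",
    "detect_granules",
    "classify_marker_distribution",
    "MARKER_CATEGORIES",
]

LOCATION_CLASSES = ("basal", "endoderm_contacting", "partially_emerged")
STAGES = ("spot", "edge", "early_rosette", "late_rosette")
MARKER_CATEGORIES = ("none", "granular", "transitional", "apical", "junctional")



def _robust_otsu(arr: np.ndarray) -> float:
    """Otsu threshold, re-run on the upper population when the split lands
    inside the (dominant) background mode of sparse-signal images."""
    if arr.max() <= arr.min():
        return np.inf
    thr = threshold_otsu(arr)
    for _ in range(3):
        if (arr > thr).mean() <= 0.3:
            break
        upper = arr[arr > thr]
        if upper.max() <= upper.min():
            break
        thr = threshold_otsu(upper)
    return thr

def classify_rosette_location(
    center_um,
    apical_domain_mask: np.ndarray,
    surface_height_map: np.ndarray,
    endoderm_mask: np.ndarray,
    voxel_size_z: float,
    voxel_size_xy: float,
    cell_diameter_um: float = 10.0,
    surface_tol_um: float | None = None,
) -> str:
    """Assign exactly one location class to a rosette.

    ``apical_domain_mask`` is the rosette's central membrane-rich domain
    (3D boolean); ``endoderm_mask`` the surface endoderm voxels.  The
    surface-breach test marks the rosette partially emerged when any
    apical voxel lies within ``surface_tol_um`` (default: one z step) of
    the surface height map; endoderm contact is 26-connected voxel
    adjacency.  ``cell_diameter_um`` documents the basal-distance rule; by
    precedence, any non-contacting rosette is basal.
    """
    nz, ny, nx = apical_domain_mask.shape
    cz, cy, cx = center_um
    if not (0 <= cz <= (nz - 1) * voxel_size_z and 0 <= cy <= (ny - 1) * voxel_size_xy
            and 0 <= cx <= (nx - 1) * voxel_size_xy):
        raise ValueError(f"rosette center {center_um} outside the stack")
    if not apical_domain_mask.any():
        raise ValueError("empty apical domain mask")
    if surface_tol_um is None:
        surface_tol_um = voxel_size_z
    # restrict to the rosette's own apical domain: every connected component
    # with a voxel within ``domain_radius_um`` of the center, so
    # neighbouring rosettes in a whole-stack mask cannot leak into the call
    domain_radius_um = 12.0
    labels = sk_label(apical_domain_mask, connectivity=3)
    keep = set()
    for sl_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        zz, yy, xx = np.nonzero(labels[sl] == sl_idx)
        d2 = ((zz + sl[0].start) * voxel_size_z - cz) ** 2 \
            + ((yy + sl[1].start) * voxel_size_xy - cy) ** 2 \
            + ((xx + sl[2].start) * voxel_size_xy - cx) ** 2
        if d2.min() <= domain_radius_um**2:
            keep.add(sl_idx)
    if keep:
        apical_domain_mask = np.isin(labels, list(keep))
    zz, yy, xx = np.nonzero(apical_domain_mask)
    depth = zz * voxel_size_z - surface_height_map[yy, xx]
    if depth.min() <= surface_tol_um:
        return "partially_emerged"
    touch = ndimage.binary_dilation(apical_domain_mask, np.ones((3, 3, 3), dtype=bool))
    if (touch & endoderm_mask).any():
        return "endoderm_contacting"
    return "basal"


@dataclass
class LumenMeasure:
    has_lumen: bool
    mask: np.ndarray | None
    area_um2: float  # largest transverse (xz) section
    volume_um3: float
    elongated: bool


def analyze_lumen(
    apical_patch: np.ndarray,
    center_um,
    voxel_size_z: float,
    voxel_size_xy: float,
    min_lumen_um3: float = 5.0,
    threshold: float | None = None,
    max_center_dist_um: float = 12.0,
    mode: str = "3d",
) -> LumenMeasure:
    """Detect and measure the lumen enclosed by an apical-marker patch.

    The lumen is a low-intensity connected component enclosed by
    apical-marker signal, not background-connected to the patch exterior,
    with volume at least ``min_lumen_um3``.  Volume is voxel count times
    voxel volume; area is the largest transverse (xz) cross-section; the
    lumen is flagged elongated when the ratio of longest to shortest
    principal extents exceeds 2.  ``mode='2d'`` additionally requires
    enclosure within at least one transverse plane instead of full 3D
    enclosure.
    """
    patch = np.asarray(apical_patch, dtype=float)
    nz, ny, nx = patch.shape
    cz, cy, cx = center_um
    ci = (int(round(cz / voxel_size_z)), int(round(cy / voxel_size_xy)),
          int(round(cx / voxel_size_xy)))
    if not all(0 <= c < n for c, n in zip(ci, patch.shape)):
        raise ValueError("rosette center outside patch")
    if mode not in ("3d", "2d"):
        raise ValueError("mode must be '3d' or '2d'")
    if threshold is None:
        threshold = _robust_otsu(patch)
    bright = patch > threshold
    dark = ~bright
    voxel_vol = voxel_size_z * voxel_size_xy**2
    none = LumenMeasure(False, None, 0.0, 0.0, False)
    if not bright.any():
        return none

    labels = sk_label(dark, connectivity=1)
    border = np.zeros(patch.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    exterior_ids = set(np.unique(labels[border & dark]).tolist())
    volumes = np.bincount(labels.ravel()) * voxel_vol
    objects = ndimage.find_objects(labels)
    candidates = []
    for rid in range(1, len(volumes)):
        if rid in exterior_ids or volumes[rid] < min_lumen_um3:
            continue
        sl = objects[rid - 1]
        if sl is None:
            continue
        zzc, yyc, xxc = np.nonzero(labels[sl] == rid)
        centroid = np.array([(zzc + sl[0].start).mean() * voxel_size_z,
                             (yyc + sl[1].start).mean() * voxel_size_xy,
                             (xxc + sl[2].start).mean() * voxel_size_xy])
        dist = np.linalg.norm(centroid - np.asarray(center_um, dtype=float))
        if dist <= max_center_dist_um:
            candidates.append((dist, rid, labels == rid, volumes[rid]))
    if not candidates:
        return none
    candidates.sort(key=lambda t: t[0])
    _, _, mask, vol = candidates[0]
    if mode == "2d":
        enclosed_any_plane = False
        for y in range(ny):
            sl = mask[:, y, :]
            if not sl.any():
                continue
            if not (sl[0].any() or sl[-1].any() or sl[:, 0].any() or sl[:, -1].any()):
                enclosed_any_plane = True
                break
        if not enclosed_any_plane:
            return none
    zzc, yyc, xxc = np.nonzero(mask)
    area = float(max(mask[:, y, :].sum() for y in range(ny)) * voxel_size_z * voxel_size_xy)
    coords = np.column_stack([zzc * voxel_size_z, yyc * voxel_size_xy, xxc * voxel_size_xy])
    elongated = False
    if len(coords) >= 4:
        cov = np.cov((coords - coords.mean(axis=0)).T)
        ev = np.sort(np.linalg.eigvalsh(cov))
        if ev[0] > 1e-9:
            elongated = bool(np.sqrt(ev[-1] / ev[0]) > 2.0)
    return LumenMeasure(True, mask, area, float(vol), elongated)


def _max_feret_um(mask: np.ndarray, pixel_size_um: float) -> float:
    props = regionprops(mask.astype(np.uint8))
    if not props:
        return 0.0
    return float(max(p.feret_diameter_max for p in props)) * pixel_size_um


def stage_junctional_region(
    patch: np.ndarray,
    cell_vertex_count: int,
    pixel_size_um: float,
    spot_max_feret_um: float = 1.5,
    hole_min_area_um2: float = 3.0,
    threshold: float | None = None,
) -> str:
    """Stage a junctional region as spot, edge, early or late rosette.

    Spot: compact punctum (max Feret below ``spot_max_feret_um``).  Late
    rosette: the central signal encloses at least one gap of area >=
    ``hole_min_area_um2`` (webbed/reticular pattern).  Early rosette:
    uninterrupted central signal at a vertex of five or more cells.  Edge:
    a linear junctional segment not at such a vertex.
    """
    patch = np.asarray(patch, dtype=float)
    if threshold is None:
        threshold = _robust_otsu(patch)
    mask = patch > threshold
    if not mask.any():
        raise ValueError("empty junctional patch")
    if _max_feret_um(mask, pixel_size_um) < spot_max_feret_um:
        return "spot"
    holes = sk_label(~mask, connectivity=1)
    ny, nx = mask.shape
    for p in regionprops(holes):
        r0, c0, r1, c1 = p.bbox
        if r0 == 0 or c0 == 0 or r1 == ny or c1 == nx:
            continue
        if p.area * pixel_size_um**2 >= hole_min_area_um2:
            return "late_rosette"
    if cell_vertex_count >= 5:
        return "early_rosette"
    return "edge"


@dataclass
class GranuleSet:
    """Detected cytoplasmic granules with per-channel co-positivity."""

    df: pd.DataFrame  # z_um, y_um, x_um, diameter_um, co_<channel> flags
    diameter_band_um: tuple[float, float]
    density_per_cell: float | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def centers_um(self) -> np.ndarray:
        return self.df[["z_um", "y_um", "x_um"]].to_numpy()


def detect_granules(
    channel: np.ndarray,
    voxel_size_z: float,
    voxel_size_xy: float,
    diameter_band_um: tuple[float, float] = (1.0, 2.0),
    cofluor: dict[str, np.ndarray] | None = None,
    background: float | None = None,
    noise_sd: float | None = None,
    k_detect: float = 4.0,
    co_factor: float = 2.0,
    band_tol_um: float = 0.75,
) -> GranuleSet:
    """Detect cytoplasmic granules restricted to a physical diameter band.

    Matched-filter detection: the channel is smoothed at the band's inner
    scale, local maxima above ``background + k_detect * noise_sd`` become
    candidate granules, each refined to an intensity-weighted subvoxel
    center; candidates whose half-maximum equivalent diameter leaves the
    band (with ``band_tol_um`` slack for smoothing inflation) are dropped.
    A granule is co-positive for an extra channel when that channel's mean
    intensity inside the granule exceeds its local background by
    ``co_factor``-fold of the noise floor.
    """
    vol = np.asarray(channel, dtype=np.float32)
    if background is None:
        background = float(np.median(vol))
    if noise_sd is None:
        mad = float(np.median(np.abs(vol - background)))
        noise_sd = max(1.4826 * mad, 1e-6)
    d_lo, d_hi = diameter_band_um
    sigma_um = 0.2 * d_lo + 0.1  # light matched filter; heavier blur costs recall
    sig = (sigma_um / voxel_size_z, sigma_um / voxel_size_xy, sigma_um / voxel_size_xy)
    smooth = ndimage.gaussian_filter(vol, sigma=sig)
    thr = background + k_detect * noise_sd
    from skimage.feature import peak_local_max

    min_dist = max(int(round(d_lo / (2 * voxel_size_xy))), 1)
    peaks = peak_local_max(smooth, min_distance=min_dist, threshold_abs=thr,
                           exclude_border=False)
    voxel_vol = voxel_size_z * voxel_size_xy**2
    rows = []
    half_win = d_hi + 1.0
    for pz, py, px in peaks:
        z0 = max(int(pz - half_win / voxel_size_z), 0)
        z1 = min(int(pz + half_win / voxel_size_z) + 1, vol.shape[0])
        y0 = max(int(py - half_win / voxel_size_xy), 0)
        y1 = min(int(py + half_win / voxel_size_xy) + 1, vol.shape[1])
        x0 = max(int(px - half_win / voxel_size_xy), 0)
        x1 = min(int(px + half_win / voxel_size_xy) + 1, vol.shape[2])
        win = smooth[z0:z1, y0:y1, x0:x1]
        peak_val = smooth[pz, py, px]
        half = background + 0.5 * (peak_val - background)
        core = win > half
        lab = sk_label(core, connectivity=1)
        rid = lab[pz - z0, py - y0, px - x0]
        if rid == 0:
            continue
        core = lab == rid
        eq_diam = 2.0 * (3.0 * core.sum() * voxel_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        if not (d_lo - band_tol_um <= eq_diam <= d_hi + band_tol_um):
            continue
        zz, yy, xx = np.nonzero(core)
        wts = win[core] - background
        wts = np.maximum(wts, 0)
        tot = wts.sum()
        if tot <= 0:
            continue
        cz = (zz + z0) @ wts / tot * voxel_size_z
        cy = (yy + y0) @ wts / tot * voxel_size_xy
        cx = (xx + x0) @ wts / tot * voxel_size_xy
        row = dict(z_um=cz, y_um=cy, x_um=cx, diameter_um=float(eq_diam))
        if cofluor:
            core_full = np.zeros(vol.shape, dtype=bool)
            core_full[z0:z1, y0:y1, x0:x1] = core
            for name, other in cofluor.items():
                other = np.asarray(other, dtype=np.float32)
                local_bg = float(np.median(other[z0:z1, y0:y1, x0:x1][~core]))
                mean_in = float(other[core_full].mean())
                row[f"co_{name}"] = bool(mean_in > local_bg + co_factor * noise_sd)
        rows.append(row)
    cols = ["z_um", "y_um", "x_um", "diameter_um"] + [
        f"co_{n}" for n in (cofluor or {})
    ]
    df = pd.DataFrame(rows, columns=cols)
    # drop duplicate detections of one granule (closer than the band floor)
    if len(df) > 1:
        keep = np.ones(len(df), dtype=bool)
        pts = df[["z_um", "y_um", "x_um"]].to_numpy()
        order = np.argsort(-df.diameter_um.to_numpy())
        for a in range(len(order)):
            if not keep[order[a]]:
                continue
            d = np.linalg.norm(pts[order] - pts[order[a]], axis=1)
            dup = (d < d_lo) & (np.arange(len(order)) > a)
            keep[order[dup]] = False
        df = df[keep].reset_index(drop=True)
    return GranuleSet(df=df, diameter_band_um=tuple(diameter_band_um))


def classify_marker_distribution(
    granules: GranuleSet,
    marker_channel: np.ndarray,
    apical_membrane_mask: np.ndarray,
    junctional_mask: np.ndarray,
    region_mask: np.ndarray,
    background: float | None = None,
    noise_sd: float | None = None,
    k_signal: float = 3.0,
    enrich_factor: float = 1.5,
) -> str:
    """Classify a marker's distribution within one region.

    Categories: ``none`` (no signal above background), ``granular``
    (granules only), ``apical`` (apical-membrane enrichment only),
    ``transitional`` (granules plus membrane enrichment), and
    ``junctional`` (enrichment restricted to junctional signal, the
    Par3-style colocalization call).
    """
    marker = np.asarray(marker_channel, dtype=np.float32)
    if background is None:
        background = float(np.median(marker))
    if noise_sd is None:
        noise_sd = max(1.4826 * float(np.median(np.abs(marker - background))), 1e-6)
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty region mask")
    lvl = background + k_signal * noise_sd

    def _mean(mask):
        m = mask & region
        return float(marker[m].mean()) if m.any() else background

    cyto_mask = region & ~apical_membrane_mask & ~junctional_mask
    cyto = float(marker[cyto_mask].mean()) if cyto_mask.any() else background
    memb = _mean(np.asarray(apical_membrane_mask, dtype=bool))
    junc = _mean(np.asarray(junctional_mask, dtype=bool))
    memb_enriched = memb > lvl and memb > background + enrich_factor * (cyto - background + noise_sd)
    junc_enriched = junc > lvl and junc > background + enrich_factor * (cyto - background + noise_sd)
    centers = granules.centers_um if len(granules) else np.zeros((0, 3))
    has_granules = len(centers) > 0
    any_signal = has_granules or memb_enriched or junc_enriched or (
        region.any() and float(marker[region].max()) > lvl
    )
    if not any_signal:
        return "none"
    if has_granules and memb_enriched:
        return "transitional"
    if has_granules:
        return "granular"
    if memb_enriched:
        return "apical"
    if junc_enriched:
        return "junctional"
    return "none"
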