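"""End-to-end validation benchmarks against synthetic ground truth.

Each function regenerates its inputs from a seed, runs the analysis path
under test, and returns summary metrics.  They power both the acceptance
test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .generator import EmbryoParams, generate_contours, generate_static_stack
from .morphometrics import segment_epithelial_regions, summarize_clusters
from .movie import default_event_schedule, expected_outcome_counts, generate_timelapse, movie_params
from .patches import generate_granule_field, generate_lumen_phantom
from .rosettes import analyze_lumen, classify_rosette_location, detect_granules, stage_junctional_region
from .stack import VoxelStack
from .surface import InteriorMask, erode_physical, interpolate_contours, project_surface, slab_projections, split_surface
from .tracking import build_tracks, classify_emergence, count_coalescence, detect_precluster_outcomes, movie_interior, segment_movie_frames

__all__ = [
    "soft_split_conservation",
    "erosion_oracle_agreement",
    "contour_recovery_iou",
    "signal_routing",
    "morphometric_recovery",
    "rosette_recovery",
    "lumen_volume_recovery",
    "granule_metrics",
    "event_recovery",
    "slab_bookkeeping",
]


def soft_split_conservation(seed: int, n_stacks: int = 50) -> dict:
    """Max voxelwise |surface + subsurface - input| over random stacks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_stacks):
        nz = int(rng.integers(8, 65))
        ny = int(rng.integers(16, 129))
        nx = int(rng.integers(16, 129))
        data = rng.random((1, nz, ny, nx), dtype=np.float32)
        stack = VoxelStack(data, 2.0, 0.5)
        interior = InteriorMask(rng.random((nz, ny, nx)) > 0.5, 0.0, 2.0, 0.5)
        sigma = float(rng.uniform(0.0, 4.0))
        split = split_surface(stack, interior, sigma_um=sigma, mode="soft")
        err = float(np.abs(split.surface.data + split.subsurface.data - data).max())
        worst = max(worst, err)
    return {"max_conservation_error": worst, "n": n_stacks}


def _brute_force_erode(mask, depth_um, vz, vxy):
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        return mask.copy()
    scale = np.array([vz, vxy, vxy], dtype=np.float64)
    out = np.zeros_like(mask)
    bgs = bg * scale
    for i in range(0, len(fg), 256):
        chunk = fg[i:i + 256] * scale
        d2 = ((chunk[:, None, :] - bgs[None, :, :]) ** 2).sum(-1).min(1)
        keep = np.sqrt(d2) > depth_um
        out[tuple(fg[i:i + 256][keep].T)] = True
    return out


def erosion_oracle_agreement(seed: int, n_trials: int = 100, max_side: int = 32) -> dict:
    """Fraction of random-mask trials where the EDT-based erosion equals a
    brute-force all-pairs anisotropic distance computation, exactly."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        shape = tuple(int(s) for s in rng.integers(6, max_side + 1, size=3))
        mask = ndimage.binary_closing(rng.random(shape) > rng.uniform(0.3, 0.6))
        depth = float(rng.uniform(0.3, 8.0))
        got = erode_physical(mask, depth, 2.0, 1.0)
        want = _brute_force_erode(mask, depth, 2.0, 1.0)
        agree += int(np.array_equal(got, want))
    return {"agreement_rate": agree / n_trials, "n": n_trials}


def contour_recovery_iou(seed: int) -> dict:
    """Voxel IoU of the interior reconstructed from sparse jittered contours
    (stride 4, 0.5 um jitter) against the true interior, default embryo."""
    params = EmbryoParams(seed=seed)
    _, truth = generate_static_stack(params)
    contours = generate_contours(truth, stride_near=4, stride_deep=4,
                                 jitter_um=0.5, seed=seed)
    nz = params.stack_shape[0]
    filled = interpolate_contours(contours, nz, truth.interior_mask.shape[1:])
    inter = (filled & truth.interior_mask).sum()
    union = (filled | truth.interior_mask).sum()
    return {"iou": float(inter / union), "n": int(union)}


def signal_routing(seed: int, erode_um: float = 10.0, sigma_um: float = 2.0) -> dict:
    """Fraction of shell junctional intensity routed to the surface stack and
    of basal-rosette junctional intensity routed to the subsurface stack."""
    params = EmbryoParams(seed=seed)
    stack, truth = generate_static_stack(params)
    eroded = erode_physical(truth.interior_mask, erode_um,
                            params.voxel_size_z, params.voxel_size_xy)
    interior = InteriorMask(eroded, erode_um, params.voxel_size_z, params.voxel_size_xy)
    split = split_surface(stack, interior, sigma_um=sigma_um, mode="soft")
    ji = stack.channel_names.index("junctional")
    total = stack.data[ji]
    surf = split.surface.data[ji]
    sub = split.subsurface.data[ji]
    shell = truth.shell_junction_mask
    deep = truth.basal_junction_mask
    return {
        "shell_to_surface": float(surf[shell].sum() / total[shell].sum()),
        "rosette_to_subsurface": float(sub[deep].sum() / total[deep].sum()),
        "n": int(shell.sum() + deep.sum()),
    }


def morphometric_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Cluster count/area/emerged-fraction recovery over basal-rosette
    embryos at default SNR."""
    exact = 0
    max_area_err = 0.0
    max_frac_err = 0.0
    for i in range(n_seeds):
        params = EmbryoParams(seed=seed + i, rosette_location_probs=(1.0, 0.0, 0.0))
        stack, truth = generate_static_stack(params)
        eroded = erode_physical(truth.interior_mask, 10.0,
                                params.voxel_size_z, params.voxel_size_xy)
        interior = InteriorMask(eroded, 10.0, params.voxel_size_z,
                                params.voxel_size_xy)
        split = split_surface(stack, interior, sigma_um=2.0, mode="soft")
        ji = stack.channel_names.index("junctional")
        table = segment_epithelial_regions(
            project_surface(split, "surface")[ji],
            project_surface(split, "subsurface")[ji],
            params.voxel_size_xy)
        emerged = table.df[table.df.emerged]
        unemerged = table.df[~table.df.emerged]
        if len(emerged) == params.n_emerged_clusters and len(unemerged) == params.n_rosettes:
            exact += 1
        centroids = {}
        for cid in truth.emerged_cluster_areas_um2:
            ys, xs = np.nonzero(truth.emerged_cluster_labels == cid)
            centroids[cid] = (ys.mean() * params.voxel_size_xy,
                              xs.mean() * params.voxel_size_xy)
        for _, row in emerged.iterrows():
            cid = min(centroids, key=lambda c: (centroids[c][0] - row.centroid_y_um) ** 2
                      + (centroids[c][1] - row.centroid_x_um) ** 2)
            gt = truth.emerged_cluster_areas_um2[cid]
            max_area_err = max(max_area_err, abs(row.area_um2 - gt) / gt)
        s = summarize_clusters(table)
        max_frac_err = max(max_frac_err,
                           abs(s["emerged_fraction"] - truth.emerged_fraction()))
    return {
        "count_exact_fraction": exact / n_seeds,
        "max_area_rel_error": max_area_err,
        "max_emerged_fraction_error": max_frac_err,
        "n": n_seeds,
    }


def rosette_recovery(seed: int, n_embryos: int = 6) -> dict:
    """Location-class, stage, and lumen-presence agreement with planted
    labels at zero noise."""
    loc_ok = stage_ok = lum_ok = total = 0
    for i in range(n_embryos):
        params = EmbryoParams(seed=seed + i, noise_sd=0.0)
        stack, truth = generate_static_stack(params)
        apical = stack.channel("apical")
        junc = stack.channel("junctional")
        mask = apical > params.background_level + 0.5 * params.signal_level
        vz, vxy = params.voxel_size_z, params.voxel_size_xy
        for r in truth.rosettes:
            total += 1
            cls = classify_rosette_location(
                r.center_um, mask, truth.surface_height_map, truth.shell_mask,
                vz, vxy, params.mesoderm_cell_diameter)
            loc_ok += int(cls == r.location_class)
            cz, cy, cx = r.center_um
            kc = int(round(cz / vz))
            iy, ix = int(round(cy / vxy)), int(round(cx / vxy))
            w = 20
            patch = junc[kc, iy - w: iy + w, ix - w: ix + w].copy()
            yy, xx = np.mgrid[-w:w, -w:w]
            patch[(yy**2 + xx**2) > (8.0 / vxy) ** 2] = 0.0
            stage_ok += int(stage_junctional_region(patch, r.n_cells, vxy) == r.stage)
            lum = analyze_lumen(apical, r.center_um, vz, vxy)
            lum_ok += int(lum.has_lumen == r.has_lumen)
    return {
        "location_accuracy": loc_ok / total,
        "stage_accuracy": stage_ok / total,
        "lumen_presence_accuracy": lum_ok / total,
        "n": total,
    }


def lumen_volume_recovery(seed: int = 0) -> dict:
    """Worst relative error of measured lumen volumes against the analytic
    sphere/tube values, radii >= 3 voxels."""
    worst = 0.0
    cases = [("sphere", 3.0, None), ("sphere", 4.0, None), ("sphere", 5.0, None),
             ("tube", 3.0, 20.0), ("tube", 4.0, 24.0)]
    for kind, r, length in cases:
        stack, truth = generate_lumen_phantom(kind, r, length_um=length or 20.0,
                                              voxel_size_z=1.0, voxel_size_xy=0.5)
        lum = analyze_lumen(stack.data[0], truth["center_um"], 1.0, 0.5)
        if not lum.has_lumen:
            return {"max_volume_rel_error": 1.0, "n": len(cases)}
        err = abs(lum.volume_um3 - truth["analytic_volume_um3"]) / truth["analytic_volume_um3"]
        worst = max(worst, err)
        if kind == "tube" and not lum.elongated:
            worst = max(worst, 1.0)
    return {"max_volume_rel_error": worst, "n": len(cases)}


def granule_metrics(seed: int, n_seeds: int = 20) -> dict:
    """Detection precision/recall and worst matched-center error for planted
    1.5 um granules at SNR 10."""
    tp = fp = fn = 0
    worst_center = 0.0
    for i in range(n_seeds):
        stack, truth = generate_granule_field(n_granules=12, diameter_um=1.5,
                                              snr=10.0, seed=seed + i)
        gs = detect_granules(stack.channel("granule"), stack.voxel_size_z,
                             stack.voxel_size_xy, background=0.1, noise_sd=0.02)
        det = gs.centers_um
        used = set()
        for p in truth["centers_um"]:
            if len(det) == 0:
                fn += 1
                continue
            d = np.linalg.norm(det - p, axis=1)
            j = int(np.argmin(d))
            if d[j] <= 1.0 and j not in used:
                tp += 1
                used.add(j)
                worst_center = max(worst_center, float(d[j]))
            else:
                fn += 1
        fp += len(det) - len(used)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"precision": precision, "recall": recall,
            "max_center_error_um": worst_center, "n": n_seeds}


def event_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of synthetic movies whose coalescence count, pre-cluster
    outcome counts, and emergence classes match the planted schedule."""
    coal_ok = outcome_ok = emerge_ok = 0
    for i in range(n_seeds):
        params = movie_params(seed=seed + i)
        schedule, roster = default_event_schedule(params)
        frames, truth = generate_timelapse(params, schedule, roster)
        interior = movie_interior(truth.surface_height_map, frames[0], 10.0)
        tables = segment_movie_frames(frames, interior=interior)
        graph = build_tracks(tables)
        n_coal, recs = count_coalescence(graph)
        sched_frames = sorted(e.frame for e in schedule if e.kind == "coalescence")
        coal_ok += int(n_coal == len(sched_frames) and
                       sorted(r["frame"] for r in recs) == sched_frames)
        got = detect_precluster_outcomes(graph).counts()
        expected = expected_outcome_counts(schedule, roster)
        outcome_ok += int(all(got.get(k, 0) == v for k, v in expected.items()))
        em = {}
        for tid in graph.tracks:
            c = classify_emergence(graph, tid)
            em[c] = em.get(c, 0) + 1
        n_emerge = sum(1 for e in schedule if e.kind == "emergence")
        emerge_ok += int(em.get("emerges", 0) == n_emerge
                         and em.get("remains_emerged", 0) == 1)
    return {
        "coalescence_exact_fraction": coal_ok / n_seeds,
        "outcome_exact_fraction": outcome_ok / n_seeds,
        "emergence_exact_fraction": emerge_ok / n_seeds,
        "n": n_seeds,
    }


def slab_bookkeeping() -> dict:
    """Slab count for 5 um slabs over 50 um and the slab index receiving a
    point source planted 23 um below the reference surface."""
    stack = VoxelStack(np.zeros((1, 40, 8, 8), dtype=np.float32), 2.0, 0.5)
    ref = np.full((8, 8), 1.0)
    stack.data[0, 12, 3, 3] = 1.0  # z = 24 um, depth 23 um below the surface
    slabs = slab_projections(stack, 5.0, 50.0, ref)
    hits = [k for k, s in enumerate(slabs) if s.any()]
    return {"n_slabs": len(slabs),
            "point_source_slab": hits[0] if len(hits) == 1 else -1,
            "n": len(slabs)}
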