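"""Surface extraction on a curved synthetic embryo.

Sparse hand-drawing-like outline contours are interpolated into a filled
volume, eroded by a physical depth, blurred into a weight field, and used
to split the stack into surface and subsurface signal.  The printed
fractions show how cleanly the curved endoderm shell separates from the
deeper rosettes.
"""

import rosettex as rx
from rosettex.surface import InteriorMask

params = rx.EmbryoParams(seed=7, rosette_location_probs=(1.0, 0.0, 0.0))
stack, truth = rx.generate_static_stack(params)

# sparse outlines: every 4th slice near the curved surface, jittered 0.5 um
contours = rx.generate_contours(truth, stride_near=4, stride_deep=10,
                                jitter_um=0.5, seed=7)
nz, ny, nx = stack.shape_zyx
filled = rx.interpolate_contours(contours, nz, (ny, nx))
iou = (filled & truth.interior_mask).sum() / (filled | truth.interior_mask).sum()
print(f"annotated slices: {len(contours.annotated_slices)} of {nz}")
print(f"interior reconstruction IoU vs ground truth: {iou:.4f}")

eroded = rx.erode_physical(filled, 10.0, params.voxel_size_z, params.voxel_size_xy)
interior = InteriorMask(eroded, 10.0, params.voxel_size_z, params.voxel_size_xy)
split = rx.split_surface(stack, interior, sigma_um=2.0, mode="soft")

ji = stack.channel_names.index("junctional")
total = stack.data[ji]
shell = truth.shell_junction_mask
deep = truth.basal_junction_mask
print(f"shell junctional intensity routed to surface:    "
      f"{split.surface.data[ji][shell].sum() / total[shell].sum():.4f}")
print(f"rosette junctional intensity routed to subsurface: "
      f"{split.subsurface.data[ji][deep].sum() / total[deep].sum():.4f}")
# Soft mode conserves signal exactly, so these two stacks sum back to the
# original; values near 1.0 mean the 10 um erosion + 2 um blur cleanly
# separates the curved shell from structures 20+ um below it.

slabs = rx.slab_projections(stack, 5.0, 50.0, truth.surface_height_map, channel=ji)
print(f"depth-resolved series: {len(slabs)} slabs of 5 um below the curved surface")
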