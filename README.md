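# rosettex

Surface extraction and rosette morphometrics for confocal z-stacks of
curved embryos, with a fully ground-truthed synthetic embryo generator.

## The problem

During gastrulation, mouse axial mesoderm cells undergo a
mesenchymal–epithelial transition: below the squamous surface endoderm
they assemble into multicellular **rosettes** — groups of cells elongated
toward a shared, membrane-rich central domain — that acquire junctional
(ZO-1) and apical (aPKC, Pals1) polarity, open a central lumen, coalesce,
and radially intercalate into the surface epithelium to build the node and
notochordal plate. Quantifying this process from 3D confocal stacks
requires separating the *curved* embryo surface from subsurface signal,
measuring the emerged epithelium, classifying rosettes in 3D, and tracking
junctional regions through time-lapse movies.

`rosettex` implements that image-analysis methodology as a tested,
reusable Python library:

* **Surface extraction** — sparse per-slice outline contours are
  interpolated (linear interpolation of per-slice signed distance fields),
  eroded by a physical depth *d* (default 10 µm, anisotropy-aware
  Euclidean distance), Gaussian-blurred into a weight field
  *w* ∈ [0, 1] (σ = 2 µm), and used to split the stack:
  `subsurface = I·w`, `surface = I − I·w` (signal-conserving), with a
  clamped-subtraction mode replicating classical image-calculator
  arithmetic. Maximum-intensity projections, 5-µm depth slabs below the
  curved surface, and calibrated orthogonal reslices come out of the same
  module.
* **Morphometrics** — the junctional lattice of the surface projection is
  binarised; enclosed apices below a small-apex threshold (default
  50 µm²) mark emerged axial-mesoderm regions; subsurface projections give
  unemerged regions. Outputs: cluster counts, areas, emerged fraction
  `A_emerged / (A_emerged + A_unemerged)`, and per-cluster mean cell area.
* **Rosette analysis** — location classes
  (`basal` / `endoderm_contacting` / `partially_emerged`, evaluated in
  that precedence), junctional staging
  (`spot` / `edge` / `early_rosette` / `late_rosette`), lumen detection and
  volumetry (enclosed negative space; spheres ≈ 4⁄3πr³, tunnels ≈ πr²L,
  elongated when principal extents ratio > 2), 1–2 µm cytoplasmic granule
  detection, and apical-marker distribution calls
  (`none` / `granular` / `transitional` / `apical` / `junctional`).
* **Tracking** — junctional regions in 12-min-interval movies are linked
  by mask overlap (IoU ≥ 0.25, 1-frame gap closing) and scored with the
  epithelial event taxonomy: pre-cluster outcomes (expansion /
  persistence / disassembly), coalescence events, emergence classes over a
  7-h window, and post-emergence apical-area time series.
* **Synthetic embryos** — `generate_static_stack` and
  `generate_timelapse` render calibrated multi-channel stacks (membrane,
  junctional, nuclear, apical, granule) of a spherical-cap embryo with a
  polygonal endoderm shell, emerged clusters, staged rosettes with lumens,
  granules, and scheduled movie events — each with a complete
  `GroundTruth` twin, so every analysis step can be validated end to end.

## Worked example

```bash
python examples/02_surface_extraction.py
```

prints (seed 7):

```
annotated slices: 12 of 64
interior reconstruction IoU vs ground truth: 0.9928
shell junctional intensity routed to surface:    1.0000
rosette junctional intensity routed to subsurface: 1.0000
depth-resolved series: 10 slabs of 5 um below the curved surface
```

The IoU line says that outlines drawn on every 4th slice (with 0.5 µm
hand-drawing jitter) reconstruct the embryo interior almost perfectly; the
routing lines say that after 10 µm erosion and 2 µm blur, the endoderm
shell's junctional signal ends up in the surface stack while basal-rosette
signal ends up in the subsurface stack — the separation the method exists
to achieve. `examples/` contains one script per capability (simulation,
extraction, morphometrics, rosettes, tracking, full pipeline), and the
`rosettex` command exposes the same stages
(`simulate`, `extract-surface`, `quantify`, `track`, `run-all`).

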