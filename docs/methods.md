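# Methods

This note documents the models, parameters, and numerical choices behind
`rosettex`, and what validation on synthetic data does and does not show.

## Surface extraction

The embryo surface is separated from subsurface signal in four steps.

**Contour interpolation.** Embryo outlines are annotated as closed simple
polygons on a sparse subset of z slices (0-based pixel coordinates,
integer coordinates at pixel centers). Unannotated slices are filled by
linear interpolation of per-slice signed distance fields between the
bracketing annotations; slices outside the annotated range copy the
nearest annotation. Signed distances are computed exactly to the polygon
boundary (sub-pixel, via shapely) rather than from a pixel EDT — a pixel
EDT measures to pixel centers, which biases the interpolated boundary by
up to half a pixel. The interpolated mask is `sdf ≥ 0`, so boundary
pixels match the rasterisation of the annotated polygons (pixel center
inside or on the polygon). Explicitly empty slices carry a large negative
constant; interpolation against them erodes the shape toward nothing
within one annotation gap, which loses at most the one or two smallest
distal slices of a spherical cap. This scheme reproduces ROI-style
interpolation on convex outlines and preserves nesting: if contour A lies
inside contour B, every interpolated slice lies between them (linear
interpolation of pointwise-ordered SDFs preserves order).

**Physical erosion.** `erode_physical` keeps exactly the voxels whose
Euclidean distance to the mask complement, measured in micrometers
between voxel centers with anisotropic sampling `(Δz, Δxy, Δxy)`, exceeds
the depth *d*. Default *d* = 10 µm, the midpoint of the 9–12 µm range the
procedure was designed around. Erosion is 3D by default; a per-slice 2D
mode exists because slice-wise tooling is common. A mask with no
background is returned unchanged (all distances infinite). The EDT-based
implementation is checked against a brute-force all-pairs distance
computation on randomized masks up to 32³ — exact agreement, not
approximate.

**Splitting.** The interior indicator is blurred with an
anisotropy-aware Gaussian (σ in µm; default 2 µm, roughly one
voxel-to-membrane transition width — the blur radius is not a reported
value and is exposed as a parameter). In the default `soft` mode,
`subsurface = I·w` and `surface = I − I·w`, so the two stacks sum to the
input *exactly* (the surface stack is computed as the residual, which
makes conservation hold in floating point by construction).
`fiji_subtract` mode instead computes `max(0, I − w)` and
`max(0, I − (1 − w))`, replicating clamped 8-bit image subtraction in
fractional units; with σ = 0 it partitions every nonzero voxel into
exactly one output. Soft mode is the default because it conserves
signal; the clamped mode exists for fidelity to the published arithmetic.

**Projections and reslices.** Surface/subsurface maximum-intensity
projections are per-(y, x) maxima over z. `slab_projections` bins voxels
by depth *below the per-column surface height map* (half-open 5-µm bins
over the distal 50 µm by default) rather than absolute z, because the
quantity of interest tracks the curved surface. `reslice` permutes axes
to transverse (xz) or sagittal (yz) view and resamples the former z axis
to the in-plane pixel size with nearest-neighbor interpolation, updating
calibration; on isotropic stacks reslicing twice is the identity up to
axis permutation.

## Morphometrics

Emerged axial mesoderm is identified by its small apical domains. The
surface projection's junctional lattice is binarised (iterated Otsu: if a
threshold marks more than 30 % of pixels — impossible for sparse
junctional signal — Otsu is re-run on the upper population; this guards
against the classic Otsu failure on images whose foreground fraction is
tiny). Enclosed apices (4-connected complement components not touching
the image border) are measured; apices below the small-apex threshold
(default 50 µm², configurable — an operationalisation of "smaller apical
surfaces", not a measured value) are unioned and morphologically closed
across the 1-px junction lines into candidate regions. A region is kept
when its median apex area stays below the threshold. Region area adds
half of the junction line bordering the region (an annotator's outline
runs through the middle of the shared boundary junction). Solid
junctional domains without enclosed apices (nascent emerged regions) are
picked up by a solidity-filtered fallback that cannot swallow the
extended lattice network. Cell counts exclude apices below 2 µm²
(constricted perimeter cells; no numeric cutoff was reported, so this is
a package default). Emerged fraction is emerged area over total
epithelial area and is invariant to pixel size within rasterisation
error.

## Rosette analysis

Rosette centers are inputs (annotations or ground truth); automatic
center detection is out of scope, mirroring manual center identification
by junctional/F-actin enrichment.

**Location.** Precedence `partially_emerged → endoderm_contacting →
basal`. The classifier first restricts the apical mask to components
within 12 µm of the given center (so whole-stack masks can be passed).
Partially emerged: any apical voxel within one z-step of the surface
height map (the central domain breaches the surface). Endoderm
contact: 26-connected voxel adjacency between the apical domain and the
endoderm mask — "visible contact" has no stated distance, so adjacency is
the operational choice. Everything else is basal; the one-cell-diameter
rule (default 10 µm, a free parameter, not a reported value) is the
biological definition whose complement the two contact tests implement.

**Lumens.** A lumen is a connected pocket of sub-threshold intensity
enclosed by apical signal, not background-connected to the exterior, of
at least 5 µm³, nearest the rosette center. Enclosure is evaluated in 3D
by default; a 2D mode additionally requires enclosure within at least one
transverse (xz) plane, matching the plane-wise scoring convention. Volume
is voxel count × voxel volume; the transverse area is the largest xz
cross-section; elongation is a > 2 ratio of principal extents
(square-root eigenvalue ratio of the voxel-coordinate covariance).
Volumes are accurate to ~5 % for radii ≥ 3 voxels and degrade below that
(a 2.5 µm sphere at 2 µm z-steps spans barely three slices); the
validation suite therefore holds only radii ≥ 3 voxels to the 10 % band.

**Staging.** Spot: max Feret diameter < 1.5 µm. Late rosette: the
binarised patch encloses a background gap ≥ 3 µm² (webbed/reticular
pattern). Early rosette: no gap, at a vertex of ≥ 5 cells (the vertex
count is an input, from annotation or ground truth). Edge: otherwise.
The Feret and hole thresholds are operationalisations, configurable.

**Granules.** Matched-filter detection: smooth at 0.3 µm (a light filter
— heavier smoothing costs recall on 1-µm puncta), find local maxima above
`background + 4·noise_sd`, refine each to an intensity-weighted subvoxel
centroid, and keep candidates whose half-maximum equivalent diameter lies
in the 1–2 µm band (±0.75 µm slack for smoothing inflation).
Co-positivity for another channel requires its in-blob mean to exceed the
local background by twice the noise floor.

**Marker distributions.** `none` (no signal above background + 3σ),
`granular` (granules only), `apical` (apical-membrane enrichment only),
`transitional` (both), `junctional` (enrichment confined to junctional
signal — the Par3-style colocalization call). Enrichment means exceeding
the cytoplasmic mean by a 1.5× margin above background.

## Tracking

Regions segmented on per-frame surface and subsurface projections are
linked greedily by mask IoU (default 0.25) to the next frame, with
1-frame gap closing; many-to-one links are merge nodes. Tracking was
manual in the workflow this automates, so linking is an
operationalisation with the synthetic generator as arbiter. A region is
a `cluster` when it encloses a background hole ≥ 3 µm² (a visible apical
domain) and a `pre_cluster` otherwise. Each pre-cluster track gets
exactly one outcome: `expansion` at its first pre-cluster→cluster
transition, `disassembly` if it ends before the final frame without
merging into another region, `persistence` otherwise; for real data a
border-touch flag can suppress disassembly calls at the image edge
(synthetic movies cannot lose regions to the field of view, and
sufficiently deep stacks rule out z-exit). Coalescence counts one event
per merge node regardless of arity and records the participant states at
the merge frame. Emergence classes use the window endpoints (default
frames 0 and 35 at 12 min ≈ 7 h): below at both → `does_not_emerge`, on
at both → `remains_emerged`, below (or first detection) then on →
`emerges`. Only monotone progress counts: a track that emerges then
submerges by the endpoint is `does_not_emerge`, so the classification is
deliberately asymmetric under time reversal. Apical-area series sample
each cell at fixed minutes after first visibility (default 12, 36,
180 min; t = 0 is the frame before the apical domain is discernible);
missing samples are flagged, never interpolated.

## Synthetic embryos

The generator renders the distal cap of an embryo mounted distal side
down: axis order (channel, z, y, x), z index 0 distal-most, intensities
fractional in [0, 1]. The surface is a spherical-cap height map (default
cap radius 400 µm over a 280 × 192 µm field; 64 × 2 µm z-steps at 0.5 µm
pixels — a 128 µm stack within the 70–200 µm range typical of whole-embryo
confocal imaging). The squamous endoderm is a 5 µm shell whose polygonal
cell outlines come from a jittered hexagonal tessellation (20 µm cells).
Emerged clusters convert whole endoderm cells into fields of 5 µm apices
(≈ 21 µm², matching measured emerged apical areas of ~21 µm²); the
mesoderm assignment is capped at 0.8 apex diameters so edge apices stay
small instead of bulging toward the sparser endoderm centers — without
the cap, unweighted Voronoi produces spurious > 50 µm² edge apices.
Rosettes are planted with a location class (default mix 0.5 / 0.3 / 0.2
basal / contacting / partially emerged, the early-stage-weighted mix),
a stage (60 / 40 early / late; a rosette that draws a lumen is rendered
late, since an expanded cavity implies maturation), an apical domain
(solid focus, or a wall of ≥ max(1.5 µm, one z-step) thickness around a
spherical or y-axis tunnel lumen — a thinner wall can vanish between
z-samples and spuriously open the lumen), a stamped 2D junctional stage
pattern at the equatorial plane, radially elongated sector cells, and
~1 granule (1–2 µm) per cell in the apical cytoplasm. Partially emerged
rosettes clear the endoderm lattice over an emergence mouth and, when
they carry a lumen, reach the surface through a solid apical neck so the
central domain is open to the exterior while the lumen stays enclosed.
Noise is additive Gaussian with Poisson-like scaling
`sd = noise_sd·sqrt(I/background)` (default noise_sd 0.02, background
0.1, signal 0.8). Movies render scheduled events on a flatter cap:
solid 3 µm pre-cluster disks, annular clusters, approach-and-merge
coalescences, depth-switch emergences, and disappearance disassemblies,
12 min per frame, 36 frames.

All randomness derives from `SeedSequence(seed).spawn(8)` with a
documented child order (tessellation, clusters, rosettes, lumens,
granules, noise, movie schedule, movie noise), so seed-replay oracles can
re-derive, e.g., the lumen Bernoulli sequence independently. Identical
parameters and seed give bit-identical stacks and ground truth.

**What the generator does not emulate:** optical point-spread functions,
spectral bleed-through, photobleaching, embryo growth or deformation,
segmentation-hostile texture, and annotation disagreement beyond vertex
jitter. Passing tests therefore demonstrate that the implementation
measures what it claims on geometrically faithful, high-contrast data;
they do not certify performance on low-SNR or optically aberrated
acquisitions, where thresholds and the linking IoU may need retuning.

## Validation problem sizes

The validation suite uses 50 random stacks (≤ 128 × 128 × 64) for
conservation, 100 random masks ≤ 32³ for the erosion oracle, one default
embryo each for contour recovery and signal routing, 20 embryos for
morphometric recovery, 6 zero-noise embryos (48 rosettes) plus 5 lumen
phantoms for classification and volumetry, 20 granule fields, and 20
scheduled 36-frame movies — sizes chosen so the whole suite validates
every pathway in a few minutes on one core. Signal routing is measured
on the endoderm shell and on basal rosettes: partially emerged and
endoderm-contacting rosettes are contiguous with the surface by
construction, so their signal legitimately straddles the split.
Morphometric recovery uses basal-only rosette placement because a
partially emerged rosette is itself a (tiny) emerged region, which would
make "planted emerged cluster count" ill-defined.

## Known limitations

* Rosette centers and per-rosette vertex counts are inputs; there is no
  automatic rosette detector.
* Lumen volumetry is unreliable below ~3 voxel radii (documented above).
* Tracking operates on 2D projections, not volumetrically; simultaneous
  events closer than the linking radius could be conflated on real data.
* The clamped `fiji_subtract` mode does not conserve signal; quantitative
  work should use the default soft split.
* ImageJ ROI archives are not parsed; contours are exchanged as JSON.
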