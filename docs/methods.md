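# Methods

This note documents the models, algorithms, parameter choices, and
validation design behind `histoatlas`, and what the synthetic-phantom
results do and do not demonstrate about real serial-section data.

## Problem setting

A brain is sectioned coronally at 50 µm on a microtome; before each cut
the block surface is photographed ("block-face image"). Alternate
sections (every 100 µm) are immunostained and imaged at high resolution.
Sections deform and land on slides in arbitrary pose, so the stained
images must be restored into block-face coordinates before 2D
annotations can be stacked into a 3D reference volume. The atlas target
is a 10 µm isotropic label volume with one region id per voxel, a
watertight non-overlapping mesh per region, and region-wise counts and
densities of total (DAPI), neuronal (NeuN), and PV-positive cells.

## Shading correction

Widefield fluorescence images carry a smooth multiplicative
illumination profile ("flat field"). The estimator draws `tile_count`
(default 20) random tiles (default 2040 px square) across the section
stack, keeps them at their global positions, and takes the per-pixel
median across covering tiles: tissue content varies between tiles while
illumination does not, so the median approximates illumination × mean
content. Because random crops rarely cover image corners, the median is
then projected onto a 2D polynomial surface of total degree 4 — the
natural parametric model of slowly varying illumination, and the only
smoother that extrapolates sensibly into uncovered corners — plus a
gentle residual low-pass (Gaussian, 1/16 of the image's smaller
dimension) of the covered-pixel residuals. The field is normalized to
mean 1; correction divides by it and (by default) rescales to the
input's global mean so correction commutes exactly with global
intensity scaling. A dark-field offset term is omitted: fluorescence
backgrounds are near zero.

On phantoms with a known polynomial × vignette field the estimator
reaches correlation ≥ 0.999 and RMS error below 1%.

## Tissue masks and part correspondence

Tissue masks come from an adaptive local-mean threshold (window 1/8 of
the smaller image dimension, offset 5% of the robust intensity range, a
background floor at 25% of that range), morphological closing (disk
radius 2), hole filling, and a minimum-area filter; disjoint parts are
returned largest-first. Correspondence between histology and block-face
parts is a minimum-cost linear assignment on normalized centroid
distance plus relative area mismatch (the published workflow determined
correspondence manually; the assignment automates the common case).

## Rigid block-face registration

The rigid stage registers binary masks, not intensities: block-face
photographs and fluorescence images have incomparable contrast, but
their tissue outlines agree. The transform is parameterized as rotation
about the moving mask's centroid (decorrelating rotation from
translation) plus translation, with an optional flip hypothesis search
(none/horizontal/vertical/flip+180°; flips are rare mounting errors
that the published workflow fixed manually). The metric is soft Dice
between Gaussian-smoothed (σ = 1.5 px) masks under bilinear warping,
optimized coarse-to-fine over downsampling factors 8/4/2/1 with Powell
search at each level.

Rotation and translation trade off along a shallow, curved valley whose
depth near the optimum is ~1e-4 in Dice, so generic descent stalls up
to a degree away from the optimum. The finest level therefore ends with
an angle-marginalized scan — translation re-optimized at each of a grid
of candidate angles over ±3° — followed by a Nelder–Mead polish. With
articulated section outlines this recovers simulated perturbations to
≈0.05° and ≈0.05 px; the residual floor is set by mask discretization,
which is why section images should be sampled finer than the target
atlas grid (real data: 0.65 µm pixels vs a 10 µm atlas; phantoms render
sections at spacing/2 by default).

## Deformable refinement and region interpolation

Nonlinear steps use SimpleITK's diffeomorphic demons (displacement
fields smoothed at σ = 1.5 px, symmetric image forces, multiscale
4/2/1), which exponentiates a velocity update and keeps the Jacobian
determinant positive; fields are inverted with the fixed-point
displacement-field inverter, and a non-positive Jacobian raises.

Between consecutive annotated sections each region is interpolated
independently: the demons field is computed between the two sections'
signed-distance transforms (clipped at ±20 px so far-field values
cannot dominate), and intermediate `i` of `n` warps the first mask by
the field scaled to `i/(n+1)`, thresholded at 0.5. A region present on
only one side morphs to or from extinction through level sets of its
distance transform, giving strictly tapering areas. A 100 µm section
interval over a 10 µm target grid inserts 9 intermediates per gap, so
the output grid hits every annotated section exactly.

## Overlap resolution

Independently interpolated regions overlap. Voxels claimed by two or
more regions are unassigned; regions then grow back into the unassigned
claimed union at equal speed, implemented as best-first (Dijkstra-style)
competitive growth under 6-connectivity with priority equal to the
Euclidean distance from the region's post-unassignment support; exact
ties go to the lower region id. Growth never leaves the original
claimed union, so the outer tissue surface cannot expand. On random
overlapping claim volumes this agrees with per-voxel nearest-support
brute force on ≥ 99% of contested voxels (the residue is voxels whose
Euclidean-nearest region cannot reach them through the gap).

## Meshing, smoothing, repair

Region surfaces are marching cubes at iso-level 0.5 on the zero-padded
binary mask (hence always closed), with vertices in µm. Smoothing is
the umbrella operator `v ← v + λ(mean(neighbors) − v)` with λ = 1e-4
and 100 iterations — deliberately gentle, removing sectioning staircase
artifacts without measurable shrinkage. If smoothed surfaces overlap at
grid resolution, repair alternates: voxelize meshes (a z-column
ray-parity rasterizer; rays carry distinct irrational sub-voxel offsets
per axis so lattice-aligned and diagonal mesh edges are never hit
exactly), unassign multiply-claimed voxels, refill competitively,
re-extract, re-smooth with λ halved (`decay` = 0.5, unspecified in the
source workflow and configurable), up to `max_cycles` = 10.

## Cell atlas

2D detections (pixel coordinates per section, markers total/neuron/PV)
map through each section's transform chain into reference µm; z is the
section position (plus half the section thickness if requested). Region
assignment is the label at `floor(position/spacing)`; border positions
clamp and are flagged. Counts aggregate up the ontology by summation
over descendant leaves, exactly conserving totals.

Because detection runs on 50 µm widefield sections, 2D counts
undercount 3D content. The calibration factor per marker is the mean of
per-patch 3D/2D count ratios over volumetric confocal patches, with
SEM = sd/√n; with no patches supplied the reference ratios 1.730 (DAPI)
and 1.864 (NeuN) are used, and PV (large, sparse somata) is treated as
exhaustively detected (ratio 1). Densities are reported per
(100 µm)³ = 10⁶ µm³ — the only reading under which realistic neuronal
densities (tens to low hundreds per unit) arise. Composition ratios
(neuron/total, PV/neuron) use calibrated counts by default and are
reported unclipped with a warning flag above 1.

Detection evaluation matches predicted to ground-truth instance masks
one-to-one, greedily by descending IoU at threshold 0.5; matched
predictions are TP, the rest FP, unmatched ground truths FN. Greedy
matching can differ from exhaustive maximum matching only on chains of
mutually overlapping instances, which compact cell-like masks
essentially never form; the test suite checks equality against a
brute-force enumerator on random instance sets.

## Ontology

The region tree stores an explicit per-node `level` (0–4). Root
divisions (gray matter, white matter, ventricular system) are level 0;
a node's level may jump more than one tier below its parent, because
anatomical groupings do not all live at the same depth — cerebellum,
fiber tracts, and the ventricular system act as major structures
directly under their divisions. All 13 coarse-annotation major
structures therefore share level 2 and are queryable as such. The basal
ganglia are kept as a single functional level-3 grouping under gray
matter holding the seven motor-circuit nuclei (caudate, putamen, GPe,
GPi, STh, SNR, SNC) as level-4 leaves, so the subtree query is well
defined inside a tree even though the nuclei anatomically span
striatum, pallidum, and midbrain. Aggregation to level k cuts the tree
at k (each leaf contributes to its deepest ancestor-or-self at
level ≤ k), the only definition that conserves mass at every k when
leaves sit at heterogeneous depths. Colors must be unique except along
a single root-to-leaf path. On disk: ITK-SNAP `.label` text plus a JSON
sidecar for hierarchy and acronyms (the `.label` dialect has no parent
column).

## Synthetic phantoms: what they emulate

`make_phantom` builds nested shells of a superellipsoid: flattened
along the cutting axis (z-exponent 6, trimmed flat at 92% of the z
semi-axis like a trimmed tissue block), with an in-plane outline
modulated by 2nd/3rd-harmonic lobes (amplitudes 0.13/0.08) and a deep
narrow notch (depth 0.30, σ = 0.06 rad) standing in for the midline
fissure — every coronal outline then pins in-plane orientation, as real
section outlines do. Shells share the full z-extent (regions span the
whole section series, as real structures span many sections); remaining
regions are z-elongated ellipsoid blobs. All shapes are analytic, so
any plane can be re-rasterized at any pixel size; sections render at
spacing/supersample (default 2) pixels. Section corruptions: per-slice
rigid perturbations (defaults ±7°, ±12 px) logged as truth, a shared
polynomial × vignette shading field, optical blur (σ = 0.6 px), and
Gaussian noise (σ = 0.02 on ~0.5 contrast). Cell clouds are homogeneous
Poisson per region with nested thinning (PV ⊆ neuron ⊆ total; default
densities 115–215 total cells per (100 µm)³ by region, neuron fractions
0.46–0.70, PV 8% of neurons); 2D slab detections take cells in each
50 µm slab (half-open intervals, no double counting) thinned at
1/1.730 (total) and 1/1.864 (neuron).

Default problem sizes — a 5-region 128³ phantom at 10 µm, ten tissue
sections — were chosen so the full round trip runs in a few minutes on
one CPU while every stage still operates far from degenerate sizes.

What passing phantom tests shows: the geometry chain (masking,
registration, interpolation, conflict resolution, meshing, counting) is
correct and self-consistent at realistic noise and perturbation levels.
What it does not show: robustness to real histology — tears, folds,
debris, staining variation, true nonlinear section distortion, and
detection errors are not simulated; block-face/histology contrast
differences are idealized; and the phantom's smooth analytic shapes are
easier to interpolate than real neuroanatomy.

## Numerical conventions

Arrays are indexed `[z, y, x]` with z the cutting axis; physical
coordinates and meshes are `(x, y, z)` µm. A voxel with index i spans
`[i, i+1)` voxel units (cells are assigned by floor); analytic
rasterization samples voxel centers at `i + 0.5`. Supersampled section
pixels tile volume voxels exactly (`supersample²` pixels per voxel),
and reconstruction collapses back by block majority, ties to the
smaller id. Degenerate inputs raise rather than guess: empty masks in
rigid registration, folding deformation fields, absent mesh regions,
zero-volume regions with nonzero counts.

## Known limitations

- The rigid stage assumes the section outline constrains orientation;
  near-circular isolated parts are genuinely ambiguous.
- Interpolation cannot reconstruct structure that appears and vanishes
  entirely between two 100 µm sections; extinction morphs are a
  principled guess, not a recovery.
- Overlap resolution matches nearest-support assignment only up to
  geodesic reachability through the contested gap.
- The repair loop assumes smoothing-induced overlaps are thin; heavily
  interpenetrating meshes would converge slowly or hit `max_cycles`.
- Calibration assumes the 2D undercount is binomial and
  region-independent, mirroring the constant-ratio observation it
  implements.
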