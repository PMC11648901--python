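# histoatlas

Serial-section histology → 3D brain atlas reconstruction.

Building a cellular-resolution reference atlas from a sectioned,
immunostained brain means solving a chain of geometric problems: each
50 µm coronal section is photographed on the block face before cutting
(the distortion-free reference), stained, imaged at sub-micron
resolution, annotated region-by-region, and then everything has to be
put back together into one isotropic 3D label volume with watertight,
non-overlapping region surfaces and region-wise cell statistics.
`histoatlas` implements that chain for anyone reconstructing atlases
from serial sections — and ships a synthetic phantom-brain module so
every stage can be validated against known ground truth.

## What it does

- **Preprocessing** (`histoatlas.preprocess`) — multiplicative
  flat-field (shading) estimation from random image tiles and
  correction by division; adaptive-threshold tissue masking.
- **Block-face alignment** (`histoatlas.reconstruct`) — tissue parts
  matched by minimum-cost assignment, then multiscale rigid
  registration maximizing mask Dice
  (coarse-to-fine factors 8/4/2/1, Powell search with an
  angle-marginalized refinement), with optional symmetric
  diffeomorphic (demons) refinement and transform application to
  images, label images, and point sets.
- **Annotation** (`histoatlas.annotate`) — closed periodic cubic
  splines through control points rasterized with the even-odd rule,
  hierarchical composition (deeper ontology levels overwrite), and
  "cut lines" that split a major region into subregions while
  conserving area.
- **Ontology** (`histoatlas.ontology`) — a 4-level brain-region tree
  (ITK-SNAP `.label` files + JSON hierarchy sidecar), with level
  queries and mass-conserving aggregation of per-leaf values to any
  tree cut. The packaged default tree carries the 13 coarse-annotation
  major structures and a basal-ganglia grouping of 7 motor nuclei.
- **Volume building** (`histoatlas.volume3d`) — per-region
  interpolation between 100 µm-spaced annotated sections
  (diffeomorphic-demons fields between signed-distance transforms,
  time-scaled to produce intermediates) onto a 10 µm grid; competitive
  resolution of interpolation overlaps (voxels claimed twice are
  unassigned and refilled by equal-speed region expansion); marching
  cubes meshing; umbrella Laplacian smoothing (λ = 1e-4,
  100 iterations) and voxel-space overlap repair with decaying λ.
- **Cell atlas** (`histoatlas.cellatlas`) — mapping 2D detections
  through the alignment chain into reference space, region assignment
  and per-marker counting, 2D→3D calibration (reference ratios
  1.730 for DAPI, 1.864 for NeuN, or estimated from paired confocal
  patches), densities per (100 µm)³, composition ratios, and
  IoU ≥ 0.5 precision/recall/F1 detection evaluation.
- **Phantoms** (`histoatlas.synthetic`) — analytic multi-region
  phantom brains (lobed, notched superellipsoid shells + blob nuclei),
  sectioned with logged rigid perturbations, shading, and noise, plus
  region-wise Poisson cell clouds with nested total/neuron/PV markers.

## Worked example

```python
from histoatlas.synthetic import make_phantom, slice_phantom
from histoatlas.pipeline import (
    align_dataset, build_volume_from_dataset, phantom_region_dice,
)

phantom = make_phantom(n_regions=5, shape=(128, 128, 128), spacing=10.0, seed=1)
dataset = slice_phantom(phantom, slice_spacing=100.0, seed=2)  # ±7°, ±12 px

alignments = align_dataset(dataset)
for al, truth in zip(alignments, dataset.true_transforms):
    ang, disp = al.transforms[0].parameter_error(truth.inverse())
    print(f"slice {al.slice_index}: angle error {ang:.3f} deg, "
          f"shift error {disp:.3f} px")

build = build_volume_from_dataset(dataset, alignments=alignments)
print(phantom_region_dice(build, phantom, dataset))
```

prints (abridged):

```
slice 0: angle error 0.007 deg, shift error 0.026 px
slice 1: angle error 0.016 deg, shift error 0.004 px
...
slice 9: angle error 0.061 deg, shift error 0.019 px
{1: 0.9384, 2: 0.9422, 3: 0.973, 4: 0.9422, 5: 0.9101}
```

i.e. every section's rigid perturbation is recovered to well within
0.5° / 1 px, and the reconstructed 10 µm label volume reproduces each
of the five phantom regions with Dice ≥ 0.91 over the sectioned extent.

A thin CLI mirrors the library (`atlas simulate`, `atlas align`,
`atlas build-volume`, `atlas mesh`, `atlas cells-count`,
`atlas ontology-validate`); run `atlas --help`.

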