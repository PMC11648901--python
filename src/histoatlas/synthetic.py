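"""Phantom brains with known ground truth for every pipeline stage.

The generator emulates the study design: an isotropic multi-region 3D
volume standing in for the reference specimen (nested shells of a
superellipsoid "brain" with an articulated outline — in-plane lobes and a
deep midline-fissure notch, flattened along the cutting axis — plus
off-center spherical blobs); coronal sections cut at a fixed interval
whose stained images suffer a logged rigid perturbation, multiplicative
shading, and noise, while the paired block-face images stay in the
reference frame; and region-dependent Poisson cell point clouds for the
total / neuron / PV markers, with 2D slab detections thinned to emulate
the undercount of 50 µm widefield imaging relative to volumetric confocal
counting.

Section images are rendered from the analytic geometry at a finer pixel
size than the volume grid (``supersample``, default 2), mirroring how real
microscopy (0.65 µm pixels) oversamples a 10 µm atlas grid; this is what
makes sub-degree mask registration possible.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .ontology import Ontology, OntologyNode
from .reconstruct import RigidTransform2D
from .volume3d import LabelVolume

__all__ = [
    "PhantomTruth",
    "SlicedDataset",
    "PerturbSpec",
    "make_phantom",
    "slice_phantom",
    "sample_cells",
    "shading_field",
    "rasterize_phantom_plane",
]

MARKERS = ("total", "neuron", "PV")

# 3D/2D count ratios measured on volumetric confocal patches for nuclear
# and neuronal markers; 2D slab detections are thinned by their inverse.
DEFAULT_UNDERCOUNT = {"total": 1.0 / 1.730, "neuron": 1.0 / 1.864, "PV": 1.0}


@dataclass
class PhantomTruth:
    """A synthetic specimen with analytic geometry and known densities.

    ``shells`` (outermost first) and ``blobs`` hold the analytic shape
    parameters in voxel units so any grid can be re-rasterized
    independently; ``modulation`` carries the shared outline parameters
    (lobe amplitudes/phases, fissure notch, z-profile exponent).
    """

    label_volume: LabelVolume
    ontology: Ontology
    region_densities: Dict[Tuple[int, str], float]  # cells per (100 µm)³
    rng_seed: int
    shells: List[Tuple[int, Tuple[float, float, float], Tuple[float, float, float]]] = field(
        default_factory=list
    )
    blobs: List[Tuple[int, Tuple[float, float, float], Tuple[float, float, float]]] = field(
        default_factory=list
    )
    modulation: Dict[str, float] = field(default_factory=dict)


@dataclass
class SlicedDataset:
    """Sectioned phantom: per-slice images plus the logged corruption truth."""

    slice_labels: List[np.ndarray]  # annotation-frame (perturbed) label images
    histology_images: List[np.ndarray]  # (C, H, W) perturbed + shaded + noisy
    blockface_images: List[np.ndarray]  # (H, W) reference-frame projections
    true_transforms: List[RigidTransform2D]  # reference -> histology frame
    slice_spacing: float  # µm
    pixel_size: float  # µm (section images; volume spacing / supersample)
    slice_z_indices: List[int]  # phantom z-planes with tissue, in order
    margin: int  # canvas padding in image px
    reference_labels: List[np.ndarray]  # unperturbed label images (truth)
    supersample: int = 1

    def __post_init__(self) -> None:
        n = len(self.slice_labels)
        if not (
            len(self.histology_images) == len(self.blockface_images)
            == len(self.true_transforms) == n
        ):
            raise ValueError("per-slice lists must have equal length")
        if self.slice_spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("spacings must be positive")


@dataclass
class PerturbSpec:
    """Per-slice corruption ranges for :func:`slice_phantom`."""

    max_rotation_deg: float = 7.0
    max_translation_px: float = 12.0
    shading_strength: float = 0.25  # peak-to-mean amplitude of the vignette
    noise_sigma: float = 0.02
    psf_sigma: float = 0.6  # optical blur of the rendered images, px


def _synthetic_ontology(n_regions: int) -> Ontology:
    root_id = n_regions + 1
    nodes = [
        OntologyNode(root_id, "TIS", "Phantom tissue", (240, 240, 240), None, 0)
    ]
    rng = np.random.default_rng(12345)
    colors = set()
    for i in range(1, n_regions + 1):
        while True:
            color = tuple(int(c) for c in rng.integers(30, 255, 3))
            if color not in colors:
                colors.add(color)
                break
        nodes.append(
            OntologyNode(i, f"R{i}", f"Phantom region {i}", color, root_id, 1)
        )
    return Ontology(nodes, annotation_level_ids=list(range(1, n_regions + 1)))


def _outline_rho(theta: np.ndarray, mod: Dict[str, float]) -> np.ndarray:
    """In-plane radial modulation: lobes plus a deep narrow fissure notch."""
    rho = (
        1.0
        + mod["a2"] * np.cos(2 * theta + mod["phi2"])
        + mod["a3"] * np.cos(3 * theta + mod["phi3"])
    )
    dang = np.angle(np.exp(1j * (theta - mod["notch_angle"])))
    rho = rho * (1.0 - mod["notch_depth"] * np.exp(-(dang**2) / (2 * mod["notch_sigma"] ** 2)))
    return rho


def _shell_membership(
    z: np.ndarray, y: np.ndarray, x: np.ndarray,
    center: Tuple[float, float, float],
    semi: Tuple[float, float, float],
    mod: Dict[str, float],
) -> np.ndarray:
    """Superellipsoid shell with modulated in-plane outline.

    Coordinates are voxel units; a voxel/pixel with index i spans
    ``[i, i+1)`` and is sampled at ``i + 0.5``.
    """
    cz, cy, cx = center
    az, ay, ax = semi
    dz, dy, dx = z - cz, y - cy, x - cx
    theta = np.arctan2(dy, dx)
    rho = _outline_rho(theta, mod)
    inside = (
        np.abs(dz / az) ** mod["z_exponent"]
        + (dx / (ax * rho)) ** 2
        + (dy / (ay * rho)) ** 2
    ) <= 1.0
    # the block is trimmed flat at both poles (as a real tissue block is),
    # which keeps thin shell rings wider than a voxel everywhere
    return inside & (np.abs(dz) <= mod.get("z_cut_frac", 1.0) * az)


def _blob_membership(z, y, x, center, semi) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax = semi
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def _paint_labels(z, y, x, shells, blobs, mod) -> np.ndarray:
    labels = np.zeros(np.broadcast(z, y, x).shape, dtype=np.int32)
    for rid, center, semi in shells:
        labels[_shell_membership(z, y, x, center, semi, mod)] = rid
    for rid, center, semi in blobs:
        labels[_blob_membership(z, y, x, center, semi)] = rid
    return labels


def _unit_sphere_points(n: int = 64) -> np.ndarray:
    """Deterministic quasi-uniform direction set (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5**0.5)
    theta = golden * i
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )  # (n, 3) as (z, y, x)


def make_phantom(
    n_regions: int = 5,
    shape: Tuple[int, int, int] = (128, 128, 128),
    spacing: float = 10.0,
    seed: int = 0,
) -> PhantomTruth:
    """Deterministic multi-region phantom volume.

    Up to three nested shells of a flattened, lobed, notched
    superellipsoid (so every coronal outline pins in-plane orientation)
    plus off-center spherical blobs for the remaining regions. Every
    region is 6-connected and non-empty; shapes too small to carry all
    regions raise.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError("shape must be at least 32 voxels per axis")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    center = (nz / 2.0, ny / 2.0, nx / 2.0)
    outer = (0.40 * nz, 0.37 * ny, 0.27 * nx)
    mod = {
        "a2": 0.13,
        "phi2": float(rng.uniform(0, 2 * np.pi)),
        "a3": 0.08,
        "phi3": float(rng.uniform(0, 2 * np.pi)),
        "notch_depth": 0.30,
        "notch_angle": float(rng.uniform(0, 2 * np.pi)),
        "notch_sigma": 0.06,
        "z_exponent": 6.0,
        "z_cut_frac": 0.92,
    }

    n_shells = min(n_regions, 3)
    n_blobs = n_regions - n_shells
    fractions = np.linspace(1.0, 0.45, n_shells + 1)[:-1] if n_shells > 1 else [1.0]
    # shells shrink in-plane only, sharing the full z-extent: every region
    # then spans (nearly) the whole section series, as real brain
    # structures span many sections, instead of appearing abruptly inside
    # one 100 µm gap
    shells = [
        (i + 1, center, (outer[0], outer[1] * frac, outer[2] * frac))
        for i, frac in enumerate(fractions)
    ]

    zz, yy, xx = np.meshgrid(
        *[np.arange(s, dtype=float) + 0.5 for s in shape], indexing="ij"
    )
    base = _paint_labels(zz, yy, xx, shells, [], mod)

    # z-elongated blob nuclei spanning several section gaps
    blob_semi = (0.17 * nz, 0.085 * ny, 0.085 * nx)
    outer_arr = np.asarray(outer)
    struct6 = ndimage.generate_binary_structure(3, 1)
    sphere_dirs = _unit_sphere_points(64)

    def blob_inside_outer(c: np.ndarray) -> bool:
        # blob surface points (plus 2-voxel slack) all inside the outer shell
        pts = c[None, :] + sphere_dirs * (np.asarray(blob_semi) + 2.0)
        ok = _shell_membership(
            pts[:, 0], pts[:, 1], pts[:, 2], center, shells[0][2], mod
        )
        return bool(ok.all())

    sep_scale = 2.0 * np.asarray(blob_semi) + 4.0  # per-axis clearance

    def try_blobs():
        labels = base.copy()
        blobs = []
        for j in range(n_blobs):
            rid = n_shells + j + 1
            for _ in range(500):
                offset = rng.uniform(-0.7, 0.7, 3) * outer_arr
                c = np.asarray(center) + offset
                apart = all(
                    np.linalg.norm((c - np.asarray(bc)) / sep_scale) > 1.0
                    for _, bc, _ in blobs
                )
                off_center = np.linalg.norm(offset) > max(blob_semi) * 0.6
                if apart and off_center and blob_inside_outer(c):
                    break
            else:
                return None, None
            labels[_blob_membership(zz, yy, xx, tuple(c), blob_semi)] = rid
            blobs.append((rid, tuple(float(v) for v in c), tuple(blob_semi)))
        # snap sub-scale rasterization slivers (stray components far below
        # 0.1% of their region) onto the nearest surviving label
        stray = np.zeros(labels.shape, dtype=bool)
        for rid in range(1, n_regions + 1):
            mask = labels == rid
            if not mask.any():
                return None, None
            comp, n_comp = ndimage.label(mask, struct6)
            if n_comp == 1:
                continue
            sizes = np.bincount(comp.ravel())[1:]
            main = int(np.argmax(sizes)) + 1
            small = mask & (comp != main)
            if small.sum() > max(8, 0.001 * mask.sum()):
                return None, None  # genuinely split region: re-draw blobs
            stray |= small
        if stray.any():
            idx = ndimage.distance_transform_edt(
                stray, return_indices=True, return_distances=False
            )
            labels = labels.copy()
            labels[stray] = labels[tuple(i[stray] for i in idx)]
        for rid in range(1, n_regions + 1):
            mask = labels == rid
            if not mask.any():
                return None, None
            _, n_comp = ndimage.label(mask, struct6)
            if n_comp != 1:
                return None, None
        return labels, blobs

    labels = blobs = None
    for _ in range(25):  # re-draw blob layouts until all regions survive
        labels, blobs = try_blobs()
        if labels is not None:
            break
    if labels is None:
        raise ValueError(
            "could not place blob regions with all regions connected; "
            "use a larger shape"
        )

    volume = LabelVolume(labels, spacing=(spacing, spacing, spacing))
    densities: Dict[Tuple[int, str], float] = {}
    for rid in range(1, n_regions + 1):
        total = 90.0 + 25.0 * rid
        neuron = total * min(0.40 + 0.06 * rid, 0.9)
        pv = neuron * 0.08
        densities[(rid, "total")] = total
        densities[(rid, "neuron")] = neuron
        densities[(rid, "PV")] = pv
    return PhantomTruth(
        label_volume=volume,
        ontology=_synthetic_ontology(n_regions),
        region_densities=densities,
        rng_seed=seed,
        shells=shells,
        blobs=blobs,
        modulation=mod,
    )


def rasterize_phantom_plane(
    phantom: PhantomTruth,
    z_index: int,
    supersample: int = 1,
    margin: int = 0,
) -> np.ndarray:
    """Analytic label image of one coronal plane at sub-voxel pixel size.

    Image pixel ``j`` maps to volume coordinate ``(j - margin + 0.5) /
    supersample`` voxel units, so blocks of ``supersample²`` pixels tile
    each volume voxel exactly.
    """
    nz, ny, nx = phantom.label_volume.labels.shape
    h = ny * supersample + 2 * margin
    w = nx * supersample + 2 * margin
    jj, ii = np.mgrid[0:h, 0:w].astype(float)
    y = (jj - margin + 0.5) / supersample
    x = (ii - margin + 0.5) / supersample
    z = np.full_like(y, z_index + 0.5)
    return _paint_labels(z, y, x, phantom.shells, phantom.blobs, phantom.modulation)


def shading_field(
    shape: Tuple[int, int], strength: float = 0.25, seed: int = 0
) -> np.ndarray:
    """Multiplicative shading: low-order polynomial × Gaussian vignette, mean 1."""
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - w / 2) / (w / 2)
    v = (yy - h / 2) / (h / 2)
    c = rng.uniform(-0.3, 0.3, size=4)
    poly = 1.0 + c[0] * u + c[1] * v + c[2] * u * v + c[3] * (u**2 - v**2)
    sigma = 0.75
    vignette = np.exp(-(u**2 + v**2) / (2 * sigma**2))
    fld = poly * (1.0 - strength + strength * vignette / vignette.max())
    fld = np.clip(fld, 0.05, None)
    return fld / fld.mean()


def slice_phantom(
    phantom: PhantomTruth,
    slice_spacing: float = 100.0,
    perturb: Optional[PerturbSpec] = None,
    seed: int = 0,
    margin: Optional[int] = None,
    supersample: int = 2,
    min_tissue_px: int = 64,
) -> SlicedDataset:
    """Cut the phantom into coronal sections with logged corruptions.

    Sections are the phantom z-planes at the requested interval, rendered
    analytically at ``spacing / supersample`` pixel size; planes without
    tissue (beyond the specimen poles) carry no section and are skipped.
    Each histology image receives a random rigid perturbation (rotation
    about the canvas center plus translation, logged in
    ``true_transforms`` as the reference→histology map), region-dependent
    intensities, a multiplicative shading field shared across the stack,
    optical blur, and Gaussian noise. Block-face images are unperturbed
    tissue projections on the same canvas.
    """
    if perturb is None:
        perturb = PerturbSpec()
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    spacing_z = phantom.label_volume.spacing[0]
    if slice_spacing < spacing_z:
        raise ValueError("slice_spacing must be >= phantom spacing")
    step_f = slice_spacing / spacing_z
    if abs(step_f - round(step_f)) > 1e-6:
        raise ValueError("slice_spacing must be an integer multiple of phantom spacing")
    step = int(round(step_f))
    nz, ny, nx = phantom.label_volume.labels.shape
    if margin is None:
        # translation + rotation slack so perturbed tissue stays on canvas
        r_max = 0.5 * max(ny, nx) * supersample
        margin = int(
            np.ceil(
                perturb.max_translation_px
                + 2 * r_max * np.sin(np.deg2rad(perturb.max_rotation_deg) / 2)
                + 8
            )
        )
    h = ny * supersample + 2 * margin
    w = nx * supersample + 2 * margin
    canvas_center = ((w - 1) / 2.0, (h - 1) / 2.0)

    rng = np.random.default_rng(seed)
    shading = shading_field((h, w), perturb.shading_strength, seed=seed + 1)

    n_regions = len(phantom.ontology.annotation_level_ids)
    base_int = {
        rid: (0.45 + 0.5 * (rid / max(n_regions, 1)), 0.9 - 0.5 * (rid / max(n_regions, 1)))
        for rid in range(1, n_regions + 1)
    }

    slice_labels, histology, blockface, transforms, reference, kept_z = (
        [], [], [], [], [], []
    )
    for zi in range(0, nz, step):
        plane = rasterize_phantom_plane(phantom, zi, supersample, margin)
        theta = float(rng.uniform(-perturb.max_rotation_deg, perturb.max_rotation_deg))
        tx, ty = rng.uniform(-perturb.max_translation_px, perturb.max_translation_px, 2)
        if (plane > 0).sum() < min_tissue_px:
            continue  # pole plane: no section cut here
        kept_z.append(zi)
        reference.append(plane)

        tf = RigidTransform2D(theta, (float(tx), float(ty)), "none", canvas_center)
        pert_labels = tf.apply_to_image(plane, order=0)
        border = np.concatenate(
            [pert_labels[0], pert_labels[-1], pert_labels[:, 0], pert_labels[:, -1]]
        )
        if (border != 0).any():
            raise ValueError(
                f"perturbation pushed tissue outside the canvas at z-index {zi}"
            )

        chans = []
        for ch in range(2):
            img = np.full((h, w), 0.03)
            for rid, bases in base_int.items():
                img[pert_labels == rid] = bases[ch]
            img = ndimage.gaussian_filter(img, perturb.psf_sigma)
            img *= shading
            img += rng.normal(0.0, perturb.noise_sigma, img.shape)
            chans.append(np.clip(img, 0.0, None))
        histology.append(np.stack(chans))

        bf = np.where(plane > 0, 0.55 + 0.02 * plane, 0.03).astype(float)
        bf = ndimage.gaussian_filter(bf, perturb.psf_sigma)
        bf += rng.normal(0.0, perturb.noise_sigma / 2, bf.shape)
        blockface.append(np.clip(bf, 0.0, None))

        slice_labels.append(pert_labels)
        transforms.append(tf)

    if not slice_labels:
        raise ValueError("no section contained tissue")
    return SlicedDataset(
        slice_labels=slice_labels,
        histology_images=histology,
        blockface_images=blockface,
        true_transforms=transforms,
        slice_spacing=slice_spacing,
        pixel_size=spacing_z / supersample,
        slice_z_indices=kept_z,
        margin=margin,
        reference_labels=reference,
        supersample=supersample,
    )


def sample_cells(
    phantom: PhantomTruth,
    seed: int = 0,
    slice_spacing: float = 100.0,
    section_thickness: float = 50.0,
    undercount_factors: Optional[Dict[str, float]] = None,
    dataset: Optional[SlicedDataset] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Region-wise homogeneous Poisson cell clouds plus 2D slab detections.

    Returns ``(cells3d, detections2d)``. ``cells3d`` holds every cell once
    with µm positions, its true region, and nested ``is_neuron``/``is_pv``
    flags (PV ⊆ neuron ⊆ total by thinning construction). ``detections2d``
    holds per-marker records of cells falling inside each section slab
    ``[z_k, z_k + thickness)``, binomially thinned by the marker's 2D
    undercount factor; positions are pixel coordinates in the annotation
    frame (perturbed when ``dataset`` is given, so they need alignment).
    """
    if undercount_factors is None:
        undercount_factors = dict(DEFAULT_UNDERCOUNT)
    for marker, f in undercount_factors.items():
        if not (0 < f <= 1):
            raise ValueError(f"undercount factor for {marker} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    vol = phantom.label_volume
    sz, sy, sx = vol.spacing
    cube = 100.0**3  # µm³ per (100 µm)³ density unit

    rows = []
    for rid in sorted({r for r, _ in phantom.region_densities}):
        d_total = phantom.region_densities.get((rid, "total"), 0.0)
        d_neuron = phantom.region_densities.get((rid, "neuron"), 0.0)
        d_pv = phantom.region_densities.get((rid, "PV"), 0.0)
        if min(d_total, d_neuron, d_pv) < 0:
            raise ValueError(f"negative density for region {rid}")
        if not (d_pv <= d_neuron <= d_total):
            raise ValueError(f"region {rid}: densities must nest PV <= neuron <= total")
        vox = np.argwhere(vol.labels == rid)
        if len(vox) == 0 or d_total == 0:
            continue
        region_vol = len(vox) * vol.voxel_volume
        n = rng.poisson(d_total * region_vol / cube)
        if n == 0:
            continue
        picks = vox[rng.integers(0, len(vox), n)]
        offs = rng.uniform(0, 1, (n, 3))
        z_um = (picks[:, 0] + offs[:, 0]) * sz
        y_um = (picks[:, 1] + offs[:, 1]) * sy
        x_um = (picks[:, 2] + offs[:, 2]) * sx
        p_neuron = d_neuron / d_total if d_total > 0 else 0.0
        is_neuron = rng.uniform(size=n) < p_neuron
        p_pv = d_pv / d_neuron if d_neuron > 0 else 0.0
        is_pv = is_neuron & (rng.uniform(size=n) < p_pv)
        rows.append(
            pd.DataFrame(
                {
                    "x_um": x_um, "y_um": y_um, "z_um": z_um,
                    "region_id": rid, "is_neuron": is_neuron, "is_pv": is_pv,
                }
            )
        )
    if rows:
        cells = pd.concat(rows, ignore_index=True)
    else:
        cells = pd.DataFrame(
            columns=["x_um", "y_um", "z_um", "region_id", "is_neuron", "is_pv"]
        )

    nz = vol.labels.shape[0]
    step = int(round(slice_spacing / sz))
    if dataset is not None:
        z_indices = list(dataset.slice_z_indices)
        pixel_size = dataset.pixel_size
        margin = dataset.margin
    else:
        z_indices = list(range(0, nz, step))
        pixel_size = sx
        margin = 0

    det_rows = []
    for k, zi in enumerate(z_indices):
        if len(cells) == 0:
            break
        z0 = zi * sz
        in_slab = (cells["z_um"] >= z0) & (cells["z_um"] < z0 + section_thickness)
        slab = cells[in_slab]
        marker_sel = {
            "total": np.ones(len(slab), dtype=bool),
            "neuron": slab["is_neuron"].to_numpy(),
            "PV": slab["is_pv"].to_numpy(),
        }
        for marker in MARKERS:
            sub = slab[marker_sel[marker]]
            keep = rng.uniform(size=len(sub)) < undercount_factors.get(marker, 1.0)
            sub = sub[keep]
            if len(sub) == 0:
                continue
            x_px = sub["x_um"].to_numpy() / pixel_size + margin
            y_px = sub["y_um"].to_numpy() / pixel_size + margin
            if dataset is not None:
                pts = dataset.true_transforms[k].apply_points(
                    np.stack([x_px, y_px], axis=1)
                )
                x_px, y_px = pts[:, 0], pts[:, 1]
            det_rows.append(
                pd.DataFrame(
                    {
                        "marker": marker, "slice_index": k,
                        "x_px": x_px, "y_px": y_px,
                        "true_region_id": sub["region_id"].to_numpy(),
                    }
                )
            )
    if det_rows:
        detections = pd.concat(det_rows, ignore_index=True)
    else:
        detections = pd.DataFrame(
            columns=["marker", "slice_index", "x_px", "y_px", "true_region_id"]
        )
    return cells, detections
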