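"""End-to-end convenience: sectioned dataset → aligned isotropic volume.

Chains the stages the way an atlas build runs them: tissue masks from
histology and block-face images, part matching and multiscale rigid
registration, application of the recovered transforms to the annotation
label images, per-region interpolation to an isotropic claim volume, and
competitive overlap resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import TissueSegConfig, segment_tissue
from .reconstruct import SliceAlignment, align_sections, apply_alignment
from .synthetic import SlicedDataset
from .volume3d import ClaimVolume, LabelVolume, build_claim_volume, resolve_overlaps

__all__ = ["AtlasBuild", "align_dataset", "build_volume_from_dataset"]


@dataclass
class AtlasBuild:
    """Everything produced by one reconstruction run."""

    alignments: List[SliceAlignment]
    aligned_labels: List[np.ndarray]
    claims: ClaimVolume
    volume: LabelVolume


def align_dataset(
    dataset: SlicedDataset,
    seg_config: Optional[TissueSegConfig] = None,
    min_area: int = 64,
    levels: int = 4,
    allow_flip: bool = False,
) -> List[SliceAlignment]:
    """Recover each slice's histology→block-face alignment from masks."""
    hist_masks = [
        segment_tissue(img, min_area=min_area, config=seg_config)
        for img in dataset.histology_images
    ]
    bf_masks = [
        segment_tissue(img, min_area=min_area, config=seg_config)
        for img in dataset.blockface_images
    ]
    return align_sections(hist_masks, bf_masks, levels=levels, allow_flip=allow_flip)


def build_volume_from_dataset(
    dataset: SlicedDataset,
    spacing_out: float = 10.0,
    alignments: Optional[Sequence[SliceAlignment]] = None,
    **align_kwargs,
) -> AtlasBuild:
    """Full reconstruction: align, restack labels, interpolate, resolve."""
    if alignments is None:
        alignments = align_dataset(dataset, **align_kwargs)
    aligned = [
        apply_alignment(lbl, al, direction="forward", kind="labels")
        for lbl, al in zip(dataset.slice_labels, alignments)
    ]
    # reference frame: z in specimen µm (first section plane at its true
    # z), in-plane in canvas µm (origin at the padded canvas corner, the
    # frame mapped cell detections land in)
    z0_um = dataset.slice_z_indices[0] * dataset.pixel_size * dataset.supersample
    claims = build_claim_volume(
        aligned,
        spacing_in=dataset.slice_spacing,
        spacing_out=spacing_out,
        pixel_size=dataset.pixel_size,
        origin=(z0_um, 0.0, 0.0),
    )
    volume = resolve_overlaps(claims)
    return AtlasBuild(list(alignments), aligned, claims, volume)


def downsample_labels_majority(
    labels: np.ndarray, supersample: int, margin: int, out_hw: Tuple[int, int]
) -> np.ndarray:
    """Collapse supersampled in-plane label planes to the volume grid.

    Each volume voxel corresponds to a ``supersample²`` pixel block
    (after stripping the canvas margin); the block's majority label wins,
    ties going to the smaller id.
    """
    ny, nx = out_hw
    ss = supersample
    core = labels[..., margin : margin + ny * ss, margin : margin + nx * ss]
    lead = core.shape[:-2]
    blocks = core.reshape(*lead, ny, ss, nx, ss)
    blocks = np.moveaxis(blocks, -3, -2).reshape(*lead, ny, nx, ss * ss)
    ids = np.unique(blocks)
    best_count = np.zeros(blocks.shape[:-1], dtype=np.int16)
    out = np.zeros(blocks.shape[:-1], dtype=labels.dtype)
    for rid in ids[::-1]:  # ascending priority: lower ids overwrite on ties
        count = (blocks == rid).sum(axis=-1).astype(np.int16)
        take = count >= np.maximum(best_count, 1)
        out[take] = rid
        best_count = np.maximum(best_count, count)
    return out


def phantom_region_dice(
    build: AtlasBuild, phantom, dataset: SlicedDataset
) -> dict:
    """Per-region Dice of the reconstruction against the phantom truth.

    The reconstructed volume (section pixel size in-plane) is collapsed to
    the phantom grid by block majority; comparison covers the z-range the
    sections span.
    """
    truth = phantom.label_volume.labels
    nz, ny, nx = truth.shape
    recon = downsample_labels_majority(
        build.volume.labels, dataset.supersample, dataset.margin, (ny, nx)
    )
    z0 = dataset.slice_z_indices[0]
    step_um = build.volume.spacing[0]
    step = int(round(step_um / phantom.label_volume.spacing[0]))
    z_planes = [z0 + p * step for p in range(recon.shape[0])]
    truth_crop = truth[z_planes]
    out = {}
    for rid in phantom.label_volume.region_ids():
        a = recon == rid
        b = truth_crop == rid
        denom = a.sum() + b.sum()
        out[int(rid)] = float(2.0 * (a & b).sum() / denom) if denom else 1.0
    return out
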