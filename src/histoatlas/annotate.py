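"""Spline annotations and cut lines → per-slice label images.

Regions are annotated as closed periodic cubic splines through control
points; rasterization samples the curve densely and fills it with the
even-odd polygon rule, so the mask is independent of traversal
orientation. Annotations compose under the ontology: deeper-level regions
overwrite shallower ones, same-level conflicts go to the later draw order.
Subregions are split off a major region by "cut lines": a 1-px polyline
divides the region support into connected components which are reassigned
individual region ids, the line pixels rejoining the neighbor with the
largest shared border so area is conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.measure import find_contours

from .ontology import Ontology

__all__ = [
    "SplineAnnotation",
    "CutLine",
    "ComposeResult",
    "rasterize_spline",
    "compose_labels",
    "apply_cutline",
    "mask_to_spline",
]


@dataclass
class SplineAnnotation:
    """One closed-region annotation on one slice.

    ``control_points`` is an ``(n, 2)`` array of ``(x, y)`` pixel
    coordinates, ``n >= 3`` and not all collinear; the curve through them
    is closed.
    """

    region_id: int
    control_points: np.ndarray
    slice_index: int = 0
    draw_order: int = 0

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.control_points, float))
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("need at least 3 control points of shape (n, 2)")
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError("control points are collinear")
        self.control_points = pts


@dataclass
class CutLine:
    """Polyline splitting one region; pieces are reassigned by index.

    ``assignments`` maps piece index → region id, with pieces ordered by
    area descending (ties: uppermost-leftmost pixel first).
    """

    points: np.ndarray
    assignments: Dict[int, int]

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, float))
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("cut line needs at least 2 points of shape (n, 2)")
        self.points = pts


def _closed_spline_samples(points: np.ndarray, arc_step: float = 0.5) -> np.ndarray:
    """Densely sample the closed periodic cubic spline through ``points``.

    The control order is canonicalized to counter-clockwise (and the start
    point to the lexicographically smallest) so traversal orientation
    cannot change the sampled polygon.
    """
    area2 = np.sum(
        points[:, 0] * np.roll(points[:, 1], -1)
        - np.roll(points[:, 0], -1) * points[:, 1]
    )
    if area2 < 0:
        points = points[::-1]
    start = np.lexsort((points[:, 1], points[:, 0]))[0]
    points = np.roll(points, -start, axis=0)
    pts = np.vstack([points, points[:1]])
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    if t[-1] == 0:
        raise ValueError("degenerate control polygon")
    spline = CubicSpline(t, pts, bc_type="periodic")
    # sample finely, then once more against the measured arc length
    dense_t = np.linspace(0.0, t[-1], max(64, 8 * len(points)))
    dense = spline(dense_t)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    n_samples = max(16, int(np.ceil(arc[-1] / arc_step)) + 1)
    return spline(np.interp(np.linspace(0, arc[-1], n_samples), arc, dense_t))


def rasterize_spline(
    annotation: SplineAnnotation, shape: Tuple[int, int], arc_step: float = 0.5
) -> np.ndarray:
    """Fill the closed spline on a ``shape`` grid (even-odd rule).

    The curve is sampled at most ``arc_step`` pixels apart; the resulting
    polygon is scan-filled, so reversing the control-point order yields an
    identical mask.
    """
    samples = _closed_spline_samples(annotation.control_points, arc_step)
    rr, cc = draw_polygon(samples[:, 1], samples[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


@dataclass
class ComposeResult:
    labels: np.ndarray
    warnings: List[str] = field(default_factory=list)


def compose_labels(
    annotations: Sequence[SplineAnnotation],
    ontology: Ontology,
    shape: Tuple[int, int],
    overlap_warn_frac: float = 0.05,
) -> ComposeResult:
    """Paint spline annotations into a label image under the ontology.

    Painting order is (ontology level, draw order) ascending, so deeper
    regions overwrite their shallower ancestors and later draw order wins
    among equals. Overlaps between same-level regions that are not on one
    ancestor line are reported when they exceed ``overlap_warn_frac`` of
    the smaller region.
    """
    for ann in annotations:
        if ann.region_id not in ontology:
            raise KeyError(f"region id {ann.region_id} not in ontology")
    masks = [(ann, rasterize_spline(ann, shape)) for ann in annotations]
    warns: List[str] = []
    for i, (a, ma) in enumerate(masks):
        for b, mb in masks[i + 1 :]:
            la, lb = ontology[a.region_id].level, ontology[b.region_id].level
            if la != lb:
                continue
            if a.region_id == b.region_id:
                continue
            if ontology.is_ancestor(a.region_id, b.region_id) or ontology.is_ancestor(
                b.region_id, a.region_id
            ):
                continue
            inter = (ma & mb).sum()
            smaller = min(ma.sum(), mb.sum())
            if smaller and inter / smaller > overlap_warn_frac:
                msg = (
                    f"regions {a.region_id} and {b.region_id} (level {la}) overlap "
                    f"on {inter} px ({inter / smaller:.1%} of the smaller)"
                )
                warns.append(msg)
                warnings.warn(msg, stacklevel=2)
    order = sorted(
        range(len(masks)),
        key=lambda i: (ontology[masks[i][0].region_id].level, masks[i][0].draw_order),
    )
    labels = np.zeros(shape, dtype=np.int32)
    for i in order:
        ann, mask = masks[i]
        labels[mask] = ann.region_id
    return ComposeResult(labels, warns)


def _order_components(comp_labels: np.ndarray, n: int) -> List[int]:
    """Component labels ordered by area desc, then topmost-leftmost pixel."""
    stats = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(comp_labels == lab)
        stats.append((-len(ys), ys.min(), xs.min(), lab))
    return [s[3] for s in sorted(stats)]


def apply_cutline(label_image: np.ndarray, cut: CutLine) -> np.ndarray:
    """Split one region along a polyline and reassign the pieces.

    The polyline is rasterized 1 px wide; it must intersect exactly one
    region id's support. That region minus the line splits into
    4-connected components, relabeled through ``cut.assignments`` (piece
    indices ordered by area descending). Line pixels then join the
    adjacent piece with the largest shared border, so the pixel total of
    the original region is conserved.
    """
    labels = np.asarray(label_image).copy()
    h, w = labels.shape
    line_mask = np.zeros_like(labels, dtype=bool)
    pts = np.round(cut.points).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        line_mask[rr[keep], cc[keep]] = True

    hit_ids = np.unique(labels[line_mask])
    hit_ids = hit_ids[hit_ids != 0]
    if len(hit_ids) == 0:
        raise ValueError("cut line does not touch any region")
    if len(hit_ids) > 1:
        raise ValueError(f"cut line crosses multiple regions: {sorted(map(int, hit_ids))}")
    rid = int(hit_ids[0])
    region = labels == rid

    remainder = region & ~line_mask
    comp, n_comp = ndimage.label(remainder, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    ))
    if n_comp < 2:
        raise ValueError("cut line does not split the region")
    ordered = _order_components(comp, n_comp)
    missing = [i for i in range(n_comp) if i not in cut.assignments]
    if missing:
        sizes = {i: int((comp == ordered[i]).sum()) for i in range(n_comp)}
        raise ValueError(
            f"assignments missing pieces {missing}; produced pieces (area px): {sizes}"
        )
    piece_id = {ordered[i]: cut.assignments[i] for i in range(n_comp)}
    out = labels.copy()
    for lab, new_id in piece_id.items():
        out[comp == lab] = new_id

    # line pixels inside the region rejoin the neighboring piece with the
    # largest shared border; iterate for pixels initially touching only line
    pending = line_mask & region
    comp_grown = comp.copy()
    while pending.any():
        ys, xs = np.nonzero(pending)
        assigned_any = False
        votes = np.zeros((len(ys), n_comp + 1), dtype=int)
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)):
            ny, nx_ = ys + dy, xs + dx
            ok = (ny >= 0) & (ny < h) & (nx_ >= 0) & (nx_ < w)
            nb = np.zeros(len(ys), dtype=int)
            nb[ok] = comp_grown[ny[ok], nx_[ok]]
            votes[np.arange(len(ys)), nb] += 1
        votes[:, 0] = 0
        has_nb = votes.max(axis=1) > 0
        for i in np.flatnonzero(has_nb):
            top = votes[i].max()
            tied = np.flatnonzero(votes[i] == top)
            # split exact border ties evenly by pixel parity so the cut
            # line does not bias one piece
            pick = int(tied[(ys[i] + xs[i]) % len(tied)])
            comp_grown[ys[i], xs[i]] = pick
            out[ys[i], xs[i]] = piece_id[pick]
            pending[ys[i], xs[i]] = False
            assigned_any = True
        if not assigned_any:
            break  # isolated line pixels not adjacent to the region interior
    return out


def mask_to_spline(
    mask: np.ndarray, region_id: int, n_points: int = 32, slice_index: int = 0
) -> SplineAnnotation:
    """Trace a region boundary and refit a closed spline annotation.

    Uses the longest 0.5-level contour of the mask, resampled to
    ``n_points`` control points at equal arc length.
    """
    contours = find_contours(np.asarray(mask, float), 0.5)
    if not contours:
        raise ValueError("mask is empty")
    contour = max(contours, key=len)  # (row, col)
    xy = contour[:, ::-1]
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    targets = np.linspace(0, arc[-1], n_points, endpoint=False)
    ctrl = np.stack(
        [np.interp(targets, arc, xy[:, 0]), np.interp(targets, arc, xy[:, 1])], axis=1
    )
    return SplineAnnotation(region_id, ctrl, slice_index=slice_index)
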