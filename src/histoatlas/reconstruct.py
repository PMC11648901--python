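"""Restore sections into block-face coordinates.

Each cut section is photographed on the block face before sectioning; the
block-face image is the distortion-free spatial reference. Stained sections
are re-aligned to it part-by-part: tissue parts are matched by a
minimum-cost assignment, each part is rigidly registered (multiscale,
mask-Dice metric), and an optional symmetric diffeomorphic stage refines
residual tissue distortion. Transforms apply to intensity images, label
images, and point sets.

Conventions: images are indexed ``[row, col] = [y, x]``; point arrays have
shape ``(n, 2)`` ordered ``(x, y)``; rotations are counter-clockwise
degrees about an explicit center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, optimize
from skimage.transform import AffineTransform, warp

__all__ = [
    "RigidTransform2D",
    "DeformationField2D",
    "SliceAlignment",
    "match_parts",
    "PartMatch",
    "register_rigid",
    "register_deformable",
    "apply_alignment",
    "align_sections",
]

Flip = Literal["none", "horizontal", "vertical"]


@dataclass
class RigidTransform2D:
    """Rigid map ``p' = R(theta) (F(p) - c) + c + t`` in pixel coordinates.

    ``F`` is an optional flip about the center ``c`` (horizontal mirrors x,
    vertical mirrors y) applied before the rotation. ``dice`` and
    ``low_quality`` carry registration diagnostics when the transform came
    out of :func:`register_rigid`.
    """

    rotation_deg: float = 0.0
    translation: Tuple[float, float] = (0.0, 0.0)
    flip: Flip = "none"
    center: Tuple[float, float] = (0.0, 0.0)
    dice: Optional[float] = None
    low_quality: bool = False

    # -- matrix plumbing ---------------------------------------------------

    def _flip_mat(self) -> np.ndarray:
        if self.flip == "horizontal":
            return np.diag([-1.0, 1.0])
        if self.flip == "vertical":
            return np.diag([1.0, -1.0])
        return np.eye(2)

    def linear(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return rot @ self._flip_mat()

    def offset(self) -> np.ndarray:
        c = np.asarray(self.center, float)
        t = np.asarray(self.translation, float)
        return c + t - self.linear() @ c

    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on ``(x, y, 1)`` columns."""
        h = np.eye(3)
        h[:2, :2] = self.linear()
        h[:2, 2] = self.offset()
        return h

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, center: Tuple[float, float] = (0.0, 0.0)
    ) -> "RigidTransform2D":
        lin = np.asarray(matrix, float)[:2, :2]
        off = np.asarray(matrix, float)[:2, 2]
        if np.linalg.det(lin) < 0:
            flip: Flip = "horizontal"
            fm = np.diag([-1.0, 1.0])
        else:
            flip = "none"
            fm = np.eye(2)
        rot = lin @ fm  # fm is its own inverse
        theta = np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0]))
        c = np.asarray(center, float)
        t = off - c + lin @ c
        return cls(float(theta), (float(t[0]), float(t[1])), flip, tuple(c))

    # -- operations --------------------------------------------------------

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.linear().T + self.offset()

    def inverse(self) -> "RigidTransform2D":
        return RigidTransform2D.from_matrix(
            np.linalg.inv(self.matrix()), center=self.center
        )

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to ``first`` then ``self``."""
        return RigidTransform2D.from_matrix(
            self.matrix() @ first.matrix(), center=self.center
        )

    def apply_to_image(
        self,
        image: np.ndarray,
        order: int = 1,
        output_shape: Optional[Tuple[int, int]] = None,
    ) -> np.ndarray:
        """Resample ``image`` so content moves by the forward transform."""
        tf = AffineTransform(matrix=np.linalg.inv(self.matrix()))
        out = warp(
            image.astype(float),
            tf,
            order=order,
            output_shape=output_shape,
            preserve_range=True,
            mode="constant",
            cval=0.0,
        )
        if order == 0:
            out = out.astype(image.dtype)
        return out

    def parameter_error(self, other: "RigidTransform2D") -> Tuple[float, float]:
        """(|Δangle| deg, displacement at the shared center, px) vs ``other``."""
        resid = self.compose(other.inverse())
        ang = abs((resid.rotation_deg + 180.0) % 360.0 - 180.0)
        c = np.asarray(self.center, float)
        disp = float(np.linalg.norm(resid.apply_points(c[None, :])[0] - c))
        return ang, disp


@dataclass
class DeformationField2D:
    """Dense displacement field on the fixed grid, pixel units.

    ``displacement[y, x] = (ux, uy)`` with the pull-back convention: the
    moving image resampled at ``(x + ux, y + uy)`` matches the fixed image
    at ``(x, y)``. Diffeomorphic contract: the Jacobian determinant of
    ``id + u`` is positive on the grid.
    """

    displacement: np.ndarray  # (H, W, 2), last axis (ux, uy)

    def _sitk_field(self) -> sitk.Image:
        return sitk.GetImageFromArray(self.displacement.astype(np.float64), isVector=True)

    def jacobian_determinant(self) -> np.ndarray:
        jac = sitk.DisplacementFieldJacobianDeterminant(self._sitk_field())
        return sitk.GetArrayFromImage(jac)

    def inverse(self) -> "DeformationField2D":
        inv = sitk.InvertDisplacementField(
            self._sitk_field(),
            maximumNumberOfIterations=50,
            meanErrorToleranceThreshold=1e-3,
            maxErrorToleranceThreshold=0.05,
            enforceBoundaryCondition=True,
        )
        return DeformationField2D(sitk.GetArrayFromImage(inv))

    def apply_to_image(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        """Warp a moving-frame image onto the fixed grid."""
        h, w = self.displacement.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        sample_x = xx + self.displacement[..., 0]
        sample_y = yy + self.displacement[..., 1]
        out = ndimage.map_coordinates(
            image.astype(float), [sample_y, sample_x], order=order, mode="constant"
        )
        if order == 0:
            out = out.astype(image.dtype)
        return out

    def _sample(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        ux = ndimage.map_coordinates(
            self.displacement[..., 0], [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
        )
        uy = ndimage.map_coordinates(
            self.displacement[..., 1], [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
        )
        return pts + np.stack([ux, uy], axis=1)

    def pull_points(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-frame points into the moving frame (``p + u(p)``)."""
        return self._sample(points)

    def push_points(
        self, points: np.ndarray, inverse_field: "DeformationField2D | None" = None
    ) -> np.ndarray:
        """Map moving-frame points onto the fixed frame (via the inverse field)."""
        inv = inverse_field if inverse_field is not None else self.inverse()
        return inv._sample(points)


@dataclass
class SliceAlignment:
    """All transforms restoring one section into block-face coordinates."""

    slice_index: int
    transforms: List[RigidTransform2D]
    part_masks: Optional[List[np.ndarray]] = None  # histology-frame masks
    deformation: Optional[DeformationField2D] = None
    provenance: Dict = field(default_factory=dict)


# -- part correspondence ---------------------------------------------------


@dataclass
class PartMatch:
    pairs: List[Tuple[int, int]]
    unmatched_hist: List[int]
    unmatched_blockface: List[int]
    costs: List[float]


def _mask_stats(mask: np.ndarray) -> Tuple[np.ndarray, float]:
    ys, xs = np.nonzero(mask)
    return np.array([xs.mean(), ys.mean()]), float(len(xs))


def match_parts(
    hist_parts: Sequence[np.ndarray],
    bf_parts: Sequence[np.ndarray],
    max_cost: Optional[float] = None,
) -> PartMatch:
    """Pair tissue parts between histology and block face.

    Cost per candidate pair is normalized centroid distance plus relative
    area mismatch; a minimum-cost assignment pairs them. Surplus parts on
    either side are reported unmatched.
    """
    if not hist_parts or not bf_parts:
        return PartMatch([], list(range(len(hist_parts))), list(range(len(bf_parts))), [])
    diag = float(np.hypot(*hist_parts[0].shape))
    hs = [_mask_stats(m) for m in hist_parts]
    bs = [_mask_stats(m) for m in bf_parts]
    cost = np.zeros((len(hs), len(bs)))
    for i, (hc, ha) in enumerate(hs):
        for j, (bc, ba) in enumerate(bs):
            cost[i, j] = np.linalg.norm(hc - bc) / diag + abs(ha - ba) / max(ha, ba)
    rows, cols = optimize.linear_sum_assignment(cost)
    pairs, costs = [], []
    for r, c in zip(rows, cols):
        if max_cost is not None and cost[r, c] > max_cost:
            continue
        pairs.append((int(r), int(c)))
        costs.append(float(cost[r, c]))
    matched_h = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return PartMatch(
        pairs,
        [i for i in range(len(hs)) if i not in matched_h],
        [j for j in range(len(bs)) if j not in matched_b],
        costs,
    )


# -- rigid registration ----------------------------------------------------


def _soft_dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a * b).sum() / denom)


def _downscale(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=factor / 2.0)
    return sm[::factor, ::factor]


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    levels: int = 4,
    allow_flip: bool = False,
    dice_floor: float = 0.8,
    smooth_sigma: float = 1.5,
    angle_scan: float = 3.0,
) -> RigidTransform2D:
    """Multiscale rigid registration of binary masks by Dice overlap.

    Coarse-to-fine (downsample factors 8/4/2/1 for ``levels=4``) Powell
    optimization of soft Dice between the warped moving mask and the fixed
    mask, initialized from centroid alignment. Because rotation and
    translation trade off along a shallow curved valley, the finest level
    finishes with an angle-marginalized scan (translation re-optimized at
    each candidate angle over ``±angle_scan`` degrees) and a simplex
    polish. Deterministic for fixed inputs. If ``allow_flip`` is set, all
    four flip hypotheses (none/H/V/HV — HV being flip plus 180 degrees)
    compete and the best final Dice wins.
    """
    moving = np.asarray(moving)
    fixed = np.asarray(fixed)
    if moving.sum() == 0 or fixed.sum() == 0:
        raise ValueError("register_rigid: empty mask")
    mov_f = ndimage.gaussian_filter(moving.astype(float), smooth_sigma)
    fix_f = ndimage.gaussian_filter(fixed.astype(float), smooth_sigma)
    center, _ = _mask_stats(moving > 0)
    fixed_centroid, _ = _mask_stats(fixed > 0)

    factors = [2 ** (levels - 1 - i) for i in range(levels)]
    pyramids = [(_downscale(mov_f, f), _downscale(fix_f, f), f) for f in factors]

    def run(flip: Flip) -> RigidTransform2D:
        def neg_dice(f, mov_l, fix_l, params) -> float:
            tf = RigidTransform2D(
                params[0],
                (params[1] / f, params[2] / f),
                flip,
                (center[0] / f, center[1] / f),
            )
            warped = tf.apply_to_image(mov_l, order=1, output_shape=fix_l.shape)
            return -_soft_dice(warped, fix_l)

        if flip == "none":
            init_t = fixed_centroid - center
        else:
            flipped_centroid = RigidTransform2D(
                0.0, (0.0, 0.0), flip, tuple(center)
            ).apply_points(center[None, :])[0]
            init_t = fixed_centroid - flipped_centroid
        x = np.array([0.0, init_t[0], init_t[1]])
        for mov_l, fix_l, f in pyramids:
            res = optimize.minimize(
                lambda p: neg_dice(f, mov_l, fix_l, p),
                x,
                method="Powell",
                options={"xtol": 1e-3, "ftol": 1e-10, "maxiter": 200},
            )
            x = res.x

        mov_l, fix_l, f = pyramids[-1]

        def tr_opt(angle, t_init):
            r = optimize.minimize(
                lambda q: neg_dice(f, mov_l, fix_l, [angle, q[0], q[1]]),
                t_init,
                method="Powell",
                options={"xtol": 1e-4, "ftol": 1e-12, "maxiter": 100},
            )
            return r.fun, r.x

        best_fun = neg_dice(f, mov_l, fix_l, x)
        best_x = x.copy()
        if angle_scan > 0:
            step = max(angle_scan / 6.0, 0.25)
            for ang in x[0] + np.arange(-angle_scan, angle_scan + step / 2, step):
                fun, tt = tr_opt(ang, best_x[1:])
                if fun < best_fun:
                    best_fun, best_x = fun, np.array([ang, tt[0], tt[1]])
            for ang in (best_x[0] - step / 2, best_x[0] + step / 2):
                fun, tt = tr_opt(ang, best_x[1:])
                if fun < best_fun:
                    best_fun, best_x = fun, np.array([ang, tt[0], tt[1]])
        res = optimize.minimize(
            lambda p: neg_dice(f, mov_l, fix_l, p),
            best_x,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-13, "maxiter": 400},
        )
        if res.fun < best_fun:
            best_x = res.x
        return RigidTransform2D(
            float(best_x[0]), (float(best_x[1]), float(best_x[2])), flip,
            (center[0], center[1]),
        )

    hypotheses: List[Flip] = ["none"]
    if allow_flip:
        hypotheses = ["none", "horizontal", "vertical"]
    best: Optional[RigidTransform2D] = None
    for flip in hypotheses:
        cand = run(flip)
        warped = cand.apply_to_image(moving.astype(float), order=1, output_shape=fixed.shape)
        cand.dice = _soft_dice((warped > 0.5).astype(float), (fixed > 0).astype(float))
        if best is None or cand.dice > best.dice:
            best = cand
    if allow_flip:
        # HV hypothesis = horizontal flip + extra 180 degrees, folded into rotation
        hv = run("horizontal")
        hv = replace(hv, rotation_deg=hv.rotation_deg + 180.0)
        warped = hv.apply_to_image(moving.astype(float), order=1, output_shape=fixed.shape)
        hv.dice = _soft_dice((warped > 0.5).astype(float), (fixed > 0).astype(float))
        if hv.dice > best.dice:
            best = hv
    assert best is not None
    best.low_quality = best.dice < dice_floor
    if best.low_quality:
        warnings.warn(
            f"register_rigid: Dice {best.dice:.3f} below floor {dice_floor}",
            stacklevel=2,
        )
    return best


# -- deformable registration -----------------------------------------------


def _level_image(arr: np.ndarray, factor: int) -> sitk.Image:
    img = sitk.GetImageFromArray(_downscale(arr, factor).astype(np.float32))
    img.SetSpacing((float(factor), float(factor)))
    return img


def register_deformable(
    moving: np.ndarray,
    fixed: np.ndarray,
    iterations: Sequence[int] = (40, 30, 20),
    smooth_sigma: float = 1.5,
    symmetric: bool = True,
) -> DeformationField2D:
    """Symmetric diffeomorphic (demons) registration, multiscale.

    Returns the displacement field warping the moving image onto the fixed
    grid; raises if the fitted field folds (non-positive Jacobian).
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape:
        raise ValueError("register_deformable: shape mismatch")
    factors = [2 ** (len(iterations) - 1 - i) for i in range(len(iterations))]
    demons = sitk.DiffeomorphicDemonsRegistrationFilter()
    if symmetric:
        demons.SetUseGradientType(demons.Symmetric)
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(smooth_sigma)
    field: Optional[sitk.Image] = None
    for factor, n_iter in zip(factors, iterations):
        f_img = _level_image(fixed, factor)
        m_img = _level_image(moving, factor)
        demons.SetNumberOfIterations(int(n_iter))
        if field is None:
            field = sitk.Image(f_img.GetSize(), sitk.sitkVectorFloat64, 2)
            field.CopyInformation(f_img)
        else:
            field = sitk.Resample(field, f_img, sitk.Transform(), sitk.sitkLinear)
        field = demons.Execute(f_img, m_img, field)
    assert field is not None
    full = sitk.GetImageFromArray(fixed.astype(np.float32))
    full.SetSpacing((1.0, 1.0))
    field = sitk.Resample(field, full, sitk.Transform(), sitk.sitkLinear)
    field.SetSpacing((1.0, 1.0))
    out = DeformationField2D(sitk.GetArrayFromImage(field))
    jac_min = float(out.jacobian_determinant().min())
    if jac_min <= 0:
        raise RuntimeError(f"register_deformable: non-positive Jacobian ({jac_min:.4f})")
    return out


# -- applying alignments ---------------------------------------------------


def apply_alignment(
    target: np.ndarray,
    alignment: SliceAlignment,
    direction: Literal["forward", "inverse"] = "forward",
    kind: Literal["image", "labels", "points"] = "image",
) -> np.ndarray:
    """Push an image, label image, or point set through a slice alignment.

    Forward maps histology-frame content into block-face coordinates.
    Multi-part slices composite each part under its own transform; points
    are routed through the transform of the part mask containing them
    (points outside every part use the first transform and are flagged by
    the caller via :func:`part_of_points`).
    """
    if direction not in ("forward", "inverse"):
        raise ValueError(f"unknown direction {direction!r}")
    order = 0 if kind == "labels" else 1

    if kind == "points":
        pts = np.atleast_2d(np.asarray(target, float))
        out = np.empty_like(pts)
        part_idx = part_of_points(pts, alignment)
        for i, tf in enumerate(alignment.transforms):
            sel = part_idx == i
            if not sel.any():
                continue
            if direction == "forward":
                mapped = tf.apply_points(pts[sel])
                if alignment.deformation is not None:
                    mapped = alignment.deformation.push_points(mapped)
            else:
                mapped = pts[sel]
                if alignment.deformation is not None:
                    mapped = alignment.deformation.pull_points(mapped)
                mapped = tf.inverse().apply_points(mapped)
            out[sel] = mapped
        return out

    composite = None
    for i, tf in enumerate(alignment.transforms):
        part = target
        if alignment.part_masks is not None and len(alignment.transforms) > 1:
            mask = alignment.part_masks[i]
            part = np.where(mask, target, 0)
        if direction == "forward":
            moved = tf.apply_to_image(part, order=order)
            if alignment.deformation is not None:
                moved = alignment.deformation.apply_to_image(moved, order=order)
        else:
            moved = part
            if alignment.deformation is not None:
                moved = alignment.deformation.inverse().apply_to_image(moved, order=order)
            moved = tf.inverse().apply_to_image(moved, order=order)
        composite = moved if composite is None else np.where(composite == 0, moved, composite)
    return composite


def part_of_points(points: np.ndarray, alignment: SliceAlignment) -> np.ndarray:
    """Index of the part mask containing each point (0 if single-part)."""
    pts = np.atleast_2d(np.asarray(points, float))
    if alignment.part_masks is None or len(alignment.transforms) == 1:
        return np.zeros(len(pts), dtype=int)
    idx = np.zeros(len(pts), dtype=int)
    for i, mask in enumerate(alignment.part_masks):
        h, w = mask.shape
        xi = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        yi = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        idx[mask[yi, xi]] = i
    return idx


# -- stack pipeline --------------------------------------------------------


def align_sections(
    histology_masks: Sequence[Sequence[np.ndarray]],
    blockface_masks: Sequence[Sequence[np.ndarray]],
    levels: int = 4,
    allow_flip: bool = False,
    deformable: bool = False,
) -> List[SliceAlignment]:
    """Register every section's tissue parts to its block-face parts.

    Inputs are per-slice lists of binary part masks (see
    ``preprocess.segment_tissue``). Returns one :class:`SliceAlignment`
    per slice with per-part rigid transforms in block-face coordinates.
    """
    if len(histology_masks) != len(blockface_masks):
        raise ValueError("slice count mismatch")
    alignments = []
    for k, (h_parts, b_parts) in enumerate(zip(histology_masks, blockface_masks)):
        match = match_parts(list(h_parts), list(b_parts))
        transforms: List[RigidTransform2D] = []
        masks: List[np.ndarray] = []
        for hi, bi in match.pairs:
            tf = register_rigid(
                h_parts[hi], b_parts[bi], levels=levels, allow_flip=allow_flip
            )
            transforms.append(tf)
            masks.append(np.asarray(h_parts[hi]) > 0)
        deform = None
        if deformable and transforms:
            moved = apply_alignment(
                (np.asarray(h_parts[0]) > 0).astype(float),
                SliceAlignment(k, transforms, masks),
                kind="image",
            )
            deform = register_deformable(moved, (np.asarray(b_parts[0]) > 0).astype(float))
        alignments.append(
            SliceAlignment(
                k,
                transforms,
                masks,
                deform,
                provenance={"unmatched_hist": match.unmatched_hist,
                            "unmatched_blockface": match.unmatched_blockface},
            )
        )
    return alignments
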