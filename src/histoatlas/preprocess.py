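"""Flat-field (shading) correction and tissue-mask extraction.

Widefield fluorescence sections carry a smooth multiplicative illumination
profile. The estimator samples random tiles across the section stack,
takes a per-pixel median of the tiles in their global positions (tissue
content averages out, illumination does not), low-passes the median with a
large-scale normalized convolution, and normalizes the field to mean 1.
Correction divides by the field. Tissue masks come from adaptive
local-mean thresholding followed by morphological cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.transform import resize

__all__ = [
    "FlatField",
    "TissueSegConfig",
    "estimate_flat_field",
    "correct_shading",
    "segment_tissue",
]


@dataclass
class FlatField:
    """Multiplicative illumination profile, strictly positive, mean 1."""

    field: np.ndarray
    tile_count: int
    tile_size: Tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        if (self.field <= 0).any():
            raise ValueError("flat field must be strictly positive")
        if abs(float(self.field.mean()) - 1.0) > 1e-6:
            raise ValueError("flat field must be normalized to mean 1")


def _polynomial_surface(values: np.ndarray, mask: np.ndarray, degree: int = 4) -> np.ndarray:
    """Least-squares 2D polynomial (total degree <= ``degree``) fit on
    ``mask`` pixels, evaluated everywhere. Extrapolates smoothly into
    rarely sampled corners, which per-pixel filters cannot."""
    h, w = values.shape
    v, u = np.mgrid[0:h, 0:w].astype(float)
    u = 2 * u / max(w - 1, 1) - 1
    v = 2 * v / max(h - 1, 1) - 1
    terms = [u**i * v**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    design = np.stack([t.ravel() for t in terms], axis=1)
    sel = mask.ravel()
    coef, *_ = np.linalg.lstsq(design[sel], values.ravel()[sel], rcond=None)
    return (design @ coef).reshape(h, w)


def estimate_flat_field(
    images: Sequence[np.ndarray],
    tile_count: int = 20,
    tile_size: Tuple[int, int] = (2040, 2040),
    seed: int = 0,
    working_size: int = 512,
    smooth_frac: float = 0.0625,
) -> FlatField:
    """Estimate the shared flat-field profile from random section tiles.

    Tiles are drawn uniformly (image and position) across the stack and
    placed back at their global coordinates; the per-pixel median across
    covering tiles is low-passed with a Gaussian of width
    ``smooth_frac × min(H, W)`` via normalized convolution (which also
    fills uncovered pixels), computed at ``working_size`` resolution and
    resized to full frame. Deterministic per seed.
    """
    if not images:
        raise ValueError("need at least one image")
    imgs = [np.asarray(im, float) for im in images]
    h, w = imgs[0].shape
    th, tw = int(tile_size[0]), int(tile_size[1])
    if th > h or tw > w:
        raise ValueError(
            f"tile size {tile_size} does not fit inside images of shape {(h, w)}; "
            "fewer tiles available than requested"
        )
    rng = np.random.default_rng(seed)
    stack = np.full((tile_count, h, w), np.nan, dtype=np.float32)
    for t in range(tile_count):
        src = imgs[int(rng.integers(0, len(imgs)))]
        y0 = int(rng.integers(0, h - th + 1))
        x0 = int(rng.integers(0, w - tw + 1))
        stack[t, y0 : y0 + th, x0 : x0 + tw] = src[y0 : y0 + th, x0 : x0 + tw]
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    covered = np.isfinite(med)
    if not covered.any():
        raise ValueError("tiles cover no pixels")
    med[~covered] = 0.0

    factor = max(1, int(np.ceil(min(h, w) / working_size)))
    med_s = med[::factor, ::factor]
    cov_s = covered[::factor, ::factor]
    sigma = smooth_frac * min(med_s.shape)
    smooth = _polynomial_surface(med_s, cov_s, degree=4)
    # mild residual low-pass of the covered median around the surface keeps
    # genuine smooth structure the polynomial misses
    resid = np.where(cov_s, med_s - smooth, 0.0)
    num = ndimage.gaussian_filter(resid, sigma)
    den = ndimage.gaussian_filter(cov_s.astype(float), sigma)
    smooth = smooth + np.where(den > 0.05, num / np.clip(den, 0.05, None), 0.0)
    fld = resize(smooth, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    fld = np.clip(fld, 1e-6, None)
    fld = fld / fld.mean()
    return FlatField(field=fld, tile_count=tile_count, tile_size=(th, tw), seed=seed)


def correct_shading(
    image: np.ndarray, flat_field: FlatField, preserve_mean: bool = True
) -> np.ndarray:
    """Divide out the illumination profile: ``corrected = image / field``.

    The field is resized to the image if shapes differ. With
    ``preserve_mean`` the output is rescaled to the input's global mean,
    so correction commutes with global intensity scaling exactly.
    """
    image = np.asarray(image, float)
    fld = flat_field.field
    if fld.shape != image.shape:
        fld = resize(fld, image.shape, order=1, preserve_range=True, anti_aliasing=False)
        fld = np.clip(fld, 1e-6, None)
    if (fld <= 0).any():
        raise ValueError("flat field contains non-positive values")
    out = image / fld
    if preserve_mean and out.mean() > 0:
        out = out * (image.mean() / out.mean())
    return out


@dataclass
class TissueSegConfig:
    """Adaptive-threshold tissue segmentation parameters.

    ``window`` defaults to 1/8 of the image's smaller dimension (odd).
    ``offset_frac`` is the threshold offset as a fraction of the robust
    intensity range (1st–99th percentile).
    """

    window: Optional[int] = None
    offset_frac: float = 0.05
    closing_radius: int = 2
    fill_holes: bool = True


def segment_tissue(
    image: np.ndarray,
    min_area: int = 64,
    config: Optional[TissueSegConfig] = None,
) -> List[np.ndarray]:
    """Binary masks of disjoint tissue parts, largest first.

    Adaptive local-mean threshold → morphological closing → hole filling →
    connected components of at least ``min_area`` pixels. An empty list is
    a valid result for a blank image.
    """
    if config is None:
        config = TissueSegConfig()
    img = np.asarray(image, float)
    if img.ndim == 3:  # multichannel: segment on the channel mean
        img = img.mean(axis=0)
    lo, hi = np.percentile(img, [1, 99])
    rng_val = hi - lo
    if rng_val <= 0:
        return []
    window = config.window or max(3, (min(img.shape) // 8) | 1)
    local_mean = ndimage.uniform_filter(img, size=window)
    mask = img > local_mean + config.offset_frac * rng_val
    # adaptive thresholding alone marks bright-vs-local pixels; also require
    # the pixel to sit above the global background floor
    mask &= img > lo + 0.25 * rng_val
    if config.closing_radius > 0:
        mask = ndimage.binary_closing(
            mask, structure=morphology.disk(config.closing_radius)
        )
    if config.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labeled = measure.label(mask, connectivity=2)
    parts = []
    for region in measure.regionprops(labeled):
        if region.area >= min_area:
            parts.append(labeled == region.label)
    parts.sort(key=lambda m: m.sum(), reverse=True)
    return parts
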