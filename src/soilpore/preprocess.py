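"""Image conditioning for µCT scans.

The chain mirrors standard intact-core practice and runs in a fixed order:

1. :func:`remove_background` — fit and subtract a global third-degree
   polynomial to cancel smooth scanner shading, then rescale back to the
   original intensity range;
2. :func:`median_filter_3d` — 3D median over a 5×5×5 cube (two-voxel
   radius) to suppress shot noise without blurring phase boundaries;
3. :func:`enhance_contrast` — linear stretch saturating 0.6% of voxels
   split evenly between the tails;
4. :func:`crop_roi` — cut the central region of interest, away from
   ring artifacts near the core wall.

All steps preserve shape (until the crop), voxel size and bit depth.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy import ndimage

from . import _poly
from .volume import GrayscaleVolume

__all__ = [
    "remove_background",
    "median_filter_3d",
    "enhance_contrast",
    "crop_roi",
    "preprocess_chain",
]

log = logging.getLogger(__name__)


def remove_background(v: GrayscaleVolume, degree: int = 3) -> GrayscaleVolume:
    """Subtract a fitted global polynomial trend and restore the range.

    A trivariate polynomial of total degree ``degree`` is least-squares
    fitted to the intensities over (normalized) voxel coordinates, on a
    regular decimated sub-grid for speed; the fitted field is subtracted
    and the residual adjusted back to the original brightness scale by an
    affine map of unit slope (a shift restoring the original global mean —
    stretching the residual to the original min/max would amplify noise
    whenever the fit explains nearly all of the variation).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    data = v.voxels.astype(np.float64)
    coeffs, step = _poly.fit_field(data, degree)
    log.info("background fit: degree=%d decimation=%d", degree, step)
    resid = data - _poly.evaluate_field(v.shape, coeffs, degree)
    out = resid - resid.mean() + data.mean()
    return v.like(out, background_degree=degree, background_decimation=step)


def median_filter_3d(v: GrayscaleVolume, radius_vox: int = 2) -> GrayscaleVolume:
    """3D median filter over a cube of half-width ``radius_vox``.

    The neighborhood is the full (2r+1)³ cube ("radius in all directions"),
    with reflected edges.
    """
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    size = 2 * radius_vox + 1
    out = ndimage.median_filter(v.voxels, size=size, mode="reflect")
    return GrayscaleVolume(out, v.voxel_size_um, v.bit_depth, {**v.meta, "median_radius": radius_vox})


def enhance_contrast(v: GrayscaleVolume, saturated_pct: float = 0.6) -> GrayscaleVolume:
    """Linear contrast stretch saturating ``saturated_pct`` % of voxels.

    The per-tail clip count is ``floor(saturated_pct/2 % of N)``; the cut
    intensities are the corresponding order statistics, and the map is the
    monotone affine stretch of [low_cut, high_cut] onto the full bit-depth
    range, clipping everything beyond.  Ties at a cut intensity are all
    treated alike, so the result is independent of voxel order.
    """
    if not (0 <= saturated_pct < 100):
        raise ValueError("saturated_pct must be in [0, 100)")
    flat = v.voxels.ravel()
    n = flat.size
    k = int(math.floor(saturated_pct / 100.0 / 2.0 * n))
    lo = float(np.partition(flat, k)[k])
    hi = float(np.partition(flat, n - 1 - k)[n - 1 - k])
    if hi <= lo:
        warnings.warn("enhance_contrast: degenerate (constant) volume; returned unchanged")
        return GrayscaleVolume(v.voxels.copy(), v.voxel_size_um, v.bit_depth, dict(v.meta))
    out = (v.voxels.astype(np.float64) - lo) * (v.max_value / (hi - lo))
    return v.like(out, saturated_pct=saturated_pct)


def crop_roi(
    v: GrayscaleVolume,
    size_vox: tuple[int, int, int],
    anchor: "str | tuple[int, int, int]" = "centered",
) -> GrayscaleVolume:
    """Cut a sub-volume; the offset used is recorded in ``meta['roi_offset']``.

    ``anchor`` is either ``"centered"`` or an explicit (z, y, x) offset.
    """
    size = tuple(int(s) for s in size_vox)
    if any(s <= 0 for s in size):
        raise ValueError(f"ROI size must be positive, got {size}")
    if any(s > n for s, n in zip(size, v.shape)):
        raise ValueError(f"ROI size {size} exceeds volume shape {v.shape}")
    if anchor == "centered":
        offset = tuple((n - s) // 2 for s, n in zip(size, v.shape))
    else:
        offset = tuple(int(o) for o in anchor)
        if any(o < 0 or o + s > n for o, s, n in zip(offset, size, v.shape)):
            raise ValueError(f"ROI at offset {offset} with size {size} exceeds shape {v.shape}")
    sl = tuple(slice(o, o + s) for o, s in zip(offset, size))
    return GrayscaleVolume(
        v.voxels[sl].copy(), v.voxel_size_um, v.bit_depth, {**v.meta, "roi_offset": offset}
    )


def preprocess_chain(
    v: GrayscaleVolume,
    degree: int = 3,
    median_radius: int = 2,
    saturated_pct: float = 0.6,
    roi_size_vox: "tuple[int, int, int] | None" = None,
) -> GrayscaleVolume:
    """The full fixed-order conditioning chain.

    Order: background removal → median filter → contrast enhancement →
    (optional) centered ROI crop.  Each stage logs its parameters.
    """
    out = remove_background(v, degree=degree)
    out = median_filter_3d(out, radius_vox=median_radius)
    out = enhance_contrast(out, saturated_pct=saturated_pct)
    if roi_size_vox is not None:
        out = crop_roi(out, roi_size_vox, anchor="centered")
    log.info(
        "preprocess chain: degree=%d median_radius=%d saturate=%.3f roi=%s",
        degree, median_radius, saturated_pct, roi_size_vox,
    )
    return out
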