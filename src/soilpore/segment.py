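"""Solid/pore/stone segmentation.

The solid/pore step follows the indicator-kriging family of two-threshold
schemes: voxels darker than ``t_low`` are certainly pore, brighter than
``t_high`` certainly solid, and voxels in the ambiguous band are resolved
by an inverse-distance-weighted vote of already-classified voxels inside a
local window that grows until every voxel is decided.  The procedure is
deterministic and, unlike a kriging system solve, exactly reproducible by
a brute-force vote on small instances.

Stones (gravel) are bright 26-connected components above a grayscale
threshold; only components larger than 10 mm³ count as stones, and
:func:`stone_free_basis` removes them from every downstream denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import GrayscaleVolume, Phase, PhaseMask

__all__ = [
    "SegmentationParams",
    "auto_thresholds",
    "segment_solid_pore",
    "segment_stones",
    "stone_free_basis",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Thresholds and window sizes for the segmentation stage.

    ``t_low``/``t_high`` bound the ambiguous grayscale band (``None`` =
    derive both from the Otsu threshold ± ``otsu_k``·within-class-sd);
    ``window_vox`` is the initial half-width of the voting window;
    ``stone_t`` the stone brightness threshold (``None`` = midpoint of
    ``t_high`` and the intensity maximum); ``stone_min_volume_mm3`` the
    minimum volume for a bright component to count as stone.
    """

    t_low: float | None = None
    t_high: float | None = None
    window_vox: int = 2
    stone_t: float | None = None
    stone_min_volume_mm3: float = 10.0
    otsu_k: float = 0.5

    def validate(self, max_value: int) -> None:
        if self.t_low is not None and self.t_high is not None and self.t_low > self.t_high:
            raise ValueError(f"t_low ({self.t_low}) > t_high ({self.t_high})")
        for name in ("t_low", "t_high", "stone_t"):
            t = getattr(self, name)
            if t is not None and not (0 <= t <= max_value):
                raise ValueError(f"{name}={t} outside [0, {max_value}]")
        if self.window_vox < 1:
            raise ValueError("window_vox must be >= 1")


def auto_thresholds(v: GrayscaleVolume, k: float = 0.5) -> tuple[float, float]:
    """Automatic ambiguous band: class-mean midpoint ± k × within-class sd.

    The Otsu threshold partitions the histogram into two classes, but with
    very unequal class sizes and tight modes it sits at the edge of the
    smaller (pore) mode rather than between the modes — a band centered
    there would swallow the whole pore class.  The band is therefore
    centered at the midpoint of the two class means, with half-width
    ``k`` × the pooled within-class standard deviation; the Otsu partition
    supplies the class statistics.  Fully deterministic.
    """
    data = v.voxels
    t = float(threshold_otsu(data))
    lo_cls = data[data <= t]
    hi_cls = data[data > t]
    if lo_cls.size == 0 or hi_cls.size == 0:
        return t, t
    w0 = lo_cls.size / data.size
    w1 = hi_cls.size / data.size
    s_within = float(np.sqrt(w0 * lo_cls.var() + w1 * hi_cls.var()))
    center = 0.5 * (float(lo_cls.mean()) + float(hi_cls.mean()))
    return max(0.0, center - k * s_within), min(float(v.max_value), center + k * s_within)


def _vote_kernel(window: int) -> np.ndarray:
    """Inverse-Euclidean-distance weights over the (2w+1)³ window, 0 at center."""
    ax = np.arange(-window, window + 1, dtype=np.float64)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    d = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    with np.errstate(divide="ignore"):
        k = np.where(d > 0, 1.0 / d, 0.0)
    return k


def segment_solid_pore(v: GrayscaleVolume, p: SegmentationParams | None = None) -> PhaseMask:
    """Two-threshold segmentation with locally voted ambiguous voxels.

    Voxels with intensity < ``t_low`` are pore, > ``t_high`` solid; voxels
    in ``[t_low, t_high]`` are assigned by an inverse-distance-weighted
    vote of classified voxels inside a Chebyshev window of half-width
    ``window_vox``, iterated (window growing by one whenever an iteration
    decides nothing) until none remain.  Pore wins ties.
    """
    p = p or SegmentationParams()
    p.validate(v.max_value)
    t_low, t_high = p.t_low, p.t_high
    if t_low is None or t_high is None:
        a_lo, a_hi = auto_thresholds(v, p.otsu_k)
        t_low = a_lo if t_low is None else t_low
        t_high = a_hi if t_high is None else t_high
        log.info("auto thresholds: t_low=%.2f t_high=%.2f", t_low, t_high)
    if t_low > t_high:
        raise ValueError(f"t_low ({t_low}) > t_high ({t_high})")

    data = v.voxels
    pore = data < t_low
    solid = data > t_high
    unknown = ~pore & ~solid
    window = p.window_vox
    while unknown.any():
        kernel = _vote_kernel(window)
        pore_score = ndimage.correlate(pore.astype(np.float32), kernel.astype(np.float32), mode="constant")
        solid_score = ndimage.correlate(solid.astype(np.float32), kernel.astype(np.float32), mode="constant")
        decided = unknown & ((pore_score > 0) | (solid_score > 0))
        if not decided.any():
            window += 1
            continue
        pore |= decided & (pore_score >= solid_score)
        solid |= decided & (pore_score < solid_score)
        unknown &= ~decided

    labels = np.where(pore, Phase.PORE.value, Phase.SOLID.value).astype(np.uint8)
    return PhaseMask(labels, v.voxel_size_um, {"t_low": float(t_low), "t_high": float(t_high)})


def segment_stones(
    v: GrayscaleVolume,
    p: SegmentationParams | None = None,
    base: PhaseMask | None = None,
) -> PhaseMask:
    """Label bright stone components, returning (or updating) a phase mask.

    Voxels above ``stone_t`` are grouped into 26-connected components;
    components strictly larger than ``stone_min_volume_mm3`` become stone,
    smaller bright specks stay solid.  Per-stone volumes land in
    ``mask.meta['stone_volumes_mm3']`` (descending).
    """
    p = p or SegmentationParams()
    p.validate(v.max_value)
    stone_t = p.stone_t
    if stone_t is None:
        t_high = base.meta.get("t_high") if base is not None else None
        if t_high is None:
            t_high = auto_thresholds(v, p.otsu_k)[1]
        stone_t = (float(t_high) + v.max_value) / 2.0
        log.info("auto stone threshold: %.2f", stone_t)

    if base is None:
        labels = np.full(v.shape, Phase.SOLID.value, dtype=np.uint8)
    else:
        if base.shape != v.shape:
            raise ValueError(f"mask shape {base.shape} != volume shape {v.shape}")
        labels = base.labels.copy()

    bright = v.voxels > stone_t
    comp, n = ndimage.label(bright, structure=_STRUCT26)
    voxvol = v.voxel_volume_mm3
    volumes = []
    if n:
        counts = np.bincount(comp.ravel())[1:]
        keep_ids = np.flatnonzero(counts * voxvol > p.stone_min_volume_mm3) + 1
        volumes = sorted((counts[i - 1] * voxvol for i in keep_ids), reverse=True)
        if len(keep_ids):
            stone_mask = np.isin(comp, keep_ids)
            labels[stone_mask] = Phase.STONE.value

    meta = dict(base.meta) if base is not None else {}
    meta.update(
        stone_t=float(stone_t),
        stone_min_volume_mm3=p.stone_min_volume_mm3,
        stone_volumes_mm3=[float(x) for x in volumes],
        stone_voxel_count=int((labels == Phase.STONE.value).sum()),
    )
    return PhaseMask(labels, v.voxel_size_um, meta)


def stone_free_basis(mask: PhaseMask) -> PhaseMask:
    """Relabel stone voxels as excluded so every fraction uses the
    stone-free denominator (total voxels − excluded voxels)."""
    out = mask.copy()
    out.labels[out.labels == Phase.STONE.value] = Phase.EXCLUDED.value
    out.meta["stone_free"] = True
    return out
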