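"""Particulate organic matter: segmentation, decomposition, and context.

POM appears in soil µCT scans as fragments of intermediate grayscale
between pore and mineral matrix.  Segmentation band-thresholds a calibrated
grayscale window, cleans boundary misclassifications with a morphological
opening and a Gaussian re-threshold, and keeps 26-connected fragments
strictly larger than 0.018 mm³.

Decomposition between a co-registered before/after scan pair is the
fractional voxel loss

    loss % = (1 − A_a / A_b) × 100,

with A_b and A_a the POM voxel counts expressed as percent of the shared
stone-free reference volume, so the ratio is a pure voxel-count ratio.
Context analyses report the pore fraction inside distance shells (1, 5,
8 mm) around each fragment and the minimum Euclidean distance to roots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import GrayscaleVolume

__all__ = [
    "PomFragment",
    "PomSegmentation",
    "PomChange",
    "ShellProfile",
    "MIN_POM_VOLUME_MM3",
    "calibrate_pom_thresholds",
    "segment_pom",
    "match_fragments",
    "pom_loss",
    "compare_pom",
    "shell_pore_fraction",
    "root_distance",
]

log = logging.getLogger(__name__)

#: Fragments at or below this volume are discarded (strictly-greater rule).
MIN_POM_VOLUME_MM3 = 0.018

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PomFragment:
    """One segmented POM fragment."""

    id: int
    voxel_count: int
    volume_mm3: float
    centroid_um: tuple[float, float, float]
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    mean_gray: float


@dataclass
class PomSegmentation:
    """Fragment table plus the label volume that gives each voxel's fragment id."""

    fragments: list[PomFragment]
    labels: np.ndarray
    voxel_size_um: float

    def fragment_mask(self, fragment_id: int) -> np.ndarray:
        return self.labels == fragment_id

    def by_id(self, fragment_id: int) -> PomFragment:
        for f in self.fragments:
            if f.id == fragment_id:
                return f
        raise KeyError(f"no fragment with id {fragment_id}")


@dataclass
class PomChange:
    """Decomposition of one fragment between paired scans."""

    fragment_id: int
    a_b_pct: float
    a_a_pct: float
    loss_pct: float
    status: str = "matched"  # matched | unmatched_before | unmatched_after


@dataclass
class ShellProfile:
    """Pore fraction in nested distance shells around one fragment."""

    fragment_id: int
    shell_distances_mm: tuple[float, ...]
    pore_fraction_per_shell: list[float]
    truncation_fraction_per_shell: list[float]
    pore_fraction_per_shell_by_size_bin: "dict[tuple[float, float], list[float]] | None" = None


def calibrate_pom_thresholds(
    v: GrayscaleVolume, fragment_seeds: "list[np.ndarray]"
) -> tuple[float, float]:
    """Derive the POM grayscale band from marked representative fragments.

    ``fragment_seeds`` are boolean masks (one per marked region).  The band
    is (mean of per-region minima, mean of per-region maxima) — averaging
    tames the outlier sensitivity of a single fragment's extremes.
    """
    if not fragment_seeds:
        raise ValueError("need at least one marked fragment region")
    mins, maxs = [], []
    for i, region in enumerate(fragment_seeds):
        region = np.asarray(region, dtype=bool)
        if region.shape != v.shape:
            raise ValueError(f"region {i} shape {region.shape} != volume shape {v.shape}")
        vals = v.voxels[region]
        if vals.size == 0:
            raise ValueError(f"marked region {i} is empty")
        mins.append(float(vals.min()))
        maxs.append(float(vals.max()))
    return float(np.mean(mins)), float(np.mean(maxs))


def segment_pom(
    v: GrayscaleVolume,
    t_low: float,
    t_high: float,
    open_steps: int = 2,
    gauss_sigma_vox: float = 1.0,
    min_volume_mm3: float = MIN_POM_VOLUME_MM3,
    exclude: "np.ndarray | None" = None,
) -> PomSegmentation:
    """Segment POM fragments from a grayscale band.

    Steps: band threshold ``[t_low, t_high]`` → ``open_steps`` erosions then
    ``open_steps`` dilations (6-connected radius-1 ball) to strip boundary
    misclassifications → Gaussian smoothing of the binary field re-thresholded
    at 0.5 → 26-connected components → discard components ≤ ``min_volume_mm3``
    (strictly-greater rule).  Fragments are ordered by volume descending,
    ties by centroid lexicographic order; ids are 1-based in that order.
    ``exclude`` (e.g. the stone mask) removes voxels from the band first.
    """
    if t_low > t_high:
        raise ValueError(f"t_low ({t_low}) > t_high ({t_high})")
    band = (v.voxels >= t_low) & (v.voxels <= t_high)
    if exclude is not None:
        band &= ~np.asarray(exclude, dtype=bool)
    if open_steps > 0 and band.any():
        band = ndimage.binary_erosion(band, _STRUCT6, iterations=open_steps, border_value=0)
        if band.any():
            band = ndimage.binary_dilation(band, _STRUCT6, iterations=open_steps, border_value=0)
    if gauss_sigma_vox > 0 and band.any():
        band = ndimage.gaussian_filter(band.astype(np.float32), gauss_sigma_vox) >= 0.5

    comp, n = ndimage.label(band, structure=_STRUCT26)
    voxvol = v.voxel_volume_mm3
    frags: list[PomFragment] = []
    keep: list[tuple[int, int]] = []  # (component id, voxel count)
    if n:
        counts = np.bincount(comp.ravel())
        for cid in range(1, n + 1):
            if counts[cid] * voxvol > min_volume_mm3:
                keep.append((cid, int(counts[cid])))

    centroids = ndimage.center_of_mass(band, comp, [cid for cid, _ in keep]) if keep else []
    objects = ndimage.find_objects(comp)
    order = []
    for (cid, cnt), cen in zip(keep, centroids):
        cen_um = tuple(float(c) * v.voxel_size_um for c in cen)
        order.append((-cnt, cen_um, cid))
    order.sort()

    labels = np.zeros(v.shape, dtype=np.int32)
    for new_id, (neg_cnt, cen_um, cid) in enumerate(order, start=1):
        sel = comp == cid
        labels[sel] = new_id
        sl = objects[cid - 1]
        frags.append(
            PomFragment(
                id=new_id,
                voxel_count=-neg_cnt,
                volume_mm3=-neg_cnt * voxvol,
                centroid_um=cen_um,
                bbox=tuple((s.start, s.stop) for s in sl),
                mean_gray=float(v.voxels[sel].mean()),
            )
        )
    log.info("segment_pom: %d components, %d kept (> %.4f mm3)", n, len(frags), min_volume_mm3)
    return PomSegmentation(frags, labels, v.voxel_size_um)


def match_fragments(
    before: PomSegmentation,
    after: PomSegmentation,
    max_dist_mm: float = 0.5,
) -> list[tuple["PomFragment | None", "PomFragment | None"]]:
    """Pair fragments across co-registered scans by nearest centroid.

    Greedy on ascending centroid distance, injective, capped at
    ``max_dist_mm``.  Unmatched fragments from either scan appear with
    ``None`` on the other side.
    """
    pairs = []
    for fb in before.fragments:
        for fa in after.fragments:
            d_mm = (
                np.linalg.norm(np.subtract(fb.centroid_um, fa.centroid_um)) * 1e-3
            )
            if d_mm <= max_dist_mm:
                pairs.append((d_mm, fb.id, fa.id))
    pairs.sort()
    used_b, used_a, matched = set(), set(), []
    for d, bid, aid in pairs:
        if bid in used_b or aid in used_a:
            continue
        used_b.add(bid)
        used_a.add(aid)
        matched.append((before.by_id(bid), after.by_id(aid)))
    for fb in before.fragments:
        if fb.id not in used_b:
            matched.append((fb, None))
    for fa in after.fragments:
        if fa.id not in used_a:
            matched.append((None, fa))
    return matched


def pom_loss(n_before: int, n_after: int, reference_voxels: int, fragment_id: int = 0) -> PomChange:
    """Decomposed fraction of one fragment: (1 − A_a/A_b) × 100.

    Both areas are percent of the same ``reference_voxels`` (the shared
    stone-free ROI voxel count of the before scan), so the ratio is
    scale-free.
    """
    if reference_voxels <= 0:
        raise ValueError("reference_voxels must be > 0")
    if n_before <= 0:
        raise ValueError("A_b must be > 0 (fragment absent from the before scan)")
    a_b = 100.0 * n_before / reference_voxels
    a_a = 100.0 * n_after / reference_voxels
    return PomChange(fragment_id, a_b, a_a, (1.0 - a_a / a_b) * 100.0)


def compare_pom(
    before: PomSegmentation,
    after: PomSegmentation,
    reference_voxels: int,
    max_dist_mm: float = 0.5,
) -> list[PomChange]:
    """Per-fragment decomposition for a matched before/after pair.

    A before-fragment with no partner is reported as 100% loss with status
    ``unmatched_after`` (it shrank below detectability or decomposed
    entirely); an after-only fragment is reported with status
    ``unmatched_before`` and NaN loss — never silently dropped.
    """
    out = []
    for fb, fa in match_fragments(before, after, max_dist_mm):
        if fb is not None and fa is not None:
            change = pom_loss(fb.voxel_count, fa.voxel_count, reference_voxels, fb.id)
            out.append(change)
        elif fb is not None:
            change = pom_loss(fb.voxel_count, 0, reference_voxels, fb.id)
            change.status = "unmatched_after"
            out.append(change)
        else:
            out.append(
                PomChange(fa.id, 0.0, 100.0 * fa.voxel_count / reference_voxels,
                          float("nan"), status="unmatched_before")
            )
    return out


def shell_pore_fraction(
    fragment_mask: np.ndarray,
    pore_mask: np.ndarray,
    voxel_size_um: float,
    distances_mm: tuple[float, ...] = (1.0, 5.0, 8.0),
    excluded_mask: "np.ndarray | None" = None,
    thickness_um: "np.ndarray | None" = None,
    size_bins_um: "list[tuple[float, float]] | None" = None,
    fragment_id: int = 0,
) -> ShellProfile:
    """Pore fraction within distance shells around one fragment.

    For each distance d the layer is every voxel with Euclidean distance to
    the fragment in (0, d·1000/voxel_size] voxels, excluding the fragment
    itself and excluded (stone) voxels; the fraction is pore voxels in the
    layer over layer voxels.  Layers are nested by construction.  For
    fragments near the volume boundary the layer is truncated; the reported
    truncation fraction is the share of the ideal (unbounded-grid) layer
    lying outside the volume.

    With ``thickness_um`` (local pore radius per voxel) and ``size_bins_um``
    the fraction is additionally restricted to pore voxels whose local
    radius falls in each inclusive [lo, hi] bin.
    """
    fragment_mask = np.asarray(fragment_mask, dtype=bool)
    pore_mask = np.asarray(pore_mask, dtype=bool)
    if fragment_mask.shape != pore_mask.shape:
        raise ValueError("fragment and pore masks must be co-registered")
    if not fragment_mask.any():
        raise ValueError("empty fragment mask")
    if list(distances_mm) != sorted(distances_mm):
        raise ValueError("distances_mm must be ascending")
    dist_vox = ndimage.distance_transform_edt(~fragment_mask)
    valid = ~fragment_mask
    if excluded_mask is not None:
        valid &= ~np.asarray(excluded_mask, dtype=bool)

    d_vox_max = max(distances_mm) * 1000.0 / voxel_size_um
    trunc_dist = None
    if _touches_boundary(fragment_mask, d_vox_max):
        pad = int(np.ceil(d_vox_max)) + 1
        trunc_dist = ndimage.distance_transform_edt(~np.pad(fragment_mask, pad))

    fractions, truncations = [], []
    by_bin: dict[tuple[float, float], list[float]] = {
        tuple(b): [] for b in (size_bins_um or [])
    }
    for d_mm in distances_mm:
        d_vox = d_mm * 1000.0 / voxel_size_um
        layer = valid & (dist_vox > 0) & (dist_vox <= d_vox)
        n_layer = int(layer.sum())
        fractions.append(float((pore_mask & layer).sum()) / n_layer if n_layer else 0.0)
        if trunc_dist is not None:
            full = int(((trunc_dist > 0) & (trunc_dist <= d_vox)).sum())
            inside = int(((dist_vox > 0) & (dist_vox <= d_vox)).sum())
            truncations.append((full - inside) / full if full else 0.0)
        else:
            truncations.append(0.0)
        for bin_range in by_bin:
            lo, hi = bin_range
            if thickness_um is None:
                raise ValueError("size_bins_um requires thickness_um")
            in_bin = pore_mask & layer & (thickness_um >= lo) & (thickness_um <= hi)
            by_bin[bin_range].append(float(in_bin.sum()) / n_layer if n_layer else 0.0)

    return ShellProfile(
        fragment_id=fragment_id,
        shell_distances_mm=tuple(distances_mm),
        pore_fraction_per_shell=fractions,
        truncation_fraction_per_shell=truncations,
        pore_fraction_per_shell_by_size_bin=by_bin if size_bins_um else None,
    )


def _touches_boundary(mask: np.ndarray, margin_vox: float) -> bool:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    return bool((lo < margin_vox).any() or ((np.array(mask.shape) - 1 - hi) < margin_vox).any())


def root_distance(
    pom: PomSegmentation, root_mask: np.ndarray
) -> dict[int, "float | None"]:
    """Minimum Euclidean distance (mm) from each fragment to the root phase.

    An empty root mask yields ``None`` for every fragment (undefined, not
    infinite — the scan simply shows no roots).
    """
    root_mask = np.asarray(root_mask, dtype=bool)
    if root_mask.shape != pom.labels.shape:
        raise ValueError("root mask must be co-registered with the POM labels")
    if not root_mask.any():
        return {f.id: None for f in pom.fragments}
    dist_vox = ndimage.distance_transform_edt(~root_mask)
    out = {}
    for f in pom.fragments:
        sel = pom.labels == f.id
        out[f.id] = float(dist_vox[sel].min()) * pom.voxel_size_um * 1e-3
    return out
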