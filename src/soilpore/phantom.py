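"""Synthetic soil-core phantoms with exact ground truth.

Intact-core X-ray µCT scans cannot be redistributed, so every stage of the
pipeline is exercised on generated volumes that emulate what such a scan
contains: a solid mineral matrix, a pore network (spheres and channels)
spanning realistic visible porosity, bright stone inclusions, intermediate-
intensity particulate organic matter (POM) fragments, optional root tubes,
a smooth multiplicative shading field, and additive Gaussian noise.

The generator rasterizes phases on the voxel-center grid, records the exact
label volume as ground truth, and only then renders intensities — so the
truth is never corrupted by the imaging model.  A paired "after growth"
volume is produced by :func:`degrade_pom`, which peels a prescribed voxel
fraction off selected POM fragments from the surface inward, mimicking
microbial decomposition fronts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import _poly
from .volume import GrayscaleVolume, Phase, PhaseMask

__all__ = [
    "SphereSpec",
    "ChannelSpec",
    "EllipsoidSpec",
    "PomBlobSpec",
    "RootSpec",
    "IntensityModel",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "degrade_pom",
    "standard_core_spec",
    "pom_study_spec",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SphereSpec:
    """Spherical pore: center in voxel coordinates (z, y, x), radius in µm."""

    center: tuple[float, float, float]
    radius_um: float


@dataclass
class ChannelSpec:
    """Cylindrical pore channel between two endpoints (voxel coords)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_um: float


@dataclass
class EllipsoidSpec:
    """Axis-aligned ellipsoidal stone; semi-axes in µm."""

    center: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]


@dataclass
class PomBlobSpec:
    """POM fragment grown from a seed voxel to a target volume.

    ``mean_gray`` overrides the intensity model's POM mean for this fragment
    (POM contrast varies with decomposition state in real scans).
    """

    seed_point: tuple[int, int, int]
    volume_mm3: float
    mean_gray: float | None = None


@dataclass
class RootSpec:
    """Root as a tube swept along a polyline of voxel-coordinate points."""

    points: Sequence[tuple[float, float, float]]
    radius_um: float


@dataclass
class IntensityModel:
    """Mean grayscale per phase plus additive noise, 8-bit defaults.

    X-ray attenuation orders the phases pore < POM < matrix < stone; roots
    are fresh organic tissue and sit between pore and POM.
    """

    pore: float = 60.0
    pom: float = 110.0
    matrix: float = 160.0
    stone: float = 230.0
    root: float = 90.0
    noise_sd: float = 8.0

    def validate(self) -> None:
        if not (self.pore < self.pom < self.matrix < self.stone):
            raise ValueError(
                "phase mean intensities must be strictly ordered pore < POM < matrix < stone, "
                f"got pore={self.pore}, pom={self.pom}, matrix={self.matrix}, stone={self.stone}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def mean_of(self, phase: Phase) -> float:
        return {
            Phase.PORE: self.pore,
            Phase.SOLID: self.matrix,
            Phase.STONE: self.stone,
            Phase.POM: self.pom,
            Phase.ROOT: self.root,
        }[phase]


# Mild default shading: a degree-3 field with ~±4% multiplicative amplitude,
# the magnitude of residual shadowing left by cone-beam scanners.
_DEFAULT_SHADING = {
    (0, 0, 0): 1.0,
    (1, 0, 0): 0.015,
    (0, 1, 0): -0.012,
    (0, 0, 1): 0.010,
    (2, 0, 0): -0.015,
    (0, 1, 1): 0.008,
    (0, 0, 3): 0.006,
}


@dataclass
class PhantomSpec:
    """Full recipe for one synthetic core volume."""

    shape: tuple[int, int, int]
    voxel_size_um: float = 18.2
    pore_spheres: list[SphereSpec] = field(default_factory=list)
    pore_channels: list[ChannelSpec] = field(default_factory=list)
    stones: list[EllipsoidSpec] = field(default_factory=list)
    pom_fragments: list[PomBlobSpec] = field(default_factory=list)
    roots: list[RootSpec] = field(default_factory=list)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    shading_coeffs: dict[tuple[int, int, int], float] | None = field(
        default_factory=lambda: dict(_DEFAULT_SHADING)
    )
    bit_depth: int = 8
    seed: int = 0
    structure_seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        for s in self.pore_spheres:
            if s.radius_um <= 0:
                raise ValueError(f"pore sphere radius must be > 0, got {s.radius_um}")
        for c in self.pore_channels:
            if c.radius_um <= 0:
                raise ValueError(f"channel radius must be > 0, got {c.radius_um}")
        for e in self.stones:
            if any(a <= 0 for a in e.semi_axes_um):
                raise ValueError(f"stone semi-axes must be > 0, got {e.semi_axes_um}")
        for b in self.pom_fragments:
            if b.volume_mm3 <= 0:
                raise ValueError(f"POM target volume must be > 0, got {b.volume_mm3}")
        for r in self.roots:
            if r.radius_um <= 0 or len(r.points) < 2:
                raise ValueError("roots need >= 2 polyline points and radius > 0")
        self.intensity.validate()

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3


@dataclass
class GroundTruth:
    """Exact phase labels and derived reference quantities for a phantom.

    ``pom_fragment_labels`` carries one positive integer id per POM voxel
    (0 elsewhere) so fragments keep their identity across a before/after
    pair; ``pom_ids_with_loss`` maps those ids to the prescribed decomposed
    voxel fraction (empty for a freshly generated "before" volume).
    """

    phase_mask: PhaseMask
    true_visible_porosity: float
    pom_fragment_labels: np.ndarray
    pom_ids_with_loss: dict[int, float] = field(default_factory=dict)
    true_psd: "object | None" = None  # PoreSizeDistribution, filled on request

    def validate(self) -> None:
        n_pore = self.phase_mask.count(Phase.PORE)
        basis = self.phase_mask.n_voxels - self.phase_mask.count(Phase.STONE) - self.phase_mask.count(Phase.EXCLUDED)
        expect = n_pore / basis if basis else 0.0
        if abs(expect - self.true_visible_porosity) > 1e-12:
            raise ValueError("true_visible_porosity inconsistent with phase mask")
        for fid, loss in self.pom_ids_with_loss.items():
            if not (0.0 <= loss <= 1.0):
                raise ValueError(f"loss fraction for fragment {fid} outside [0, 1]: {loss}")

    def fragment_voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.pom_fragment_labels[self.pom_fragment_labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def _grids(shape):
    return np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij", sparse=True)


def _rasterize_sphere(shape, center, radius_vox) -> np.ndarray:
    zz, yy, xx = _grids(shape)
    cz, cy, cx = center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_vox ** 2


def _rasterize_cylinder(shape, start, end, radius_vox) -> np.ndarray:
    """Voxel centers within ``radius_vox`` of the segment start-end."""
    p0 = np.asarray(start, dtype=np.float64)
    d = np.asarray(end, dtype=np.float64) - p0
    len2 = float(d @ d)
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    pz, py, px = zz - p0[0], yy - p0[1], xx - p0[2]
    if len2 == 0.0:
        dist2 = pz ** 2 + py ** 2 + px ** 2
    else:
        t = np.clip((pz * d[0] + py * d[1] + px * d[2]) / len2, 0.0, 1.0)
        dist2 = (pz - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (px - t * d[2]) ** 2
    return dist2 <= radius_vox ** 2


def _rasterize_ellipsoid(shape, center, semi_axes_vox) -> np.ndarray:
    zz, yy, xx = _grids(shape)
    cz, cy, cx = center
    az, ay, ax = semi_axes_vox
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _grow_blob(allowed: np.ndarray, seed_point, target_voxels: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic dilation from a seed until the blob reaches target size.

    Each round, 6-neighbor frontier voxels are admitted independently with
    probability 0.85 (shuffled, truncated to the remaining budget), giving
    compact blobs with irregular but not fractal boundaries — the
    sharp-edged fragment morphology that paired-scan POM tracking selects
    for.
    """
    seed_point = tuple(int(c) for c in seed_point)
    if not allowed[seed_point]:
        raise ValueError(f"POM seed point {seed_point} does not lie in solid matrix")
    blob = np.zeros_like(allowed, dtype=bool)
    blob[seed_point] = True
    n = 1
    while n < target_voxels:
        frontier = ndimage.binary_dilation(blob, _STRUCT6) & allowed & ~blob
        cand = np.argwhere(frontier)
        if len(cand) == 0:
            raise ValueError(
                f"POM blob at seed {seed_point} is enclosed after {n} voxels; "
                f"cannot reach target of {target_voxels}"
            )
        keep = rng.random(len(cand)) < 0.85
        if not keep.any():
            keep[rng.integers(len(cand))] = True
        cand = cand[keep]
        rng.shuffle(cand)
        cand = cand[: target_voxels - n]
        blob[tuple(cand.T)] = True
        n += len(cand)
    return blob


def rasterize_labels(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize all phases; returns (labels, pom_fragment_labels).

    Precedence: the volume starts as solid matrix; pores are carved; stones
    override pore and solid; POM blobs grow only through solid; roots carve
    through solid and pore.  A stone overlapping a POM blob makes the phase
    assignment ambiguous and is rejected.
    """
    spec.validate()
    shape = tuple(int(n) for n in spec.shape)
    vs = spec.voxel_size_um
    labels = np.full(shape, Phase.SOLID.value, dtype=np.uint8)

    for s in spec.pore_spheres:
        labels[_rasterize_sphere(shape, s.center, s.radius_um / vs)] = Phase.PORE.value
    for c in spec.pore_channels:
        labels[_rasterize_cylinder(shape, c.start, c.end, c.radius_um / vs)] = Phase.PORE.value

    stone_mask = np.zeros(shape, dtype=bool)
    for e in spec.stones:
        stone_mask |= _rasterize_ellipsoid(
            shape, e.center, tuple(a / vs for a in e.semi_axes_um)
        )
    labels[stone_mask] = Phase.STONE.value

    # Blob growth draws from structure_seed, not seed: the noise seed must
    # never alter the ground-truth labels.
    rng = np.random.default_rng(spec.structure_seed)
    pom_labels = np.zeros(shape, dtype=np.int32)
    voxvol = spec.voxel_volume_mm3
    for i, b in enumerate(spec.pom_fragments, start=1):
        target = max(1, int(round(b.volume_mm3 / voxvol)))
        allowed = labels == Phase.SOLID.value
        sz, sy, sx = (int(c) for c in b.seed_point)
        if stone_mask[sz, sy, sx]:
            raise ValueError(
                f"POM fragment {i} seed {b.seed_point} overlaps a stone; phases ambiguous"
            )
        blob = _grow_blob(allowed, b.seed_point, target, rng)
        if (ndimage.binary_dilation(blob, _STRUCT6) & stone_mask).any():
            raise ValueError(
                f"POM fragment {i} grown from seed {b.seed_point} touches a stone; "
                "phases ambiguous — move the seed or shrink the stone"
            )
        labels[blob] = Phase.POM.value
        pom_labels[blob] = i

    for r in spec.roots:
        tube = np.zeros(shape, dtype=bool)
        pts = list(r.points)
        for a, b in zip(pts[:-1], pts[1:]):
            tube |= _rasterize_cylinder(shape, a, b, r.radius_um / vs)
        carveable = (labels == Phase.SOLID.value) | (labels == Phase.PORE.value)
        labels[tube & carveable] = Phase.ROOT.value

    return labels, pom_labels


def render(spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator) -> GrayscaleVolume:
    """Render intensities from labels: phase means, per-fragment overrides
    not applied here (see :func:`generate_phantom`), multiplicative shading,
    additive Gaussian noise, clip to bit depth."""
    means = np.zeros(256, dtype=np.float64)
    for ph in (Phase.PORE, Phase.SOLID, Phase.STONE, Phase.POM, Phase.ROOT):
        means[ph.value] = spec.intensity.mean_of(ph)
    img = means[labels]

    if spec.shading_coeffs:
        exps = _poly.monomial_exponents(3)
        coeffs = np.zeros(len(exps))
        for key, val in spec.shading_coeffs.items():
            if tuple(key) not in exps:
                raise ValueError(f"shading exponent {key} exceeds total degree 3")
            coeffs[exps.index(tuple(key))] = val
        img *= _poly.evaluate_field(labels.shape, coeffs, 3)

    if spec.intensity.noise_sd > 0:
        img += rng.normal(0.0, spec.intensity.noise_sd, size=img.shape)

    max_value = 2 ** spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    vox = np.clip(np.rint(img), 0, max_value).astype(dtype)
    return GrayscaleVolume(vox, spec.voxel_size_um, spec.bit_depth)


def generate_phantom(spec: PhantomSpec, compute_psd: bool = False):
    """Generate one phantom volume and its exact ground truth.

    Returns ``(GrayscaleVolume, GroundTruth)``.  With ``compute_psd=True``
    the truth also carries the maximal-inscribed-sphere pore-size
    distribution of the exact pore mask (costly on large volumes).
    Identical spec (including seed) gives identical output.
    """
    labels, pom_labels = rasterize_labels(spec)
    rng = np.random.default_rng(spec.seed)

    # Per-fragment grayscale overrides enter as label-map tweaks at render
    # time: render from phase means first, then repaint overridden fragments.
    vol = render(spec, labels, rng)
    overrides = [
        (i, b.mean_gray)
        for i, b in enumerate(spec.pom_fragments, start=1)
        if b.mean_gray is not None
    ]
    if overrides:
        img = vol.voxels.astype(np.float64)
        for fid, gray in overrides:
            sel = pom_labels == fid
            img[sel] += gray - spec.intensity.pom
        vol = GrayscaleVolume(vol.quantize(img), vol.voxel_size_um, vol.bit_depth)

    mask = PhaseMask(
        labels,
        spec.voxel_size_um,
        {"intensity": {"pore": spec.intensity.pore, "noise_sd": spec.intensity.noise_sd}},
    )
    n_pore = mask.count(Phase.PORE)
    basis = mask.n_voxels - mask.count(Phase.STONE)
    truth = GroundTruth(
        phase_mask=mask,
        true_visible_porosity=n_pore / basis if basis else 0.0,
        pom_fragment_labels=pom_labels,
        pom_ids_with_loss={},
    )
    if compute_psd:
        from .pore_metrics import pore_size_distribution
        from .segment import stone_free_basis

        truth.true_psd = pore_size_distribution(stone_free_basis(mask))
    truth.validate()
    return vol, truth


def degrade_pom(
    volume: GrayscaleVolume,
    truth: GroundTruth,
    losses: dict[int, float],
    seed: int,
):
    """Produce the paired "after" volume by decomposing POM fragments.

    For each fragment id in ``losses``, voxels are peeled from the fragment
    surface inward (6-connected surface; ties within a peeling round broken
    by the seeded RNG) until ``round((1 - loss) * original_count)`` voxels
    remain.  Removed voxels become pore, re-rendered at pore intensity with
    the spec'd noise level.  All non-POM phases are untouched.
    """
    counts = truth.fragment_voxel_counts()
    for fid, loss in losses.items():
        if fid not in counts:
            raise KeyError(f"unknown POM fragment id {fid}; known ids: {sorted(counts)}")
        if not (0.0 <= loss <= 1.0):
            raise ValueError(f"loss fraction for fragment {fid} outside [0, 1]: {loss}")

    rng = np.random.default_rng(seed)
    labels = truth.phase_mask.labels.copy()
    pom_labels = truth.pom_fragment_labels.copy()
    img = volume.voxels.astype(np.float64)

    for fid in sorted(losses):
        loss = losses[fid]
        frag = pom_labels == fid
        n0 = counts[fid]
        keep = int(round((1.0 - loss) * n0))
        to_remove = n0 - keep
        while to_remove > 0:
            interior = ndimage.binary_erosion(frag, _STRUCT6, border_value=0)
            surface = np.argwhere(frag & ~interior)
            if len(surface) <= to_remove:
                removed = surface
            else:
                idx = rng.choice(len(surface), size=to_remove, replace=False)
                removed = surface[idx]
            frag[tuple(removed.T)] = False
            to_remove -= len(removed)
        removed_mask = (pom_labels == fid) & ~frag
        labels[removed_mask] = Phase.PORE.value
        pom_labels[removed_mask] = 0
        # re-render removed voxels at pore intensity: use the recorded
        # rendering model when available, else infer from existing pores
        model = truth.phase_mask.meta.get("intensity")
        if model is not None:
            mean, sd = model["pore"], model["noise_sd"]
        else:
            mean, sd = _infer_pore_mean(volume, truth), _infer_noise_sd(volume, truth)
        img[removed_mask] = rng.normal(mean, sd, size=int(removed_mask.sum()))

    mask = PhaseMask(labels, truth.phase_mask.voxel_size_um, dict(truth.phase_mask.meta))
    n_pore = mask.count(Phase.PORE)
    basis = mask.n_voxels - mask.count(Phase.STONE) - mask.count(Phase.EXCLUDED)
    new_truth = GroundTruth(
        phase_mask=mask,
        true_visible_porosity=n_pore / basis if basis else 0.0,
        pom_fragment_labels=pom_labels,
        pom_ids_with_loss=dict(losses),
    )
    new_truth.validate()
    out_vol = GrayscaleVolume(
        volume.quantize(img), volume.voxel_size_um, volume.bit_depth, dict(volume.meta)
    )
    return out_vol, new_truth


def standard_core_spec(
    n: int = 160,
    voxel_size_um: float = 18.2,
    noise_sd: float = 8.0,
    seed: int = 0,
    placement_seed: int = 42,
    include_stones: bool = False,
) -> PhantomSpec:
    """The package's standard validation core.

    A macropore-dominated network — spheres of radius 12–22 voxels
    (218–400 µm at scan resolution, the packing-void/biopore scale that
    carries most image-resolved porosity in intact cores) plus
    through-going channels of radius 9–14 voxels — at ~16% visible
    porosity for the default size, matching the porosity range of intact
    topsoil cores.  Counts scale with volume so smaller grids keep the
    same porosity.  ``include_stones`` adds one >10 mm³ ellipsoid and a
    sub-threshold bright speck.
    """
    rng = np.random.default_rng(placement_seed)
    scale = (n / 160.0) ** 3
    shrink = min(1.0, n / 88.0)  # keep pores inside small validation grids
    spheres = []
    for _ in range(max(3, int(round(20 * scale)))):
        r = rng.uniform(12, 22) * shrink
        c = rng.uniform(r * 0.3, n - r * 0.3, 3)
        spheres.append(SphereSpec(tuple(c), r * voxel_size_um))
    margin = min(20.0, n / 4.0)
    channels = [
        ChannelSpec(
            (0.0, rng.uniform(margin, n - margin), rng.uniform(margin, n - margin)),
            (float(n - 1), rng.uniform(margin, n - margin), rng.uniform(margin, n - margin)),
            rng.uniform(9, 14) * shrink * voxel_size_um,
        )
        for _ in range(max(1, int(round(5 * scale))))
    ]
    stones = []
    if include_stones:
        # >10 mm³ requires semi-axes ~(1.4 mm)³·4π/3; at 18.2 µm that is
        # only feasible in larger grids — callers use coarser voxels in
        # stone-focused tests.
        a = 1.45e3  # µm
        stones = [EllipsoidSpec((n * 0.5, n * 0.5, n * 0.5), (a, a, a))]
    return PhantomSpec(
        shape=(n, n, n),
        voxel_size_um=voxel_size_um,
        pore_spheres=spheres,
        pore_channels=channels,
        stones=stones,
        intensity=IntensityModel(noise_sd=noise_sd),
        seed=seed,
        structure_seed=placement_seed,
    )


def pom_study_spec(
    n_fragments: int = 20,
    fragment_volume_mm3: float = 0.35,
    n: int = 160,
    voxel_size_um: float = 40.0,
    noise_sd: float = 8.0,
    seed: int = 0,
    placement_seed: int = 5,
) -> PhantomSpec:
    """The standard POM-decomposition study phantom.

    Fragments of ~0.35 mm³ (≈0.9 mm across — the sharp-edged,
    well-contrasted size class tracked in paired-scan studies) seeded on a
    jittered 3×3×3 grid in a solid matrix, rendered at 40 µm voxels so
    each fragment spans ~5500 voxels.  Up to 27 fragments fit; more raises
    an error.
    """
    if n_fragments > 27:
        raise ValueError("at most 27 fragments fit on the 3×3×3 grid")
    third = n // 6
    grid = [third, n // 2, n - third]
    pts = [(z, y, x) for z in grid for y in grid for x in grid]
    rng = np.random.default_rng(placement_seed)
    rng.shuffle(pts)
    frags = [PomBlobSpec(pts[i], fragment_volume_mm3) for i in range(n_fragments)]
    return PhantomSpec(
        shape=(n, n, n),
        voxel_size_um=voxel_size_um,
        pom_fragments=frags,
        intensity=IntensityModel(noise_sd=noise_sd),
        seed=seed,
        structure_seed=placement_seed,
    )


def _infer_pore_mean(volume: GrayscaleVolume, truth: GroundTruth) -> float:
    pore = truth.phase_mask.phase(Phase.PORE)
    if pore.any():
        return float(volume.voxels[pore].mean())
    return 0.0


def _infer_noise_sd(volume: GrayscaleVolume, truth: GroundTruth) -> float:
    pore = truth.phase_mask.phase(Phase.PORE)
    if pore.any():
        return float(volume.voxels[pore].std())
    return 0.0
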