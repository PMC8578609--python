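"""Core voxel containers: grayscale volumes and phase-label masks.

A scan is held as a :class:`GrayscaleVolume` — a 3D integer intensity grid
with an isotropic physical voxel size — and every segmentation stage produces
a co-registered :class:`PhaseMask` whose labels partition the same grid into
pore, solid, stone, particulate organic matter (POM), root, and excluded
voxels.  All physical quantities downstream (porosities, interfacial areas,
pore radii) derive from these two containers plus the voxel edge length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = ["Phase", "GrayscaleVolume", "PhaseMask"]


class Phase(IntEnum):
    """Voxel phase labels.

    ``EXCLUDED`` marks voxels removed from every denominator (stone-free
    basis); it is distinct from ``STONE`` so that masks record both the stone
    geometry and the bookkeeping decision.
    """

    PORE = 1
    SOLID = 2
    STONE = 3
    POM = 4
    ROOT = 5
    EXCLUDED = 6


@dataclass
class GrayscaleVolume:
    """A 3D grayscale image with isotropic voxel size.

    Parameters
    ----------
    voxels:
        3D integer array, intensities in ``[0, 2**bit_depth - 1]``.
    voxel_size_um:
        Edge length of a voxel in micrometres (isotropic).
    bit_depth:
        8 or 16; fixes the intensity range and the on-disk dtype.
    meta:
        Free-form provenance (ROI offsets, processing parameters).
    """

    voxels: np.ndarray
    voxel_size_um: float
    bit_depth: int = 8
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"volume must be 3D with positive dims, got shape {self.voxels.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lo, hi = self.voxels.min(), self.voxels.max()
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_value}] for {self.bit_depth}-bit volume"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    def quantize(self, data: np.ndarray) -> np.ndarray:
        """Round and clip a float field back into this volume's integer range."""
        return np.clip(np.rint(data), 0, self.max_value).astype(self.dtype)

    def like(self, data: np.ndarray, **meta) -> "GrayscaleVolume":
        """A new volume with this one's geometry and ``data`` as intensities."""
        return GrayscaleVolume(
            self.quantize(np.asarray(data, dtype=np.float64)),
            self.voxel_size_um,
            self.bit_depth,
            {**self.meta, **meta},
        )


@dataclass
class PhaseMask:
    """A co-registered label volume over :class:`Phase` values."""

    labels: np.ndarray
    voxel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        valid = np.isin(self.labels, [p.value for p in Phase])
        if not valid.all():
            bad = np.unique(self.labels[~valid])
            raise ValueError(f"unknown phase labels {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    def phase(self, phase: Phase) -> np.ndarray:
        """Boolean mask of one phase."""
        return self.labels == phase.value

    def count(self, phase: Phase) -> int:
        return int(np.count_nonzero(self.labels == phase.value))

    @property
    def n_voxels(self) -> int:
        return int(self.labels.size)

    @property
    def n_basis_voxels(self) -> int:
        """Denominator for stone-free fractions: all voxels minus excluded."""
        return self.n_voxels - self.count(Phase.EXCLUDED)

    def copy(self) -> "PhaseMask":
        return PhaseMask(self.labels.copy(), self.voxel_size_um, dict(self.meta))
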