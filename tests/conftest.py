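import numpy as np
import pytest

from soilpore import GrayscaleVolume, Phase, PhaseMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(data, voxel_size_um=18.2, bit_depth=8):
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return GrayscaleVolume(np.asarray(data, dtype=dtype), voxel_size_um, bit_depth)


def sphere_mask(shape, center, radius):
    """Boolean ball by the voxel-center test."""
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij", sparse=True)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def mask_from_pore(pore, voxel_size_um=18.2):
    labels = np.where(pore, Phase.PORE.value, Phase.SOLID.value).astype(np.uint8)
    return PhaseMask(labels, voxel_size_um)


def opening_psd_oracle(pore):
    """Brute-force local pore size by opening with explicit discrete balls.

    Independent of the package's EDT construction: erosion/dilation with
    materialized ``{d : |d|² ≤ r²}`` structuring elements.  Erosion treats
    the outside as pore (border_value=1) and dilation as empty
    (border_value=0) — an inscribed sphere may extend past the boundary but
    must be anchored inside.
    """
    from scipy import ndimage
    from skimage.morphology import ball

    pore = np.asarray(pore, bool)
    edt = ndimage.distance_transform_edt(pore)
    rmax = int(np.floor(np.sqrt(np.rint(edt.max() ** 2) - 1))) if edt.max() else 0
    out = np.zeros(pore.shape, dtype=np.int32)
    for r in range(1, rmax + 1):
        selem = ball(r)
        eroded = ndimage.binary_erosion(pore, selem, border_value=1)
        if not eroded.any():
            continue
        opened = ndimage.binary_dilation(eroded, selem, border_value=0)
        out[opened & pore] = r
    return out
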