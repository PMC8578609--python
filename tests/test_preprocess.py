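"""Preprocessing chain: background removal, median, contrast, crop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import soilpore as sp
from soilpore import preprocess

from conftest import make_volume


class TestRemoveBackground:
    def test_constant_volume_is_fixed_point(self):
        v = make_volume(np.full((8, 8, 8), 77))
        out = preprocess.remove_background(v)
        assert np.all(out.voxels == 77)

    def test_pure_polynomial_becomes_flat(self):
        z, y, x = np.meshgrid(*(np.linspace(-1, 1, 12),) * 3, indexing="ij")
        field = 120 + 40 * x + 30 * y * z - 25 * x ** 3
        v = make_volume(np.clip(field, 0, 255))
        out = preprocess.remove_background(v)
        # exact fit: residual is constant up to integer quantization
        assert int(out.voxels.max()) - int(out.voxels.min()) <= 2

    def test_recovers_unshaded_phantom(self):
        """Multiplicative degree-3 shading, zero noise: residual vs the
        unshaded phantom stays below 1% of the dynamic range.

        Structure must be fine-grained relative to the trend (as in a real
        scan) or the global fit would alias onto the pore pattern itself.
        """
        rng = np.random.default_rng(77)
        spheres = [
            sp.SphereSpec(tuple(rng.uniform(3, 93, 3)), rng.uniform(2.0, 5.0) * 18.2)
            for _ in range(260)
        ]
        def build(shading):
            return sp.PhantomSpec(
                shape=(96, 96, 96), pore_spheres=spheres,
                intensity=sp.IntensityModel(noise_sd=0.0),
                shading_coeffs=shading,
            )
        shaded, _ = sp.generate_phantom(build(dict(sp.phantom._DEFAULT_SHADING)))
        flat, _ = sp.generate_phantom(build(None))
        out = preprocess.remove_background(shaded)
        # control: the unshaded volume gets the same conditioning, since a
        # global fit also removes the low-order component of true structure
        ref = preprocess.remove_background(flat)
        resid = out.voxels.astype(float) - ref.voxels.astype(float)
        assert resid.std() < 0.01 * 255

    def test_too_few_voxels_error(self):
        with pytest.raises(ValueError, match="coefficients"):
            preprocess.remove_background(make_volume(np.zeros((2, 2, 2))))

    def test_shape_and_voxel_size_preserved(self):
        v = make_volume(np.random.default_rng(0).integers(0, 255, (10, 12, 14)))
        out = preprocess.remove_background(v)
        assert out.shape == v.shape and out.voxel_size_um == v.voxel_size_um


class TestMedianFilter:
    def test_constant_unchanged(self):
        v = make_volume(np.full((10, 10, 10), 42))
        assert np.all(preprocess.median_filter_3d(v).voxels == 42)

    def test_impulse_removed(self):
        data = np.full((11, 11, 11), 100)
        data[5, 5, 5] = 250
        out = preprocess.median_filter_3d(make_volume(data), radius_vox=2)
        assert np.all(out.voxels == 100)

    def test_matches_brute_force_neighborhood_median(self, rng):
        """Per-voxel equality with an independent cube-neighborhood median
        (reflected edges) on a 16³ random volume."""
        data = rng.integers(0, 256, (16, 16, 16)).astype(np.uint8)
        out = preprocess.median_filter_3d(make_volume(data), radius_vox=2).voxels
        padded = np.pad(data, 2, mode="symmetric")  # scipy's "reflect" convention
        expect = np.empty_like(data)
        for z in range(16):
            for y in range(16):
                for x in range(16):
                    block = padded[z:z + 5, y:y + 5, x:x + 5]
                    expect[z, y, x] = np.median(block)
        np.testing.assert_array_equal(out, expect)

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            preprocess.median_filter_3d(make_volume(np.zeros((4, 4, 4))), radius_vox=0)


class TestEnhanceContrast:
    def test_zero_saturation_full_range_unchanged(self):
        data = np.linspace(0, 255, 1000).astype(np.uint8).reshape(10, 10, 10)
        out = preprocess.enhance_contrast(make_volume(data), saturated_pct=0.0)
        np.testing.assert_array_equal(out.voxels, data)

    def test_clip_count_matches_tail_rule(self, rng):
        """0.6% on 1000 distinct-valued voxels clips floor(0.003·1000)=3 per tail."""
        vals = rng.choice(65536, size=1000, replace=False).astype(np.uint16)
        v = make_volume(vals.reshape(10, 10, 10), bit_depth=16)
        out = preprocess.enhance_contrast(v, saturated_pct=0.6)
        srt = np.sort(vals)
        lo, hi = srt[3], srt[996]
        assert int((vals < lo).sum()) == 3 and int((vals > hi).sum()) == 3
        # the three sub-cut voxels per tail land exactly on the range extremes
        assert int((out.voxels == 0).sum()) >= 3
        assert int((out.voxels == 65535).sum()) >= 3
        # cut voxels map to the extremes themselves
        assert out.voxels.ravel()[np.argmin(vals)] == 0
        assert out.voxels.ravel()[np.argmax(vals)] == 65535

    def test_rank_order_preserved_among_unclipped(self, rng):
        data = rng.integers(0, 256, (12, 12, 12)).astype(np.uint8)
        v = make_volume(data)
        out = preprocess.enhance_contrast(v, saturated_pct=2.0)
        inner = (out.voxels > 0) & (out.voxels < 255)
        a = data[inner].ravel()
        b = out.voxels[inner].ravel()
        order = np.argsort(a, kind="stable")
        assert np.all(np.diff(b[order].astype(int)) >= -1)  # monotone up to rounding

    @settings(derandomize=True, max_examples=30)
    @given(
        data=hnp.arrays(np.uint8, (5, 5, 5), elements=st.integers(0, 255)),
        pct=st.floats(0.0, 20.0),
    )
    def test_mapping_is_monotone_nondecreasing(self, data, pct):
        import warnings as _warnings

        with _warnings.catch_warnings():
            # heavy saturation on tiny volumes can degenerate to identity
            _warnings.simplefilter("ignore", UserWarning)
            out = preprocess.enhance_contrast(make_volume(data), saturated_pct=pct).voxels
        a = data.ravel().astype(int)
        b = out.ravel().astype(int)
        order = np.argsort(a, kind="stable")
        assert np.all(np.diff(b[order]) >= 0)

    def test_constant_volume_warns_and_passes_through(self):
        v = make_volume(np.full((5, 5, 5), 9))
        with pytest.warns(UserWarning, match="degenerate"):
            out = preprocess.enhance_contrast(v)
        np.testing.assert_array_equal(out.voxels, v.voxels)


class TestCropRoi:
    def test_full_size_is_identity(self, rng):
        data = rng.integers(0, 256, (8, 9, 10)).astype(np.uint8)
        v = make_volume(data)
        out = preprocess.crop_roi(v, (8, 9, 10))
        np.testing.assert_array_equal(out.voxels, data)
        assert out.meta["roi_offset"] == (0, 0, 0)

    def test_centered_crop_offset(self, rng):
        v = make_volume(rng.integers(0, 256, (64, 64, 64)))
        out = preprocess.crop_roi(v, (32, 32, 32))
        assert out.meta["roi_offset"] == (16, 16, 16)
        assert out.shape == (32, 32, 32)

    def test_three_offset_subsamples_are_disjoint(self, rng):
        data = np.arange(32 ** 3, dtype=np.uint16).reshape(32, 32, 32)
        v = make_volume(data, bit_depth=16)
        crops = [
            preprocess.crop_roi(v, (8, 8, 8), anchor=off)
            for off in [(0, 0, 0), (10, 10, 10), (22, 22, 22)]
        ]
        seen = [set(c.voxels.ravel().tolist()) for c in crops]
        assert not (seen[0] & seen[1]) and not (seen[1] & seen[2]) and not (seen[0] & seen[2])

    def test_oversize_crop_errors_with_shapes(self):
        v = make_volume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match=r"\(16, 16, 16\)"):
            preprocess.crop_roi(v, (16, 16, 16))


def test_chain_preserves_shape_and_voxel_size():
    spec = sp.standard_core_spec(n=48, noise_sd=4.0)
    vol, _ = sp.generate_phantom(spec)
    out = preprocess.preprocess_chain(vol)
    assert out.shape == vol.shape
    assert out.voxel_size_um == vol.voxel_size_um
    assert out.bit_depth == vol.bit_depth
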