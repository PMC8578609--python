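"""POM segmentation, Eq.-style loss, shell analysis, root distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import soilpore as sp
from soilpore import Phase, pom

from conftest import make_volume, sphere_mask


class TestCalibrateThresholds:
    def _vol(self, data):
        return make_volume(data)

    def test_single_region_min_max(self):
        data = np.full((6, 6, 6), 150, dtype=np.uint8)
        region = np.zeros((6, 6, 6), bool)
        region[2, 2, 2:5] = True
        data[2, 2, 2:5] = [80, 100, 120]
        assert sp.calibrate_pom_thresholds(self._vol(data), [region]) == (80, 120)

    def test_two_regions_mean_of_extremes(self):
        data = np.full((6, 6, 6), 150, dtype=np.uint8)
        r1 = np.zeros((6, 6, 6), bool); r1[1, 1, 1:3] = True
        r2 = np.zeros((6, 6, 6), bool); r2[4, 4, 1:3] = True
        data[1, 1, 1:3] = [80, 120]
        data[4, 4, 1:3] = [100, 140]
        assert sp.calibrate_pom_thresholds(self._vol(data), [r1, r2]) == (90, 130)

    def test_constant_regions_degenerate_band(self):
        data = np.full((5, 5, 5), 99, dtype=np.uint8)
        region = np.zeros((5, 5, 5), bool); region[0, 0, 0] = True
        assert sp.calibrate_pom_thresholds(self._vol(data), [region]) == (99, 99)

    def test_empty_region_errors_naming_it(self):
        data = np.zeros((4, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="region 0"):
            sp.calibrate_pom_thresholds(self._vol(data), [np.zeros((4, 4, 4), bool)])


class TestSegmentPom:
    def test_phantom_blob_recovered_within_10pct(self):
        spec = sp.pom_study_spec(
            n_fragments=1, n=96, fragment_volume_mm3=0.05, voxel_size_um=18.2, noise_sd=0.0
        )
        vol, truth = sp.generate_phantom(spec)
        seg = sp.segment_pom(vol, 86, 134)
        assert len(seg.fragments) == 1
        true_vol = truth.fragment_voxel_counts()[1] * spec.voxel_volume_mm3
        assert seg.fragments[0].volume_mm3 == pytest.approx(true_vol, rel=0.10)

    def test_isolated_band_voxel_removed_by_opening(self):
        data = np.full((20, 20, 20), 200, dtype=np.uint8)
        data[10, 10, 10] = 110
        seg = sp.segment_pom(make_volume(data, voxel_size_um=100.0), 86, 134)
        assert seg.fragments == []

    def test_exactly_threshold_volume_discarded(self):
        # a blob of exactly the minimum volume (18 voxels of 100 µm here):
        # the strictly-greater rule drops it even with cleaning disabled
        vol_18 = 18 * (100.0 * 1e-3) ** 3
        data = np.full((20, 20, 20), 200, dtype=np.uint8)
        data[5:7, 5:8, 5:8] = 110  # 2·3·3 = 18 voxels
        seg = sp.segment_pom(
            make_volume(data, voxel_size_um=100.0), 86, 134,
            open_steps=0, gauss_sigma_vox=0.0, min_volume_mm3=vol_18,
        )
        assert seg.fragments == []
        data[7, 5, 5] = 110  # 19 voxels: strictly greater, kept
        seg = sp.segment_pom(
            make_volume(data, voxel_size_um=100.0), 86, 134,
            open_steps=0, gauss_sigma_vox=0.0, min_volume_mm3=vol_18,
        )
        assert len(seg.fragments) == 1 and seg.fragments[0].voxel_count == 19

    def test_fragments_sorted_by_volume_desc(self):
        spec = sp.pom_study_spec(n_fragments=4, n=96, fragment_volume_mm3=0.08, noise_sd=4.0)
        # one larger fragment
        spec.pom_fragments[2] = sp.PomBlobSpec(spec.pom_fragments[2].seed_point, 0.2)
        vol, _ = sp.generate_phantom(spec)
        seg = sp.segment_pom(vol, 86, 134)
        vols = [f.volume_mm3 for f in seg.fragments]
        assert vols == sorted(vols, reverse=True)
        assert [f.id for f in seg.fragments] == list(range(1, len(vols) + 1))


class TestPomLoss:
    def test_identity_zero_loss(self):
        ch = sp.pom_loss(500, 500, 10000)
        assert ch.loss_pct == 0.0

    def test_complete_loss(self):
        ch = sp.pom_loss(500, 0, 10000)
        assert ch.loss_pct == 100.0

    def test_product_antisymmetry(self):
        l1 = sp.pom_loss(800, 600, 10000).loss_pct
        l2 = sp.pom_loss(600, 800, 10000).loss_pct
        assert (1 - l1 / 100) * (1 - l2 / 100) == pytest.approx(1.0)

    def test_zero_before_errors(self):
        with pytest.raises(ValueError):
            sp.pom_loss(0, 10, 1000)

    @settings(derandomize=True, max_examples=50)
    @given(
        n_b=st.integers(1, 10 ** 6),
        n_a=st.integers(0, 10 ** 6),
        ref1=st.integers(1, 10 ** 8),
        ref2=st.integers(1, 10 ** 8),
    )
    def test_loss_is_reference_free_and_bounded(self, n_b, n_a, ref1, ref2):
        """The loss is a pure count ratio: the shared normalization cancels,
        and loss ≤ 100 always."""
        l1 = sp.pom_loss(n_b, n_a, ref1).loss_pct
        l2 = sp.pom_loss(n_b, n_a, ref2).loss_pct
        assert l1 == pytest.approx(l2, rel=1e-9, abs=1e-9)
        assert l1 <= 100.0

    def test_prescribed_loss_recovered_with_ideal_segmentation(self):
        spec = sp.pom_study_spec(n_fragments=1, n=72, fragment_volume_mm3=0.12, noise_sd=4.0)
        vol, truth = sp.generate_phantom(spec)
        vol_a, truth_a = sp.degrade_pom(vol, truth, {1: 0.4}, seed=3)
        n_b = truth.fragment_voxel_counts()[1]
        n_a = truth_a.fragment_voxel_counts()[1]
        ch = sp.pom_loss(n_b, n_a, vol.voxels.size)
        assert ch.loss_pct == pytest.approx(40.0, abs=5.0)

    def test_unmatched_fragments_reported_not_dropped(self):
        spec = sp.pom_study_spec(n_fragments=2, n=96, fragment_volume_mm3=0.12, noise_sd=4.0)
        vol, truth = sp.generate_phantom(spec)
        vol_a, _ = sp.degrade_pom(vol, truth, {1: 1.0}, seed=3)
        segb = sp.segment_pom(vol, 86, 134)
        sega = sp.segment_pom(vol_a, 86, 134)
        changes = sp.compare_pom(segb, sega, vol.voxels.size)
        statuses = {c.status for c in changes}
        assert len(changes) == 2
        assert "unmatched_after" in statuses  # fully decomposed fragment reported at 100%
        gone = [c for c in changes if c.status == "unmatched_after"]
        assert gone[0].loss_pct == 100.0


class TestShells:
    vs = 250.0  # µm → 1 mm = 4 voxels, 8 mm = 32 voxels

    def _fragment(self, n=96):
        frag = np.zeros((n, n, n), bool)
        frag[46:50, 46:50, 46:50] = True
        return frag

    def test_empty_pore_all_zero(self):
        frag = self._fragment()
        prof = sp.shell_pore_fraction(frag, np.zeros_like(frag), self.vs)
        assert prof.pore_fraction_per_shell == [0.0, 0.0, 0.0]

    def test_everything_pore_all_one(self):
        frag = self._fragment()
        prof = sp.shell_pore_fraction(frag, ~frag, self.vs)
        assert prof.pore_fraction_per_shell == [1.0, 1.0, 1.0]

    def test_uniform_random_pore_within_3_binomial_sd(self, rng):
        frag = self._fragment()
        p = 0.15
        pore = (rng.random(frag.shape) < p) & ~frag
        prof = sp.shell_pore_fraction(frag, pore, self.vs)
        dist = ndimage.distance_transform_edt(~frag)
        for d_mm, frac in zip(prof.shell_distances_mm, prof.pore_fraction_per_shell):
            n_layer = int(((dist > 0) & (dist <= d_mm * 1000 / self.vs)).sum())
            sd = np.sqrt(p * (1 - p) / n_layer)
            assert abs(frac - p) <= 3 * sd

    def test_shells_nested_and_exclude_stones(self, rng):
        frag = self._fragment()
        pore = rng.random(frag.shape) < 0.2
        excluded = np.zeros_like(frag)
        excluded[40:60, 40:60, 60:80] = True
        pore &= ~excluded
        prof = sp.shell_pore_fraction(frag, pore, self.vs, excluded_mask=excluded)
        dist = ndimage.distance_transform_edt(~frag)
        counts = []
        for d_mm in prof.shell_distances_mm:
            layer = (dist > 0) & (dist <= d_mm * 1000 / self.vs) & ~excluded & ~frag
            counts.append(int(layer.sum()))
        assert counts[0] < counts[1] < counts[2]

    def test_boundary_fragment_reports_truncation(self):
        n = 48
        frag = np.zeros((n, n, n), bool)
        frag[0:4, 22:26, 22:26] = True  # touches z=0 face
        prof = sp.shell_pore_fraction(frag, np.zeros_like(frag), self.vs, distances_mm=(1.0, 5.0))
        assert prof.truncation_fraction_per_shell[0] > 0.0
        assert prof.truncation_fraction_per_shell[1] > prof.truncation_fraction_per_shell[0]


class TestRootDistance:
    def _pom_seg(self, frag, vs=250.0):
        labels = frag.astype(np.int32)
        f = pom.PomFragment(
            id=1,
            voxel_count=int(frag.sum()),
            volume_mm3=float(frag.sum()) * (vs * 1e-3) ** 3,
            centroid_um=tuple(np.argwhere(frag).mean(axis=0) * vs),
            bbox=((0, 1), (0, 1), (0, 1)),
            mean_gray=110.0,
        )
        return pom.PomSegmentation([f], labels, vs)

    def test_adjacent_root_within_one_diagonal(self):
        frag = np.zeros((20, 20, 20), bool); frag[10, 10, 10] = True
        root = np.zeros((20, 20, 20), bool); root[10, 10, 11] = True
        d = sp.root_distance(self._pom_seg(frag), root)
        assert d[1] <= np.sqrt(3) * 0.25

    def test_plane_root_axis_distance(self):
        frag = np.zeros((30, 30, 30), bool); frag[12:15, 10:14, 10:14] = True
        root = np.zeros((30, 30, 30), bool); root[0] = True
        d = sp.root_distance(self._pom_seg(frag), root)
        assert d[1] == pytest.approx(12 * 0.25)

    def test_matches_brute_force_all_pairs(self, rng):
        frag = sphere_mask((32, 32, 32), (8, 8, 8), 3)
        root = rng.random((32, 32, 32)) < 0.002
        root &= ~frag
        if not root.any():
            root[25, 25, 25] = True
        d = sp.root_distance(self._pom_seg(frag), root)[1]
        fv = np.argwhere(frag)[:, None, :]
        rv = np.argwhere(root)[None, :, :]
        brute = np.sqrt(((fv - rv) ** 2).sum(-1)).min() * 0.25
        assert d == pytest.approx(brute, abs=1e-9)

    def test_empty_root_mask_undefined(self):
        frag = np.zeros((10, 10, 10), bool); frag[5, 5, 5] = True
        d = sp.root_distance(self._pom_seg(frag), np.zeros((10, 10, 10), bool))
        assert d[1] is None
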