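import dataclasses

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import focusctu as f
from focusctu.focusview import FocusedViewConfig
from focusctu.volio import LabelVolume

from .conftest import flood_fill_components, single_component_contains


def brute_force_dilation(mask, radius_mm, spacing):
    """O(n^2) oracle: voxel in output iff its center is within radius of a
    foreground voxel center (physical mm)."""
    centers = np.argwhere(np.ones(mask.shape, dtype=bool)) * np.asarray(spacing)
    fg = np.argwhere(mask) * np.asarray(spacing)
    if len(fg) == 0:
        return np.zeros(mask.shape, dtype=bool)
    d = cdist(centers, fg).min(axis=1)
    return (d <= radius_mm).reshape(mask.shape)


class TestMethod1:
    def test_empty_labels_give_empty_mask(self):
        lab = LabelVolume(np.zeros((5, 5, 5), dtype=np.uint8))
        assert not f.method1_mask(lab).any()

    def test_single_voxel(self):
        arr = np.zeros((5, 5, 5), dtype=np.uint8)
        arr[2, 3, 1] = 1
        mask = f.method1_mask(LabelVolume(arr))
        assert mask.sum() == 1 and mask[2, 3, 1]

    def test_cardinality_matches_nonzero_labels(self, small_phantom):
        mask = f.method1_mask(small_phantom.observed)
        assert mask.sum() == (small_phantom.observed.labels > 0).sum()


class TestMethod2:
    def test_zero_boundary_equals_method1(self, small_phantom):
        np.testing.assert_array_equal(
            f.method2_mask(small_phantom.observed, 0.0),
            f.method1_mask(small_phantom.observed),
        )

    def test_single_voxel_anisotropic_matches_brute_force(self):
        arr = np.zeros((21, 21, 11), dtype=np.uint8)
        arr[10, 10, 5] = 2
        lab = LabelVolume(arr, spacing=(1.0, 1.0, 2.0))
        mask = f.method2_mask(lab, 10.0)
        oracle = brute_force_dilation(arr > 0, 10.0, lab.spacing)
        np.testing.assert_array_equal(mask, oracle)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_masks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        arr = (rng.random((16, 16, 16)) < 0.02).astype(np.uint8)
        lab = LabelVolume(arr, spacing=(1.5, 1.0, 2.5))
        for radius in (0.0, 4.0, 7.5):
            np.testing.assert_array_equal(
                f.method2_mask(lab, radius),
                brute_force_dilation(arr > 0, radius, lab.spacing),
            )

    def test_dilation_monotone_in_radius(self, small_phantom):
        m10 = f.method2_mask(small_phantom.observed, 10.0)
        m20 = f.method2_mask(small_phantom.observed, 20.0)
        assert np.all(m10 <= m20)


class TestBridging:
    def test_connected_tract_is_noop(self, small_phantom):
        mask, segments = f.bridge_components(small_phantom.observed)
        assert segments == []
        np.testing.assert_array_equal(mask, small_phantom.observed.labels > 0)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            f.bridge_components(LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8)))

    def test_single_gap_bridged(self, gapped_phantom):
        out = gapped_phantom
        mask, segments = f.bridge_components(out.observed)
        assert len(segments) == 1
        assert single_component_contains(
            mask, out.truth.labels == f.KIDNEY, out.truth.labels == f.BLADDER
        )

    def test_bridge_length_matches_exhaustive_nearest_pair(self, gapped_phantom):
        out = gapped_phantom
        tract = out.observed.labels > 0
        comps = flood_fill_components(tract)
        spacing = np.asarray(out.observed.spacing)
        # exhaustive closest pair between the two flood-fill components
        a = np.argwhere(comps == 1) * spacing
        b = np.argwhere(comps == 2) * spacing
        expected = cdist(a, b).min()
        (seg,) = f.bridge_components(out.observed)[1]
        assert abs(seg.length_mm - expected) <= 2 * max(out.observed.spacing)

    def test_two_gaps_two_bridges(self):
        out = f.generate_phantom(f.random_spec(seed=21, n_gaps=2))
        mask, segments = f.bridge_components(out.observed)
        assert len(segments) == 2
        assert flood_fill_components(mask).max() == 1

    def test_bridge_endpoints_on_distinct_components(self, gapped_phantom):
        out = gapped_phantom
        tract = out.observed.labels > 0
        comps = flood_fill_components(tract)
        (seg,) = f.bridge_components(out.observed)[1]
        spacing = np.asarray(out.observed.spacing)
        ids = []
        for p in (seg.start_mm, seg.end_mm):
            idx = tuple(np.round(np.asarray(p) / spacing).astype(int))
            ids.append(comps[idx])
        assert ids[0] != 0 and ids[1] != 0 and ids[0] != ids[1]

    def test_missing_bladder_warns_but_bridges(self):
        arr = np.zeros((20, 20, 10), dtype=np.uint8)
        arr[2:4, 2:4, 2:4] = 2
        arr[15:17, 15:17, 6:8] = 2
        lab = LabelVolume(arr, spacing=(2.0, 2.0, 4.0))
        with pytest.warns(UserWarning, match="kidney or bladder"):
            mask, segments = f.bridge_components(lab)
        assert len(segments) == 1
        assert flood_fill_components(mask).max() == 1


class TestMethod3:
    def test_gap_free_equals_method2(self, small_phantom):
        np.testing.assert_array_equal(
            f.method3_mask(small_phantom.observed),
            f.method2_mask(small_phantom.observed, 10.0),
        )

    def test_containment_chain(self, gapped_phantom):
        cfg = FocusedViewConfig()
        m1 = f.method1_mask(gapped_phantom.observed)
        m2 = f.method2_mask(gapped_phantom.observed, cfg.boundary_mm)
        m3 = f.method3_mask(gapped_phantom.observed, cfg)
        assert np.all(m1 <= m2) and np.all(m2 <= m3)

    def test_gap_region_near_bridge_is_visible(self, gapped_phantom):
        out = gapped_phantom
        cfg = FocusedViewConfig()
        m3 = f.method3_mask(out.observed, cfg)
        (seg,) = f.bridge_components(out.observed)[1]
        # gap voxels (truth ureter removed from observed) within the bridge
        # radius of the straight path must be inside the method-3 mask
        gap_vox = np.argwhere((out.truth.labels == f.URETER) & (out.observed.labels == 0))
        pts = gap_vox * np.asarray(out.observed.spacing)
        p, q = np.asarray(seg.start_mm), np.asarray(seg.end_mm)
        d = q - p
        t = np.clip(((pts - p) @ d) / (d @ d), 0.0, 1.0)
        dist = np.linalg.norm(pts - (p + t[:, None] * d), axis=1)
        near = gap_vox[dist <= cfg.bridge_radius_mm - max(out.observed.spacing)]
        assert near.size > 0
        assert m3[tuple(near.T)].all()


class TestApplyMask:
    def test_full_mask_identity(self, small_phantom):
        out = f.apply_mask(small_phantom.ctu, np.ones(small_phantom.ctu.shape, bool))
        np.testing.assert_array_equal(out.voxels, small_phantom.ctu.voxels)

    def test_empty_mask_constant_fill(self, small_phantom):
        out = f.apply_mask(small_phantom.ctu, np.zeros(small_phantom.ctu.shape, bool), -1024.0)
        assert np.all(out.voxels == -1024.0)

    def test_grid_mismatch_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            f.apply_mask(small_phantom.ctu, np.ones((2, 2, 2), bool))

    def test_idempotent(self, small_phantom):
        mask = f.method2_mask(small_phantom.observed, 10.0)
        once = f.apply_mask(small_phantom.ctu, mask)
        twice = f.apply_mask(once, mask)
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_inside_voxels_copied_exactly(self, small_phantom):
        mask = f.method1_mask(small_phantom.observed)
        out = f.apply_mask(small_phantom.ctu, mask, -1024.0)
        np.testing.assert_array_equal(out.voxels[mask], small_phantom.ctu.voxels[mask])
        assert np.all(out.voxels[~mask] == -1024.0)


class TestFocusedView:
    def test_identity_misalignment_equals_direct_masking(self):
        spec = dataclasses.replace(
            f.default_spec("small"), misalignment=f.AffineTransform.identity()
        )
        out = f.generate_phantom(spec)
        res = f.focused_view(
            out.ctu, out.unenhanced, out.observed,
            FocusedViewConfig(method=2), register_unenhanced=False,
        )
        direct = f.apply_mask(out.unenhanced, res.mask, res.config.fill_hu)
        np.testing.assert_allclose(res.masked_unenhanced.voxels, direct.voxels, atol=1e-3)

    def test_method3_reveals_more_than_method1(self, gapped_phantom):
        out = gapped_phantom
        res1 = f.focused_view(out.ctu, out.unenhanced, out.observed,
                              FocusedViewConfig(method=1), register_unenhanced=False)
        res3 = f.focused_view(out.ctu, out.unenhanced, out.observed,
                              FocusedViewConfig(method=3), register_unenhanced=False)
        tract_visible_1 = ((out.truth.labels > 0) & res1.mask).sum()
        tract_visible_3 = ((out.truth.labels > 0) & res3.mask).sum()
        assert tract_visible_3 > tract_visible_1

    def test_registration_then_concealment(self, small_phantom):
        out = small_phantom
        res = f.focused_view(out.ctu, out.unenhanced, out.observed, FocusedViewConfig(method=3))
        conc = f.concealment_check(out.incidental_mask, res.mask)
        assert conc.all_hidden
        # the registered unenhanced volume must match the CTU frame anatomy:
        # its correlation with the CTU should beat the unregistered one
        assert res.registration.metric_value > res.registration.metric_at_identity
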