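"""Dense inference, mask post-processing and the overlap metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlradiomics import (
    LabeledVolume,
    postprocess_mask,
    segment_volume,
    segmentation_metrics,
)


class TestSegmentVolume:
    def test_probability_map_valid(self, tiny_net, one_phantom):
        res = segment_volume(tiny_net, one_phantom)
        assert res.probability_map.shape == one_phantom.spatial_shape
        assert res.probability_map.min() >= 0.0
        assert res.probability_map.max() <= 1.0
        assert res.mask.shape == one_phantom.spatial_shape

    def test_constant_zero_volume_no_crash(self, tiny_net):
        vol = LabeledVolume(
            intensities=np.zeros((2, 4, 40, 40)),
            mask=np.pad(np.ones((1, 1, 1)), ((1, 2), (19, 20), (19, 20))),
            label=0,
            case_id="zero",
        )
        res = segment_volume(tiny_net, vol)
        assert np.isfinite(res.probability_map).all()

    def test_channel_mismatch_rejected(self, tiny_net):
        vol = LabeledVolume(
            intensities=np.zeros((1, 4, 40, 40)),
            mask=np.pad(np.ones((1, 1, 1)), ((1, 2), (19, 20), (19, 20))),
            label=0,
            case_id="onechan",
        )
        with pytest.raises(ValueError):
            segment_volume(tiny_net, vol)


class TestPostprocessMask:
    def test_largest_component_survives(self):
        pm = np.zeros((3, 20, 20))
        pm[:, 2:7, 2:12] = 1.0  # 50 voxels per slice
        pm[:, 12:14, 15:20] = 1.0  # 10 voxels per slice
        out = postprocess_mask(pm, threshold=0.5)
        assert out[:, 12:14, 15:20].sum() == 0
        assert out[1, 2:7, 2:12].sum() > 0

    def test_all_zero_map_gives_empty_mask(self):
        assert postprocess_mask(np.zeros((3, 10, 10))).sum() == 0

    def test_isolated_voxel_removed_by_box_filter(self):
        pm = np.zeros((3, 9, 9))
        pm[1, 4, 4] = 1.0  # smoothed value 1/27 < 0.5
        assert postprocess_mask(pm, threshold=0.5).sum() == 0

    def test_solid_block_interior_kept(self):
        pm = np.zeros((5, 11, 11))
        pm[1:4, 2:9, 2:9] = 0.9
        out = postprocess_mask(pm, threshold=0.5)
        assert out[2, 5, 5] == 1

    def test_out_of_range_map_rejected(self):
        with pytest.raises(ValueError):
            postprocess_mask(np.full((1, 4, 4), 1.5))


class TestSegmentationMetrics:
    def test_perfect_overlap(self):
        m = np.zeros((2, 5, 5), dtype=bool)
        m[0, 1:4, 1:4] = True
        assert segmentation_metrics(m, m) == (1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((1, 6, 6), dtype=bool)
        b = np.zeros((1, 6, 6), dtype=bool)
        a[0, :2, :2] = True
        b[0, 4:, 4:] = True
        assert segmentation_metrics(a, b) == (0.0, 0.0, 0.0)

    def test_hand_counted_partial_overlap(self):
        pred = np.zeros((1, 4, 4), dtype=bool)
        truth = np.zeros((1, 4, 4), dtype=bool)
        pred[0, 0, :4] = True  # |P| = 4
        truth[0, 0, :2] = True  # |T| = 2, intersection 2
        dsc, ppv, sens = segmentation_metrics(pred, truth)
        assert dsc == pytest.approx(2 * 2 / 6)
        assert ppv == pytest.approx(0.5)
        assert sens == pytest.approx(1.0)

    def test_empty_denominators_return_zero_with_warning(self):
        empty = np.zeros((1, 3, 3), dtype=bool)
        full = ~empty
        with pytest.warns(UserWarning):
            dsc, ppv, sens = segmentation_metrics(empty, empty)
        assert (dsc, ppv, sens) == (0.0, 0.0, 0.0)
        with pytest.warns(UserWarning):
            assert segmentation_metrics(empty, full)[1] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**24 - 1))
    def test_dsc_symmetric_and_bounded(self, bits):
        grid = np.array([(bits >> i) & 1 for i in range(24)]).reshape(2, 12)
        p, t = grid[0].reshape(1, 3, 4).astype(bool), grid[1].reshape(1, 3, 4).astype(bool)
        if not (p.any() or t.any()):
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_pt = segmentation_metrics(p, t)
            m_tp = segmentation_metrics(t, p)
        assert m_pt[0] == pytest.approx(m_tp[0])
        assert all(0.0 <= v <= 1.0 for v in m_pt)
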