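"""Voxelwise operations: normalization, MTR, T1 subtraction, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remyetrack.imgproc import (
    LabelMap,
    Volume,
    compute_mtr,
    detect_enhancement,
    normalize_to_gm,
    segment_lesions,
    t1_subtraction,
)


def vol(data, tag="PDw"):
    return Volume(np.asarray(data, dtype=float), contrast_tag=tag)


class TestNormalizeToGM:
    def test_constant_volume_maps_to_ones(self):
        v = vol(np.full((4, 4, 2), 7.0))
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[0, 0, 0] = True
        out = normalize_to_gm(v, mask)
        assert np.allclose(out.data, 1.0)

    def test_wm_at_seventy_percent_of_gm_lands_in_nawm_band(self):
        data = np.full((6, 6, 3), 200.0)
        gm = np.zeros_like(data, dtype=bool)
        gm[:3] = True
        data[~gm] = 0.70 * 200.0
        out = normalize_to_gm(vol(data), gm)
        wm_mean = out.data[~gm].mean()
        assert 0.65 <= wm_mean <= 0.75

    def test_direct_arithmetic(self):
        data = np.full((3, 3, 1), 200.0)
        data[1, 1, 0] = 300.0
        gm = np.ones_like(data, dtype=bool)
        gm[1, 1, 0] = False
        out = normalize_to_gm(vol(data), gm)
        assert out.data[1, 1, 0] == pytest.approx(1.5)

    def test_gm_mean_is_one_and_idempotent(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(50, 150, size=(5, 5, 4))
        gm = rng.random((5, 5, 4)) > 0.5
        once = normalize_to_gm(vol(data), gm)
        assert once.data[gm].mean() == pytest.approx(1.0, abs=1e-9)
        twice = normalize_to_gm(once, gm)
        assert np.allclose(once.data, twice.data, atol=1e-9)

    @pytest.mark.parametrize("bad", ["empty", "negative"])
    def test_invalid_reference_raises(self, bad):
        data = np.full((3, 3, 2), -1.0 if bad == "negative" else 1.0)
        mask = np.zeros((3, 3, 2), dtype=bool)
        if bad == "negative":
            mask[:] = True
        with pytest.raises(ValueError):
            normalize_to_gm(vol(data), mask)


class TestComputeMTR:
    def test_equal_volumes_give_zero(self):
        m0 = vol(np.full((3, 3, 2), 2.0), "MT_off")
        out = compute_mtr(m0, vol(np.full((3, 3, 2), 2.0), "MT_on"))
        assert np.allclose(out.data, 0.0)

    def test_single_voxel_arithmetic(self):
        m0 = vol(np.full((2, 2, 1), 2.0), "MT_off")
        msat = vol(np.full((2, 2, 1), 1.0), "MT_on")
        assert np.allclose(compute_mtr(m0, msat).data, 0.5)

    def test_matches_bruteforce_voxel_loop(self):
        rng = np.random.default_rng(1)
        m0d = rng.uniform(0.5, 2.0, size=(4, 3, 2))
        msatd = rng.uniform(0.1, 2.0, size=(4, 3, 2))
        out = compute_mtr(vol(m0d, "MT_off"), vol(msatd, "MT_on")).data
        for idx in np.ndindex(m0d.shape):
            assert out[idx] == pytest.approx((m0d[idx] - msatd[idx]) / m0d[idx])

    def test_physical_inputs_bounded(self):
        rng = np.random.default_rng(2)
        m0d = rng.uniform(0.5, 2.0, size=(4, 4, 3))
        msatd = m0d * rng.uniform(0.01, 1.0, size=m0d.shape)
        out = compute_mtr(vol(m0d, "MT_off"), vol(msatd, "MT_on")).data
        assert np.all((out >= 0) & (out < 1))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            compute_mtr(vol(np.zeros((2, 2, 2)), "MT_off"),
                        vol(np.zeros((3, 2, 2)), "MT_on"))

    def test_zero_reference_masked_out(self):
        m0d = np.full((2, 2, 1), 2.0)
        m0d[0, 0, 0] = 0.0
        out = compute_mtr(vol(m0d, "MT_off"), vol(np.ones((2, 2, 1)), "MT_on"))
        assert np.isnan(out.data[0, 0, 0]) and np.isfinite(out.data[1, 1, 0])


class TestT1Subtraction:
    def test_identical_gives_zero(self):
        pre = vol(np.random.default_rng(0).random((3, 3, 2)), "T1w_pre")
        assert np.allclose(t1_subtraction(pre, pre.with_data(pre.data,
                                                             "T1w_post")).data, 0)

    def test_lesion_offset_recovered(self):
        pre = vol(np.full((4, 4, 2), 1.0), "T1w_pre")
        lesion = np.zeros((4, 4, 2), dtype=bool)
        lesion[1:3, 1:3, :] = True
        post_data = pre.data + 0.2 * lesion
        sub = t1_subtraction(pre, vol(post_data, "T1w_post")).data
        assert np.allclose(sub[lesion], 0.2) and np.allclose(sub[~lesion], 0.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((2, 3, 4, 2))
        sub = t1_subtraction(vol(a, "T1w_pre"), vol(b, "T1w_post")).data
        for idx in np.ndindex(a.shape):
            assert sub[idx] == pytest.approx(b[idx] - a[idx])


class TestDetectEnhancement:
    def setup_method(self):
        self.lesion = np.zeros((6, 6, 3), dtype=bool)
        self.lesion[2:4, 2:4, 1] = True
        self.bg = ~self.lesion

    def test_zero_subtraction_not_enhancing(self):
        sub = vol(np.zeros((6, 6, 3)), "T1_subtraction")
        enhancing, mean = detect_enhancement(sub, self.lesion, self.bg)
        assert not enhancing and mean == 0.0

    def test_offset_above_noise_is_enhancing(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0.0, 0.01, size=(6, 6, 3))
        data[self.lesion] += 0.2
        enhancing, mean = detect_enhancement(
            vol(data, "T1_subtraction"), self.lesion, self.bg)
        assert enhancing and mean == pytest.approx(0.2, abs=0.02)

    def test_lesion_at_background_level_not_enhancing(self):
        data = np.full((6, 6, 3), 0.35)
        enhancing, _ = detect_enhancement(
            vol(data, "T1_subtraction"), self.lesion, self.bg)
        assert not enhancing

    def test_empty_mask_raises(self):
        sub = vol(np.zeros((6, 6, 3)), "T1_subtraction")
        with pytest.raises(ValueError, match="empty"):
            detect_enhancement(sub, np.zeros((6, 6, 3), bool), self.bg)


class TestSegmentLesions:
    def _grid(self):
        data = np.full((10, 10, 3), 0.70)
        wm = np.ones((10, 10, 3), dtype=bool)
        return data, wm

    def test_component_below_min_size_removed(self):
        data, wm = self._grid()
        data[0, 0:3, 0] = 0.9  # 3 voxels only
        lm = segment_lesions(Volume(data), wm)
        assert lm.n_components == 0 and not lm.labels.any()

    def test_nothing_above_threshold(self):
        data, wm = self._grid()
        lm = segment_lesions(Volume(data), wm)
        assert lm.n_components == 0

    def test_size_filter_keeps_only_large_component(self):
        data, wm = self._grid()
        data[1, 1:6, 1] = 0.95   # 5 voxels
        data[8, 0:3, 1] = 0.95   # 3 voxels
        lm = segment_lesions(Volume(data), wm)
        assert lm.n_components == 1
        assert int(np.count_nonzero(lm.labels)) == 5
        # flood-fill oracle: the surviving component is the 5-voxel one
        assert lm.labels[1, 3, 1] == 1 and lm.labels[8, 1, 1] == 0

    def test_labels_ordered_by_size_then_centroid(self):
        data, wm = self._grid()
        data[1, 1:6, 1] = 0.95   # 5 voxels at x=1
        data[7, 1:8, 1] = 0.95   # 7 voxels
        lm = segment_lesions(Volume(data), wm)
        assert lm.component_sizes() == {1: 7, 2: 5}

    def test_no_component_below_min_voxels_property(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0.6, 1.0, size=(12, 12, 4))
        wm = np.ones(data.shape, dtype=bool)
        lm = segment_lesions(Volume(data), wm, min_voxels=4)
        sizes = lm.component_sizes().values()
        assert all(s >= 4 for s in sizes)
        assert np.count_nonzero(lm.labels) <= np.count_nonzero(data > 0.80)

    def test_deterministic_labels(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(0.6, 1.0, size=(12, 12, 4))
        wm = np.ones(data.shape, dtype=bool)
        a = segment_lesions(Volume(data), wm)
        b = segment_lesions(Volume(data.copy()), wm.copy())
        assert np.array_equal(a.labels, b.labels)

    def test_warns_on_unnormalized_input(self, caplog):
        data, wm = self._grid()
        gm = np.zeros_like(wm)
        gm[0] = True
        data[0] = 5.0  # GM mean far from 1
        with caplog.at_level("WARNING"):
            segment_lesions(Volume(data), wm, gm_mask=gm)
        assert any("normalized" in r.message for r in caplog.records)

    def test_respects_wm_mask(self):
        data, wm = self._grid()
        data[1, 1:6, 1] = 0.95
        wm[:] = False
        lm = segment_lesions(Volume(data), wm)
        assert lm.n_components == 0


@settings(max_examples=25, derandomize=True)
@given(gain=st.floats(min_value=0.1, max_value=100.0,
                      allow_nan=False, allow_infinity=False))
def test_normalization_is_scale_invariant(gain):
    """Normalizing a rescaled volume recovers the same normalized image."""
    rng = np.random.default_rng(7)
    data = rng.uniform(10, 20, size=(4, 4, 2))
    gm = rng.random((4, 4, 2)) > 0.4
    base = normalize_to_gm(Volume(data), gm).data
    scaled = normalize_to_gm(Volume(data * gain), gm).data
    assert np.allclose(base, scaled, rtol=1e-9)
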