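"""K-means tumor detection, ADC labeling, ROI extraction, ADC fitting."""

from __future__ import annotations

import numpy as np
import pytest

from heteromap import (
    DEFAULT_ADC_CUTOFF,
    compute_adc,
    extract_roi,
    label_cellularity,
    segment_tumor_kmeans,
)
from heteromap.segmentation import (
    LABEL_BACKGROUND,
    LABEL_HIGH,
    LABEL_LOW,
    LABEL_UNCERTAIN,
    TumorMask,
)
from heteromap.volume import Volume


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestKMeansSegmentation:
    def test_high_contrast_phantom_dice(self, rng):
        """Tumor mean 100, background 10, sigma 1: Dice ≥ 0.99."""
        truth = np.zeros((8, 24, 24), dtype=bool)
        truth[2:6, 8:16, 6:18] = True
        data = np.where(truth, 100.0, 10.0) + rng.normal(0, 1.0, truth.shape)
        mask = segment_tumor_kmeans(Volume(data), k=2, seed=0)
        assert _dice(mask.mask, truth) >= 0.99

    def test_two_cluster_partition_small_example(self):
        """Intensities {0,0,0,10,10}: SSE-optimal 2-partition is {0},{10}."""
        data = np.array([0.0, 0.0, 0.0, 10.0, 10.0]).reshape(1, 1, 5)
        mask = segment_tumor_kmeans(Volume(data), k=2, seed=0)
        assert np.array_equal(mask.mask[0, 0], [False, False, False, True, True])

    def test_seed_invariance_for_separated_clusters(self, rng):
        truth = np.zeros((6, 20, 20), dtype=bool)
        truth[1:5, 5:15, 5:15] = True
        data = np.where(truth, 80.0, 5.0) + rng.normal(0, 1.0, truth.shape)
        vol = Volume(data)
        m1 = segment_tumor_kmeans(vol, k=2, seed=0)
        m2 = segment_tumor_kmeans(vol, k=2, seed=12345)
        assert np.array_equal(m1.mask, m2.mask)

    def test_largest_component_cleanup(self, rng):
        data = np.full((4, 20, 20), 5.0) + rng.normal(0, 0.5, (4, 20, 20))
        data[1:3, 3:9, 3:9] = 90.0     # main lesion
        data[3, 18, 18] = 90.0         # speck
        mask = segment_tumor_kmeans(Volume(data), k=2, seed=0)
        assert mask.mask[1:3, 3:9, 3:9].all()
        assert not mask.mask[3, 18, 18]

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            segment_tumor_kmeans(Volume(np.ones((4, 4, 4))), k=2, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            segment_tumor_kmeans(Volume(np.zeros((2, 2, 2))), k=1, seed=0)

    def test_default_phantom_dice(self, default_phantom):
        """At the phantom's contrast-to-noise (≫5) the mask matches truth."""
        mask = segment_tumor_kmeans(default_phantom.require_b(), seed=0)
        assert _dice(mask.mask, default_phantom.truth_tumor_mask) >= 0.95


class TestCellularityLabels:
    def _setup(self):
        adc = np.full((2, 3, 3), 1.2e-3)
        adc[0, 0, 0] = 0.5e-3
        adc[0, 0, 1] = 0.9e-3
        mask = np.zeros((2, 3, 3), dtype=bool)
        mask[0] = True
        return Volume(adc), TumorMask(mask)

    def test_threshold_assignments(self):
        adc, mask = self._setup()
        lab = label_cellularity(adc, mask, DEFAULT_ADC_CUTOFF, (0.85e-3, 1.0e-3))
        assert lab.labels[0, 0, 0] == LABEL_HIGH       # 0.5e-3 < cutoff
        assert lab.labels[0, 0, 1] == LABEL_UNCERTAIN  # in the band
        assert lab.labels[0, 1, 1] == LABEL_LOW        # 1.2e-3 above both
        assert np.all(lab.labels[1] == LABEL_BACKGROUND)

    def test_partition_property(self):
        adc, mask = self._setup()
        lab = label_cellularity(adc, mask, DEFAULT_ADC_CUTOFF, (0.85e-3, 1.0e-3))
        counts = lab.counts()
        assert counts["high"] + counts["low"] + counts["uncertain"] == mask.voxel_count

    def test_cutoff_monotonicity(self, default_phantom):
        mask = TumorMask(default_phantom.truth_tumor_mask)
        sizes = []
        for cutoff in (0.4e-3, 0.85e-3, 1.2e-3, 2.0e-3):
            lab = label_cellularity(default_phantom.adc, mask, cutoff, None)
            sizes.append(lab.counts()["high"])
        assert sizes == sorted(sizes)

    def test_binary_collapses_uncertain_to_low(self):
        adc, mask = self._setup()
        lab = label_cellularity(adc, mask, DEFAULT_ADC_CUTOFF, (0.85e-3, 1.0e-3))
        binary = lab.binary_within(mask.mask)
        assert binary.sum() == 1  # only the single sub-cutoff voxel

    def test_negative_adc_rejected(self):
        adc, mask = self._setup()
        bad = adc.data.copy()
        bad[0, 2, 2] = -1.0
        with pytest.raises(ValueError):
            label_cellularity(Volume(bad), mask)


class TestRoiExtraction:
    def test_bounding_box_arithmetic(self):
        mask = np.zeros((8, 9, 7), dtype=bool)
        mask[2:6, 3:8, 1:5] = True
        t2 = Volume(np.arange(8 * 9 * 7, dtype=float).reshape(8, 9, 7))
        roi = extract_roi(t2, TumorMask(mask))
        assert roi.t2.shape == (4, 5, 4)
        assert roi.offset == (2, 3, 1)
        assert roi.mask.mask.all()

    def test_full_mask_identity(self):
        t2 = Volume(np.random.default_rng(0).normal(size=(3, 4, 5)))
        roi = extract_roi(t2, TumorMask(np.ones((3, 4, 5), bool)))
        assert np.array_equal(roi.t2.data, t2.data)
        assert roi.offset == (0, 0, 0)

    def test_background_zeroed_and_roundtrip(self, default_phantom):
        mask = TumorMask(default_phantom.truth_tumor_mask)
        roi = extract_roi(default_phantom.t2, mask)
        assert np.all(roi.t2.data[~roi.mask.mask] == 0)
        crop_idx = np.argwhere(roi.mask.mask)
        orig_idx = roi.to_original(crop_idx)
        lookup = default_phantom.truth_tumor_mask[tuple(orig_idx.T)]
        assert lookup.all()
        assert len(orig_idx) == mask.voxel_count

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_roi(Volume(np.zeros((2, 2, 2))), TumorMask(np.zeros((2, 2, 2), bool)))


class TestComputeAdc:
    def test_two_point_inversion(self):
        s0 = Volume(np.full((1, 2, 2), 100.0))
        s1 = Volume(np.full((1, 2, 2), 100.0 * np.exp(-1200 * 0.85e-3)))
        adc = compute_adc({0.0: s0, 1200.0: s1})
        assert np.allclose(adc.data, 0.85e-3, atol=1e-9)

    def test_constant_signal_gives_zero(self):
        vols = {b: Volume(np.full((1, 2, 2), 50.0)) for b in (0.0, 600.0, 1200.0)}
        assert np.allclose(compute_adc(vols).data, 0.0)

    def test_three_b_noiseless_phantom_roundtrip(self, noiseless_phantom):
        adc = compute_adc(noiseless_phantom.dwi)
        rel = np.abs(adc.data - noiseless_phantom.truth_adc.data)
        rel /= noiseless_phantom.truth_adc.data
        assert rel.max() < 1e-6

    def test_nonpositive_signal_masked_to_zero(self):
        s0 = Volume(np.array([[[100.0, -1.0]]]))
        s1 = Volume(np.array([[[50.0, 10.0]]]))
        adc = compute_adc({0.0: s0, 1200.0: s1})
        assert adc.data[0, 0, 1] == 0.0
        assert adc.data[0, 0, 0] > 0

    def test_missing_b0_rejected(self):
        with pytest.raises(ValueError):
            compute_adc({600.0: Volume(np.ones((1, 1, 1))), 1200.0: Volume(np.ones((1, 1, 1)))})
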