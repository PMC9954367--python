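"""Mutual information, affine and Demons registration, RMS metric."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from heteromap import PhantomSpec, apply_misalignment, generate_phantom
from heteromap.registration import (
    AffineTransform,
    MetricError,
    RegistrationConfig,
    align_study,
    apply_deformation,
    mattes_mutual_information,
    register_affine,
    register_demons,
    rms_difference,
)
from heteromap.volume import Volume


class TestMutualInformation:
    def test_self_information_equals_marginal_entropy(self, rng):
        data = rng.normal(size=(6, 16, 16))
        vol = Volume(data)
        mi = mattes_mutual_information(vol, vol, n_bins=16, n_samples=1536, seed=3)
        # entropy of the sampled marginal with the same binning
        from heteromap.registration import _sample_positions

        pos = _sample_positions(vol, 1536 / data.size, 3)
        vals = data[tuple(pos.astype(int))]
        hist, _ = np.histogram(vals, bins=16)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(entropy, rel=1e-9)

    def test_independent_noise_has_near_zero_information(self, rng):
        fixed = Volume(rng.normal(size=(6, 16, 16)))
        mis = []
        for s in range(20):
            moving = Volume(np.random.default_rng(1000 + s).normal(size=(6, 16, 16)))
            mis.append(mattes_mutual_information(fixed, moving, n_bins=8, seed=3))
        mis = np.asarray(mis)
        self_mi = mattes_mutual_information(fixed, fixed, n_bins=8, seed=3)
        # small positive bias only, far below the self-information
        assert mis.mean() < 0.1 * self_mi
        assert mis[0] <= mis.mean() + 3 * mis.std()

    def test_invariance_to_intensity_inversion(self):
        """MI depends on the joint histogram only: inverting the intensities
        of one image (a bijective relabeling with equal bin occupancy)
        leaves it unchanged.  Checked on an 8×8 discrete toy image."""
        rng = np.random.default_rng(0)
        data = rng.integers(0, 4, size=(1, 8, 8)).astype(float)
        vol = Volume(data)
        inverted = Volume(3.0 - data)
        n = data.size
        mi_self = mattes_mutual_information(vol, vol, n_bins=4, n_samples=n, seed=0)
        mi_inv = mattes_mutual_information(vol, inverted, n_bins=4, n_samples=n, seed=0)
        assert mi_inv == pytest.approx(mi_self, abs=1e-12)

    def test_invalid_bins(self):
        vol = Volume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            mattes_mutual_information(vol, vol, n_bins=1)

    def test_disjoint_supports_raise_metric_error(self):
        fixed = Volume(np.ones((2, 4, 4)))
        moving = Volume(np.ones((2, 4, 4)), origin=(1000.0, 0.0, 0.0))
        with pytest.raises(MetricError):
            mattes_mutual_information(fixed, moving, seed=0)


class TestRmsDifference:
    def test_identity_and_offset(self):
        a = Volume(np.arange(8.0).reshape(2, 2, 2))
        assert rms_difference(a, a) == 0.0
        b = a.with_data(a.data + 3.0)
        assert rms_difference(a, b) == pytest.approx(3.0)

    def test_hand_arithmetic(self):
        a = Volume(np.array([0.0, 0.0]).reshape(1, 1, 2))
        b = Volume(np.array([3.0, 4.0]).reshape(1, 1, 2))
        assert rms_difference(a, b) == pytest.approx(np.sqrt(12.5))

    def test_symmetry_and_mask(self, rng):
        a = Volume(rng.normal(size=(2, 3, 3)))
        b = Volume(rng.normal(size=(2, 3, 3)))
        assert rms_difference(a, b) == pytest.approx(rms_difference(b, a))
        mask = np.zeros((2, 3, 3), bool)
        mask[0, 0, 0] = True
        assert rms_difference(a, b, mask) == pytest.approx(abs(a.data[0, 0, 0] - b.data[0, 0, 0]))
        with pytest.raises(ValueError):
            rms_difference(a, b, np.zeros((2, 3, 3), bool))

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            rms_difference(Volume(np.zeros((2, 2, 2))), Volume(np.zeros((2, 2, 3))))


class TestAffineRegistration:
    def test_identical_volumes_recover_identity(self, default_phantom):
        vol = default_phantom.t2
        res = register_affine(vol, vol)
        assert np.all(np.abs(res.transform.translation) < 0.5)
        # rotation angle from the linear part
        from scipy.linalg import polar

        U, _ = polar(res.transform.matrix)
        angle = np.degrees(np.arccos(np.clip((np.trace(U) - 1) / 2, -1, 1)))
        assert angle < 0.5

    def test_known_translation_recovered(self):
        spec = PhantomSpec(seed=8, noise_sigma=0.0, translation_mm=(0.0, 5.0, 0.0))
        case = generate_phantom(spec)
        moved = apply_misalignment(case, spec)
        res = register_affine(case.t2, moved.dwi[0.0])
        assert abs(res.transform.translation[1] - 5.0) < 0.5
        assert abs(res.transform.translation[0]) < 0.5
        assert abs(res.transform.translation[2]) < 0.5

    def test_constant_moving_image_flags_warning(self, default_phantom):
        const = default_phantom.t2.with_data(np.zeros(default_phantom.t2.shape))
        res = register_affine(default_phantom.t2, const)
        assert res.warning is not None

    def test_optimizer_trace_recorded(self, default_phantom):
        vol = default_phantom.t2
        res = register_affine(vol, vol)
        assert len(res.trace) > 10
        assert all(np.isfinite(m) for _, m in res.trace)


def _bump_warped_pair(sigma_img=2.0):
    """Band-limited mono-modal pair differing by a smooth ~2 mm bump warp."""
    case = generate_phantom(PhantomSpec(seed=3, noise_sigma=0.0))
    f = Volume(
        ndimage.gaussian_filter(case.t2.data, [sigma_img / s for s in case.t2.spacing]),
        case.t2.spacing,
    )
    shape, spacing = f.shape, np.array(f.spacing)
    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, f.spacing)), indexing="ij"
    )
    c = f.center_world()
    bump = 2.0 * np.exp(
        -(((yy - c[1]) / 10) ** 2 + ((xx - c[2]) / 10) ** 2 + ((zz - c[0]) / 8) ** 2)
    )
    u = np.zeros((3,) + shape)
    u[1], u[2] = bump, -0.5 * bump
    base = np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij"))
    m = ndimage.map_coordinates(
        f.data, base + u / spacing.reshape(3, 1, 1, 1), order=1, mode="nearest"
    )
    return f, Volume(m, f.spacing)


class TestDemons:
    def test_identical_images_zero_field(self, default_phantom):
        vol = default_phantom.t2
        res = register_demons(vol, vol, RegistrationConfig(demons_histogram_match=False))
        assert res.field.magnitude.max() < 1e-6

    def test_bump_warp_reduces_rms_to_fifth(self):
        f, m = _bump_warped_pair()
        pre = rms_difference(f, m)
        # regularization matched to the ~1 cm bump (narrower than the
        # default inter-sequence warp scale)
        cfg = RegistrationConfig(demons_histogram_match=False, demons_sigma_mm=1.0)
        res = register_demons(f, m, cfg)
        warped = apply_deformation(m, f, AffineTransform.identity(f.center_world()), res.field)
        assert rms_difference(f, warped) <= 0.2 * pre

    def test_rms_trace_non_increasing(self):
        f, m = _bump_warped_pair()
        res = register_demons(f, m, RegistrationConfig(demons_histogram_match=False))
        trace = res.rms_trace
        assert len(trace) > 2
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_zero_gradient_fixed_warns(self):
        flat = Volume(np.zeros((3, 8, 8)))
        res = register_demons(flat, flat, RegistrationConfig())
        assert res.warning is not None
        assert np.all(res.field.displacement == 0)


class TestAlignStudy:
    def test_zero_misalignment_is_near_identity(self):
        spec = PhantomSpec(seed=12)
        case = generate_phantom(spec)
        raw = apply_misalignment(case, spec)  # identity, but flagged raw
        aligned = align_study(raw)
        assert aligned.alignment == "aligned"
        assert np.all(np.abs(aligned.meta["transform"]["affine"].translation) < 0.5)
        rms = aligned.meta["registration"]["rms"]["dwi_b1200"]
        assert rms["rms_after"] <= rms["rms_before"] * 1.01

    def test_misaligned_phantom_recovers(self):
        spec = PhantomSpec(
            seed=13,
            translation_mm=(1.0, 4.0, -5.0),
            rotation_deg=(6.0, 1.5, -1.5),
            warp_amplitude_mm=1.0,
        )
        case = generate_phantom(spec)
        raw = apply_misalignment(case, spec)
        aligned = align_study(raw)
        truth = case.require_b().data
        pre = np.sqrt(np.mean((raw.require_b().data - truth) ** 2))
        post = np.sqrt(np.mean((aligned.require_b().data - truth) ** 2))
        assert post <= 0.5 * pre

        # low-ADC tumor centroid back within 1 voxel of its true position
        # (restrict to the tumor neighbourhood; the bone-like anchors are
        # low-ADC as well)
        near_tumor = ndimage.binary_dilation(case.truth_tumor_mask, iterations=3)
        sel = lambda d: (d < 0.85e-3) & near_tumor
        true_c = np.array(ndimage.center_of_mass(sel(case.adc.data)))
        rec_c = np.array(ndimage.center_of_mass(sel(aligned.adc.data)))
        assert np.all(np.abs(true_c - rec_c) <= 1.0)

    def test_requires_raw_case(self, default_phantom):
        with pytest.raises(ValueError):
            align_study(default_phantom)
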