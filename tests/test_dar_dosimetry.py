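"""Activity calibration, cloning/sequential dose rates, gamma analysis."""

import numpy as np
import pytest

from alphadose3d import (
    AC225_CHAIN,
    ActivityImage,
    ActivityVolume,
    CalibrationFactors,
    CountImage,
    DoseRateImage,
    assemble_3d,
    clone_volume,
    convolve_dose_rate,
    counts_to_activity_image,
    extract_plane,
    gamma_index,
    method_error,
    sampling_plan,
    sequential_dose_rate,
)
from alphadose3d.dar_dosimetry import SECONDS_PER_HOUR
from alphadose3d.phantoms import simulate_counts

from conftest import gamma_exhaustive


class TestActivityCalibration:
    def test_absolute_efficiency_is_38_percent(self):
        cal = CalibrationFactors()
        assert round(cal.absolute_efficiency * 100) == 38

    def test_zero_counts_zero_activity(self):
        img = CountImage(np.zeros((8, 8)), 39.0, 10.0, live_time=600.0)
        out = counts_to_activity_image(img, CalibrationFactors(), AC225_CHAIN)
        assert np.all(out.activity == 0.0)

    def test_known_counts_inversion(self):
        cal = CalibrationFactors()
        counts = np.full((4, 4), 1000.0)
        img = CountImage(counts, 39.0, 10.0, live_time=100.0)
        out = counts_to_activity_image(img, cal, AC225_CHAIN)
        expected = (
            1000.0
            * cal.frame_factor
            / (AC225_CHAIN.alphas_per_chain * 0.5 * (1 - 0.238) * 100.0)
        )
        assert np.allclose(out.activity, expected)

    def test_decay_correction_applied(self):
        cal = CalibrationFactors()
        img = CountImage(np.ones((2, 2)), 39.0, 10.0, live_time=1.0,
                         acquisition_start_offset=AC225_CHAIN.parent.half_life)
        out = counts_to_activity_image(img, cal, AC225_CHAIN)
        img0 = CountImage(np.ones((2, 2)), 39.0, 10.0, live_time=1.0)
        out0 = counts_to_activity_image(img0, cal, AC225_CHAIN)
        assert np.allclose(out.activity, 2.0 * out0.activity)

    def test_round_trip_unbiased(self):
        cal = CalibrationFactors()
        truth = ActivityImage(np.full((16, 16), 0.02), 39.0, 10.0)
        recovered = []
        for rep in range(100):
            counts = simulate_counts(truth, cal, 3600.0, AC225_CHAIN, rng=rep)
            rec = counts_to_activity_image(counts, cal, AC225_CHAIN)
            recovered.append(rec.activity.mean())
        mean_counts = 0.02 * 4 * 0.38 * 3600 / cal.frame_factor
        sigma_rel = 1.0 / np.sqrt(mean_counts * 256 * 100)
        assert np.mean(recovered) == pytest.approx(0.02, rel=2 * sigma_rel * 3)


class TestCloneVolume:
    def test_single_clone_is_identity(self):
        img = ActivityImage(np.arange(12.0).reshape(3, 4), 39.0, 10.0)
        vol = clone_volume(img, 1)
        assert vol.activity.shape == (1, 3, 4)
        assert np.array_equal(vol.activity[0], img.activity)

    def test_sum_conservation_exact(self):
        img = ActivityImage(np.random.default_rng(0).random((10, 10)), 39.0, 10.0)
        vol = clone_volume(img, 21)
        assert vol.activity.sum() == pytest.approx(21 * img.activity.sum(), rel=1e-15)
        for plane in vol.activity:
            assert np.array_equal(plane, img.activity)

    def test_even_clone_count_rejected(self):
        img = ActivityImage(np.ones((4, 4)), 39.0, 10.0)
        with pytest.raises(ValueError, match="odd"):
            clone_volume(img, 10)


class TestConvolution:
    def test_delta_source_reproduces_kernel(self, iso_kernel):
        shape = iso_kernel.voxel_kernel.shape
        n = 21
        act = np.zeros((n, n, n))
        act[n // 2, n // 2, n // 2] = 7.0  # Bq
        vol = ActivityVolume(act, iso_kernel.voxel_dims)
        rate = convolve_dose_rate(vol, iso_kernel).dose_rate
        kz, ky, kx = shape
        c = n // 2
        sub = rate[
            c - kz // 2 : c + kz // 2 + 1,
            c - ky // 2 : c + ky // 2 + 1,
            c - kx // 2 : c + kx // 2 + 1,
        ]
        expected = 7.0 * SECONDS_PER_HOUR * iso_kernel.voxel_kernel
        assert np.allclose(sub, expected, rtol=1e-9, atol=expected.max() * 1e-12)

    def test_uniform_interior_equilibrium(self, iso_kernel):
        n = 21
        vol = ActivityVolume(np.full((n, n, n), 0.5), iso_kernel.voxel_dims)
        rate = convolve_dose_rate(vol, iso_kernel).dose_rate
        expected = 0.5 * SECONDS_PER_HOUR * iso_kernel.voxel_kernel.sum()
        c = n // 2
        assert rate[c, c, c] == pytest.approx(expected, rel=1e-9)

    def test_against_double_sum_oracle(self, iso_kernel):
        rng = np.random.default_rng(5)
        act = rng.random((21, 21, 21))
        vol = ActivityVolume(act, iso_kernel.voxel_dims)
        rate = convolve_dose_rate(vol, iso_kernel).dose_rate
        kern = iso_kernel.voxel_kernel
        kz, ky, kx = kern.shape
        oracle = np.zeros_like(act)
        pz, py, px = kz // 2, ky // 2, kx // 2
        padded = np.pad(act, ((pz, pz), (py, py), (px, px)))
        for dz in range(kz):
            for dy in range(ky):
                for dx in range(kx):
                    w = kern[kz - 1 - dz, ky - 1 - dy, kx - 1 - dx]
                    if w:
                        oracle += w * padded[dz : dz + 21, dy : dy + 21, dx : dx + 21]
        oracle *= SECONDS_PER_HOUR
        rel = np.abs(rate - oracle) / oracle.max()
        assert rel.max() < 1e-8

    def test_linearity(self, iso_kernel):
        rng = np.random.default_rng(9)
        a1 = rng.random((9, 9, 9))
        a2 = rng.random((9, 9, 9))
        dims = iso_kernel.voxel_dims
        r12 = convolve_dose_rate(ActivityVolume(a1 + a2, dims), iso_kernel).dose_rate
        r1 = convolve_dose_rate(ActivityVolume(a1, dims), iso_kernel).dose_rate
        r2 = convolve_dose_rate(ActivityVolume(a2, dims), iso_kernel).dose_rate
        assert np.allclose(r12, r1 + r2, rtol=1e-10, atol=r12.max() * 1e-10)

    def test_dim_mismatch_rejected(self, iso_kernel):
        vol = ActivityVolume(np.ones((5, 5, 5)), (39.0, 39.0, 10.0))
        with pytest.raises(ValueError, match="voxel dims"):
            convolve_dose_rate(vol, iso_kernel)


class TestSequentialVsCloning:
    def test_identical_slices_match_cloning(self, voxel_kernel):
        rng = np.random.default_rng(3)
        plane = rng.random((24, 24))
        img = ActivityImage(plane, 39.0, 10.0)
        slices = [ActivityImage(plane.copy(), 39.0, 10.0) for _ in range(21)]
        seq = sequential_dose_rate(slices, voxel_kernel)
        clone = convolve_dose_rate(clone_volume(img, 21), voxel_kernel)
        central = clone.dose_rate[10]
        assert np.allclose(seq.dose_rate, central, rtol=1e-10, atol=central.max() * 1e-12)
        assert method_error(DoseRateImage(central, 39.0, 10.0), seq) < 1e-8

    def test_z_gradient_against_oracle(self, voxel_kernel):
        # linear-in-z activity: central-plane dose equals the direct sum
        n = 21
        slices = [
            ActivityImage(np.full((16, 16), 1.0 + 0.05 * z), 39.0, 10.0)
            for z in range(n)
        ]
        seq = sequential_dose_rate(slices, voxel_kernel)
        act = np.stack([s.activity for s in slices])
        kern = voxel_kernel.voxel_kernel
        kz, ky, kx = kern.shape
        pz, py, px = kz // 2, ky // 2, kx // 2
        padded = np.pad(act, ((pz, pz), (py, py), (px, px)))
        centre = n // 2
        oracle = np.zeros((16, 16))
        for dz in range(kz):
            for dy in range(ky):
                for dx in range(kx):
                    w = kern[kz - 1 - dz, ky - 1 - dy, kx - 1 - dx]
                    if w:
                        oracle += w * padded[centre + dz, dy : dy + 16, dx : dx + 16]
        oracle *= SECONDS_PER_HOUR
        assert np.allclose(seq.dose_rate, oracle, rtol=1e-8, atol=oracle.max() * 1e-10)

    def test_too_few_slices_rejected(self, voxel_kernel):
        img = ActivityImage(np.ones((4, 4)), 39.0, 10.0)
        with pytest.raises(ValueError, match="at least 3"):
            sequential_dose_rate([img], voxel_kernel)

    def test_method_error_scaling(self):
        base = DoseRateImage(np.full((8, 8), 2.0), 39.0, 10.0)
        scaled = DoseRateImage(base.dose_rate * 1.05, 39.0, 10.0)
        assert method_error(base, base) == 0.0
        assert method_error(scaled, base) == pytest.approx(5.0)


class TestAssemble3D:
    def test_paper_voxel_geometry(self):
        slices = [
            DoseRateImage(np.full((6, 6), float(k)), 39.0, 10.0) for k in range(23)
        ]
        vol = assemble_3d(slices, z_pitch=200.0)
        assert vol.voxel_dims == (39.0, 39.0, 210.0)
        assert vol.dose_rate.shape == (23, 6, 6)
        assert vol.dose_rate.mean() == pytest.approx(
            np.mean([s.dose_rate.mean() for s in slices])
        )

    def test_round_trip_extraction(self):
        rng = np.random.default_rng(1)
        slices = [DoseRateImage(rng.random((5, 7)), 39.0, 10.0) for _ in range(4)]
        vol = assemble_3d(slices, 200.0)
        for k, s in enumerate(slices):
            assert np.array_equal(extract_plane(vol, k).dose_rate, s.dose_rate)


class TestSamplingPlan:
    @pytest.mark.parametrize(
        "extent,pitch,per_pos,positions,total",
        [
            (5000.0, 200.0, 1, 25, 25),
            (5000.0, 200.0, 10, 25, 250),
            (5000.0, 10.0, 1, 500, 500),
        ],
    )
    def test_paper_counts(self, extent, pitch, per_pos, positions, total):
        assert sampling_plan(extent, pitch, per_pos) == (positions, total)

    def test_pitch_exceeding_extent_warns(self):
        with pytest.warns(UserWarning, match="zero positions"):
            positions, total = sampling_plan(100.0, 200.0, 1)
        assert positions == 0 and total == 0


class TestGammaIndex:
    def test_identical_images_all_zero(self):
        img = DoseRateImage(np.random.default_rng(0).random((16, 16)) + 0.5, 39.0, 10.0)
        res = gamma_index(img, img)
        assert np.all(res.gamma_map == 0.0)
        assert res.pass_rate == 1.0

    def test_uniform_scaling_closed_form(self):
        ref = DoseRateImage(np.full((12, 12), 10.0), 39.0, 10.0)
        ev = DoseRateImage(np.full((12, 12), 10.5), 39.0, 10.0)
        res = gamma_index(ref, ev, dose_tol=0.10, normalization="local")
        assert np.allclose(res.gamma_map, 0.5)

    @pytest.mark.parametrize("normalization", ["local", "global"])
    def test_against_exhaustive_oracle(self, normalization):
        rng = np.random.default_rng(17)
        ref = rng.random((32, 32)) + 0.5
        ev = ref * (1 + 0.15 * rng.standard_normal((32, 32)))
        ev = np.clip(ev, 0.01, None)
        px = 39.0
        res = gamma_index(
            DoseRateImage(ref, px, 10.0),
            DoseRateImage(ev, px, 10.0),
            dose_tol=0.10,
            dist_tol=117.0,
            normalization=normalization,
            search_factor=100.0,  # wide enough that the search is exhaustive
        )
        oracle = gamma_exhaustive(ref, ev, 0.10, 117.0, px, normalization)
        assert np.allclose(res.gamma_map, oracle, atol=1e-10)

    def test_scale_invariance_local(self):
        rng = np.random.default_rng(2)
        ref = rng.random((16, 16)) + 0.5
        ev = ref * (1 + 0.1 * rng.standard_normal((16, 16)))
        r1 = gamma_index(DoseRateImage(ref, 39.0, 10.0), DoseRateImage(ev, 39.0, 10.0))
        r2 = gamma_index(
            DoseRateImage(7.3 * ref, 39.0, 10.0), DoseRateImage(7.3 * ev, 39.0, 10.0)
        )
        assert np.allclose(r1.gamma_map, r2.gamma_map, rtol=1e-12)

    def test_low_dose_floor_excludes(self):
        ref = np.ones((8, 8))
        ref[0] = 0.001  # below a 10% floor
        ev = ref.copy()
        ev[0] = 0.1  # large local discrepancy in floored region
        res = gamma_index(
            DoseRateImage(ref, 39.0, 10.0), DoseRateImage(ev, 39.0, 10.0), floor=0.10
        )
        assert res.pass_rate == 1.0
        assert res.evaluated.sum() == 56

    def test_all_floored_rejected(self):
        ref = DoseRateImage(np.ones((4, 4)), 39.0, 10.0)
        with pytest.raises(ValueError, match="floor"):
            gamma_index(ref, ref, floor=1.5)


class TestCloningFoundingAssumption:
    def test_cloning_equals_sequential_on_z_uniform_phantom(self, voxel_kernel):
        """On a z-uniform activity distribution the two methods coincide."""
        rng = np.random.default_rng(8)
        plane = rng.random((20, 20)) * 0.01
        img = ActivityImage(plane, 39.0, 10.0)
        n = 21
        seq = sequential_dose_rate(
            [ActivityImage(plane.copy(), 39.0, 10.0) for _ in range(n)], voxel_kernel
        )
        clone = convolve_dose_rate(clone_volume(img, n), voxel_kernel)
        central = clone.dose_rate[n // 2]
        rel = np.abs(central - seq.dose_rate) / seq.dose_rate.max()
        assert rel.max() < 1e-6
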