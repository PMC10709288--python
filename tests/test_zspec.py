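"""Static Z-spectrum analysis tests: normalization, B0 mapping and
correction, two-pool fitting, glucoCEST."""

import numpy as np
import pytest

import dgecest as d
from dgecest.phantom import WM
from dgecest.zspec import HYDROXYL_FWHM_PPM, HYDROXYL_OFFSET_PPM

from conftest import single_voxel_zvol


class TestGridStep:
    def test_one_hertz_at_3t_is_0p0078_ppm(self):
        assert d.b0_grid_step_ppm() == pytest.approx(0.0078, abs=1e-12)


class TestNormalize:
    def test_all_frames_equal_s0_gives_unit_z(self, volunteer_schedule):
        series = np.full((3, 3, 2, len(volunteer_schedule)), 500.0)
        zvol = d.normalize(series, volunteer_schedule)
        assert np.all(zvol.z == 1.0)
        assert zvol.z.shape[-1] == 35

    def test_half_signal_gives_half_z(self, volunteer_schedule):
        series = np.full((2, 2, 1, len(volunteer_schedule)), 100.0)
        idx6 = np.nonzero(np.isclose(volunteer_schedule.offsets_ppm, 6.0))[0]
        sat = np.nonzero(~volunteer_schedule.is_reference)[0]
        series[..., sat[idx6[0]]] = 50.0
        zvol = d.normalize(series, volunteer_schedule)
        assert np.all(zvol.at_offset(6.0) == 0.5)

    def test_nonpositive_s0_flagged_as_nan(self, volunteer_schedule):
        series = np.full((2, 2, 1, len(volunteer_schedule)), 100.0)
        series[0, 0, 0, :] = 0.0
        zvol = d.normalize(series, volunteer_schedule)
        assert np.all(np.isnan(zvol.z[0, 0, 0]))
        assert np.all(np.isfinite(zvol.z[1, 1, 0]))

    def test_length_mismatch_rejected(self, volunteer_schedule):
        with pytest.raises(ValueError, match="frames"):
            d.normalize(np.zeros((2, 2, 1, 10)), volunteer_schedule)

    def test_roundtrip_matches_forward_model(self):
        truth = d.default_phantom(shape=(8, 8, 3), b0_amplitude_ppm=0.0)
        frames, _ = d.simulate_static_scan(truth)
        sched = d.OffsetSchedule.volunteer_static()
        zvol = d.normalize(frames, sched)
        vox = tuple(np.argwhere(truth.label_map == WM)[0])
        expected = d.zspectrum_forward(truth.pool_params[WM],
                                       sched.offsets_ppm)
        np.testing.assert_allclose(zvol.z[vox], expected, atol=1e-12)


class TestFitB0Map:
    @pytest.mark.parametrize("shift", [0.0, 0.10])
    def test_single_voxel_recovery(self, volunteer_schedule, wm_pools,
                                   shift):
        zvol = single_voxel_zvol(wm_pools, volunteer_schedule.offsets_ppm,
                                 b0_shift=shift)
        b0 = d.fit_b0_map(zvol)
        assert abs(b0.shift_ppm[0, 0, 0] - shift) <= 0.0078 + 1e-12

    def test_recovery_over_grid_of_shifts(self, volunteer_schedule,
                                          wm_pools):
        """Noiseless shifts in {-0.2 .. 0.2} ppm recovered to within one
        1-Hz grid step."""
        errs = []
        for shift in (-0.2, -0.1, 0.0, 0.1, 0.2):
            zvol = single_voxel_zvol(wm_pools,
                                     volunteer_schedule.offsets_ppm,
                                     b0_shift=shift)
            b0 = d.fit_b0_map(zvol)
            errs.append(abs(b0.shift_ppm[0, 0, 0] - shift))
        assert max(errs) <= 0.0078 + 1e-12

    def test_robust_to_solute_signal(self, volunteer_schedule, wm_pools):
        """A calibrated 10-mM glucose pool does not displace the water-line
        estimate (the multi-pool fit absorbs it)."""
        glu = d.LorentzianPool(0.04, HYDROXYL_FWHM_PPM, HYDROXYL_OFFSET_PPM)
        shift = 0.1
        zvol = single_voxel_zvol(wm_pools, volunteer_schedule.offsets_ppm,
                                 b0_shift=shift, extra_pools=[glu])
        b0 = d.fit_b0_map(zvol)
        assert abs(b0.shift_ppm[0, 0, 0] - shift) <= 0.0078 + 1e-12

    def test_noise_robustness_median_bound(self, volunteer_schedule,
                                           wm_pools):
        """Gaussian noise sigma=0.005 on Z moves the B0 estimate by at most
        0.03 ppm in the median over voxels."""
        rng = np.random.default_rng(42)
        n = 100
        shift = 0.05
        z0 = d.zspectrum_forward(wm_pools, volunteer_schedule.offsets_ppm,
                                 shift)
        z = np.tile(z0, (n, 1, 1, 1)) + rng.normal(0.0, 0.005,
                                                   (n, 1, 1, z0.size))
        zvol = d.ZSpectrumVolume(z, volunteer_schedule.offsets_ppm,
                                 np.ones((n, 1, 1)))
        b0 = d.fit_b0_map(zvol)
        med = np.median(np.abs(b0.shift_ppm - shift))
        assert med <= 0.03

    def test_too_few_subset_offsets_rejected(self):
        offsets = np.array([0.0, 0.5, 3.0, 4.0])
        zvol = d.ZSpectrumVolume(np.ones((1, 1, 1, 4)), offsets,
                                 np.ones((1, 1, 1)))
        with pytest.raises(ValueError, match="subset"):
            d.fit_b0_map(zvol)


class TestCorrectZspectrumB0:
    def test_zero_shift_is_identity(self, volunteer_schedule, wm_pools):
        zvol = single_voxel_zvol(wm_pools, volunteer_schedule.offsets_ppm)
        b0 = d.B0Map(np.zeros((1, 1, 1)))
        out = d.correct_zspectrum_b0(zvol, b0)
        np.testing.assert_array_equal(out.z, zvol.z)

    def test_exact_for_linear_spectrum(self):
        offsets = np.linspace(-3.0, 3.0, 13)
        z = (0.5 + 0.05 * offsets).reshape(1, 1, 1, -1)
        zvol = d.ZSpectrumVolume(z, offsets, np.ones((1, 1, 1)))
        b0 = d.B0Map(np.full((1, 1, 1), 0.31))
        out = d.correct_zspectrum_b0(zvol, b0)
        expected = 0.5 + 0.05 * (offsets + 0.31)
        inside = offsets + 0.31 <= offsets[-1]
        np.testing.assert_allclose(out.z[0, 0, 0, inside],
                                   expected[inside], atol=1e-12)

    def test_improves_match_to_unshifted_model(self, volunteer_schedule,
                                               wm_pools):
        """Corrected spectra deviate less from the zero-shift forward model
        than uncorrected ones."""
        offsets = volunteer_schedule.offsets_ppm
        shift = 0.15
        zvol = single_voxel_zvol(wm_pools, offsets, b0_shift=shift)
        ref = d.zspectrum_forward(wm_pools, offsets)
        b0 = d.fit_b0_map(zvol)
        out = d.correct_zspectrum_b0(zvol, b0)
        inner = np.abs(offsets) <= 4.0
        before = np.abs(zvol.z[0, 0, 0, inner] - ref[inner]).max()
        after = np.abs(out.z[0, 0, 0, inner] - ref[inner]).max()
        assert after < before


class TestFitTwoPool:
    def test_recovers_noiseless_amplitudes(self, volunteer_schedule):
        pools = (d.LorentzianPool(0.82, 2.4, 0.0),
                 d.LorentzianPool(0.07, 22.0, 0.0))
        zvol = single_voxel_zvol(pools, volunteer_schedule.offsets_ppm)
        maps = d.fit_two_pool(zvol)
        assert maps["converged"][0, 0, 0]
        assert maps["ds_amplitude"][0, 0, 0] == pytest.approx(0.82,
                                                              abs=1e-3)
        assert maps["mt_amplitude"][0, 0, 0] == pytest.approx(0.07,
                                                              abs=1e-3)

    def test_pure_water_voxel_has_no_mt(self, volunteer_schedule):
        pools = (d.LorentzianPool(0.94, 2.0, 0.0),)
        zvol = single_voxel_zvol(pools, volunteer_schedule.offsets_ppm)
        maps = d.fit_two_pool(zvol)
        assert maps["mt_amplitude"][0, 0, 0] <= 0.01

    def test_glucose_pool_barely_perturbs_ds_amplitude(self,
                                                       volunteer_schedule,
                                                       wm_pools):
        """The fitted direct-saturation amplitude moves by less than the
        added glucose amplitude (the fit subset avoids 1.2 ppm)."""
        glu_amp = 0.04
        glu = d.LorentzianPool(glu_amp, HYDROXYL_FWHM_PPM,
                               HYDROXYL_OFFSET_PPM)
        z_clean = single_voxel_zvol(wm_pools, volunteer_schedule.offsets_ppm)
        z_glu = single_voxel_zvol(wm_pools, volunteer_schedule.offsets_ppm,
                                  extra_pools=[glu])
        a0 = d.fit_two_pool(z_clean)["ds_amplitude"][0, 0, 0]
        a1 = d.fit_two_pool(z_glu)["ds_amplitude"][0, 0, 0]
        assert abs(a1 - a0) < glu_amp


class TestComputeGlucocest:
    def _zvol(self, value12, value20):
        offsets = np.array([1.2, 2.0, 3.0])
        z = np.array([value12, value20, 0.9]).reshape(1, 1, 1, 3)
        return d.ZSpectrumVolume(z, offsets, np.ones((1, 1, 1)))

    def test_identical_inputs_give_zero(self):
        a = self._zvol(0.6, 0.7)
        assert d.compute_glucocest(a, a, 1.2)[0, 0, 0] == 0.0

    def test_direct_difference_arithmetic(self):
        base = self._zvol(0.60, 0.70)
        post = self._zvol(0.58, 0.67)
        assert d.compute_glucocest(base, post, 1.2)[0, 0, 0] == \
            pytest.approx(0.02, abs=1e-12)
        assert d.compute_glucocest(base, post, 2.0)[0, 0, 0] == \
            pytest.approx(0.03, abs=1e-12)

    def test_antisymmetric_under_swap(self):
        base = self._zvol(0.61, 0.72)
        post = self._zvol(0.55, 0.69)
        fwd = d.compute_glucocest(base, post, 2.0)
        rev = d.compute_glucocest(post, base, 2.0)
        np.testing.assert_allclose(fwd, -rev, atol=1e-15)

    def test_unknown_offset_names_alternatives(self):
        a = self._zvol(0.6, 0.7)
        with pytest.raises(ValueError, match="available"):
            d.compute_glucocest(a, a, 5.5)

    def test_linear_in_simulated_concentration(self):
        """Noiseless, shift-free phantom glucoCEST equals concentration
        times sensitivity to within 1e-6."""
        truth = d.default_phantom(shape=(6, 6, 3), b0_amplitude_ppm=0.0)
        sched = d.OffsetSchedule.volunteer_static()
        base, _ = d.simulate_static_scan(truth, state="baseline")
        zb = d.normalize(base, sched)
        vox = tuple(np.argwhere(truth.label_map == WM)[0])
        for c in (1.0, 4.0, 8.0):
            post, _ = d.simulate_static_scan(truth, state="postinfusion",
                                             concentration_mM=c)
            zp = d.normalize(post, sched)
            g = d.compute_glucocest(zb, zp, 2.0)[vox]
            assert g == pytest.approx(c * truth.glucose_sensitivity[WM],
                                      abs=1e-6)
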