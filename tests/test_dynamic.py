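"""Dynamic DGE tests: interleave splitting, dynamic B0 correction, PCA
denoising, DGE computation and time blocks."""

import numpy as np
import pytest

import dgecest as d
from dgecest.phantom import SS
from dgecest.zspec import B0Map


def make_series(n, spatial=(2, 2, 1), values=None, offsets=None,
                normalized=True):
    frames = np.ones(spatial + (n,))
    if values is not None:
        frames = frames * np.asarray(values)
    if offsets is None:
        offsets = np.where(np.arange(n) % 2 == 0, 1.2, 2.0)
    return d.DynamicSeries(frames, offsets, 7.2 * np.arange(n),
                           s0=np.ones(spatial), normalized=normalized)


class TestSplitInterleaved:
    @pytest.mark.parametrize("n,per", [(128, 64), (88, 44), (2, 1)])
    def test_split_counts(self, n, per):
        low, high = d.split_interleaved(make_series(n))
        assert low.n_frames == per and high.n_frames == per
        assert np.all(low.offsets_ppm == 1.2)
        assert np.all(high.offsets_ppm == 2.0)

    def test_original_times_preserved(self):
        low, high = d.split_interleaved(make_series(6))
        np.testing.assert_allclose(low.times_s, [0.0, 14.4, 28.8])
        np.testing.assert_allclose(high.times_s, [7.2, 21.6, 36.0])

    def test_non_alternating_labels_listed(self):
        offsets = np.array([1.2, 2.0, 2.0, 1.2])
        with pytest.raises(ValueError, match=r"\[2\]"):
            d.split_interleaved(make_series(4, offsets=offsets))

    def test_unnormalized_series_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            d.split_interleaved(make_series(4, normalized=False))


class TestInterpolateB0Series:
    def test_identical_endpoints_constant(self):
        m = B0Map(np.full((2, 2, 1), 0.05))
        series = d.interpolate_b0_series(m, m, [10.0, 20.0, 30.0])
        assert np.all(series.shifts == 0.05)

    def test_midpoint_is_average(self):
        a = B0Map(np.full((2, 2, 1), 0.00))
        b = B0Map(np.full((2, 2, 1), 0.10))
        series = d.interpolate_b0_series(a, b, [0.0, 50.0, 100.0])
        assert series.shifts[0, 0, 0, 1] == pytest.approx(0.05)

    def test_volunteer_protocol_yields_64_maps(self):
        a = B0Map(np.zeros((2, 2, 1)))
        b = B0Map(np.zeros((2, 2, 1)))
        low, high = d.split_interleaved(make_series(128))
        ptimes = (low.times_s + high.times_s) / 2.0
        series = d.interpolate_b0_series(a, b, ptimes)
        assert len(series) == 64

    def test_reversed_endpoint_times_rejected(self):
        m = B0Map(np.zeros((2, 2, 1)))
        with pytest.raises(ValueError, match="exceed"):
            d.interpolate_b0_series(m, m, [5.0], t_baseline_s=10.0,
                                    t_post_s=10.0)


class TestDynamicB0Correct:
    def test_zero_shift_identity(self):
        z12 = np.array([[0.5]])
        z20 = np.array([[0.7]])
        c12, c20 = d.dynamic_b0_correct_pair(z12, z20, np.array([[0.0]]))
        assert c12[0, 0] == 0.5 and c20[0, 0] == 0.7

    def test_exact_for_affine_spectrum(self):
        """A spectrum linear in offset is restored exactly for any shift."""
        slope, icpt = 0.21, 0.33
        delta = 0.17

        def f(x):
            return icpt + slope * x

        z12 = np.array([f(1.2 - delta)])
        z20 = np.array([f(2.0 - delta)])
        c12, c20 = d.dynamic_b0_correct_pair(z12, z20, np.array([delta]))
        assert c12[0] == pytest.approx(f(1.2), abs=1e-12)
        assert c20[0] == pytest.approx(f(2.0), abs=1e-12)

    def test_halves_error_on_lorentzian_voxel(self, wm_pools):
        """For a forward-simulated voxel with a 0.05-ppm shift the
        corrected values are at least twice closer to the unshifted truth
        at both offsets."""
        delta = 0.05
        offs = np.array([1.2, 2.0])
        truth = d.zspectrum_forward(wm_pools, offs)
        meas = d.zspectrum_forward(wm_pools, offs, b0_shift_ppm=delta)
        c12, c20 = d.dynamic_b0_correct_pair(np.array([meas[0]]),
                                             np.array([meas[1]]),
                                             np.array([delta]))
        for corr, raw, tru in ((c12[0], meas[0], truth[0]),
                               (c20[0], meas[1], truth[1])):
            assert abs(corr - tru) <= 0.5 * abs(raw - tru)

    def test_series_level_pairing(self):
        low, high = d.split_interleaved(make_series(8))
        b0 = d.B0Series(np.zeros((2, 2, 1, 4)), (low.times_s
                                                 + high.times_s) / 2)
        clow, chigh = d.dynamic_b0_correct(low, high, b0)
        np.testing.assert_array_equal(clow.frames, low.frames)
        np.testing.assert_array_equal(chigh.frames, high.frames)


class TestPCADenoise:
    def test_rank_one_series_exact_with_one_component(self):
        rng = np.random.default_rng(0)
        amp = rng.random((5, 4, 1, 1))
        course = np.sin(np.linspace(0, 3, 16))
        series = d.DynamicSeries(amp * course, np.full(16, 2.0),
                                 np.arange(16.0), normalized=True)
        out, cumvar = d.pca_denoise(series, n_components=1)
        np.testing.assert_allclose(out.frames, series.frames, atol=1e-10)
        assert cumvar[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction_is_identity(self):
        rng = np.random.default_rng(1)
        series = d.DynamicSeries(rng.random((3, 3, 1, 8)), np.full(8, 2.0),
                                 np.arange(8.0), normalized=True)
        out, _ = d.pca_denoise(series, n_components=8)
        np.testing.assert_allclose(out.frames, series.frames, atol=1e-10)

    def test_reduces_rmse_on_three_source_series(self):
        """Three temporal sources + Gaussian noise: the 3-component
        reconstruction is strictly closer to the noiseless truth."""
        rng = np.random.default_rng(2)
        t = np.linspace(0.0, 1.0, 64)
        sources = np.stack([np.ones_like(t), t, np.sin(2 * np.pi * t)])
        weights = rng.random((200, 3))
        clean = (weights @ sources).reshape(20, 10, 1, 64)
        noisy = clean + rng.normal(0.0, 0.002, clean.shape)
        series = d.DynamicSeries(noisy, np.full(64, 2.0), np.arange(64.0),
                                 normalized=True)
        out, _ = d.pca_denoise(series, n_components=3)
        rmse_before = np.sqrt(((noisy - clean) ** 2).mean())
        rmse_after = np.sqrt(((out.frames - clean) ** 2).mean())
        assert rmse_after < rmse_before

    def test_component_count_validated(self):
        series = make_series(4)
        with pytest.raises(ValueError, match="n_components"):
            d.pca_denoise(series, n_components=0)
        with pytest.raises(ValueError, match="n_components"):
            d.pca_denoise(series, n_components=5)


class TestComputeDGE:
    def test_constant_series_gives_zero(self):
        low, _ = d.split_interleaved(make_series(8, values=0.6))
        res = d.compute_dge(low, infusion_start_s=15.0)
        assert np.all(res.dge_t == 0.0)

    def test_direct_arithmetic(self):
        vals = np.array([0.60, 0.60, 0.58, 0.58])
        series = d.DynamicSeries(np.broadcast_to(vals, (1, 1, 1, 4)).copy(),
                                 np.full(4, 2.0),
                                 100.0 * np.arange(1, 5.0),
                                 normalized=True)
        res = d.compute_dge(series, infusion_start_s=250.0)
        np.testing.assert_allclose(res.dge_t[0, 0, 0],
                                   [0.0, 0.0, 0.02, 0.02], atol=1e-12)
        assert res.block_means[2][0, 0, 0] == pytest.approx(0.02)

    def test_sinus_block3_matches_truth_noiseless(self):
        """On a noiseless drift-free phantom the sinus block-3 DGE equals
        the simulated Z reduction averaged over the block's frame times."""
        truth = d.default_phantom(shape=(16, 16, 4), b0_amplitude_ppm=0.0)
        kin = truth.kinetics
        series, _ = d.simulate_dynamic_scan(truth, n_timepoints=128)
        series = d.normalize_dynamic(series)
        low, high = d.split_interleaved(series)
        res = d.compute_dge(high, kin.infusion_start_s)
        rel = high.times_s - kin.infusion_start_s
        sel = (rel >= 200.0) & (rel < 400.0)
        expected = truth.true_dge(SS, 2.0, high.times_s[sel]).mean()
        got = res.block_means[3][truth.mask(SS)].mean()
        assert got == pytest.approx(expected, abs=1e-4)

    def test_scaling_invariance(self):
        """Multiplying raw frames and S0 by one constant leaves DGE(t)
        unchanged."""
        truth = d.default_phantom(shape=(8, 8, 2))
        series, refs = d.simulate_dynamic_scan(truth, n_timepoints=16)
        scaled = d.DynamicSeries(series.frames * 3.7, series.offsets_ppm,
                                 series.times_s, s0=series.s0 * 3.7)
        r1 = d.compute_dge(d.split_interleaved(
            d.normalize_dynamic(series))[1], truth.kinetics.infusion_start_s)
        r2 = d.compute_dge(d.split_interleaved(
            d.normalize_dynamic(scaled))[1], truth.kinetics.infusion_start_s)
        m = truth.mask()
        np.testing.assert_allclose(r1.dge_t[m], r2.dge_t[m], atol=1e-12)

    def test_block_partition_counts(self):
        series = make_series(128)
        low, _ = d.split_interleaved(series)
        res = d.compute_dge(low, infusion_start_s=180.0)
        counts = res.block_counts
        rel = low.times_s - 180.0
        assert counts[1] == int((rel < 0).sum())
        assert sum(counts.values()) + int((rel >= 600.0).sum()) == \
            low.n_frames
        for b, lo, hi in ((2, 0.0, 200.0), (3, 200.0, 400.0),
                          (4, 400.0, 600.0)):
            assert counts[b] == int(((rel >= lo) & (rel < hi)).sum())

    def test_empty_baseline_rejected(self):
        series = make_series(8)
        low, _ = d.split_interleaved(series)
        with pytest.raises(ValueError, match="baseline"):
            d.compute_dge(low, infusion_start_s=-10.0)
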