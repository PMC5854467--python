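import numpy as np
import pytest

from spcryo.ctf import CTFParams
from spcryo.image import (Image, RadialProfile, Volume, fft3c,
                          freq_magnitude, n_shells, radial_average,
                          radius_grid)
from spcryo.refine3d import AlignmentParams
from spcryo.reconstruct3d import (FSCCurve, ReconstructionAccumulator,
                                  SharpenConfig, blurred_insert,
                                  compute_fsc, finalize, insert_particle,
                                  mask_particle_ratio, part_fsc,
                                  part_fsc_model, particle_volume_from_mass,
                                  pssnr_from_fsc, reconstruct,
                                  resolution_at_threshold, score_weights,
                                  sharpen_map, split_dataset,
                                  whiten_background)


def high_pssnr(box=48, px=3.0, value=1e4):
    dg = 1.0 / (box * px)
    return RadialProfile(np.arange(n_shells(box)) * dg,
                         np.full(n_shells(box), value))


class TestWhitenBackground:
    def test_white_noise_scaled_to_unit_variance(self):
        rng = np.random.default_rng(0)
        img = Image(rng.normal(scale=2.0, size=(48, 48)), 3.0)
        out = whiten_background(img, mask_radius=40.0)
        assert abs(out.pixels.var() - 1.0) < 0.02

    def test_colored_noise_flattened(self):
        rng = np.random.default_rng(1)
        import scipy.fft as fft
        from spcryo.image import freq_magnitude as fm
        g = fm(48, 3.0, 2)
        color = 1.0 / (1.0 + (g / 0.05) ** 2)
        acc = None
        # average whitened spectra over many noise draws
        for _ in range(50):
            noise = fft.ifft2(fft.fft2(rng.normal(size=(48, 48)))
                              * color).real
            out = whiten_background(Image(noise, 3.0), mask_radius=40.0)
            p = radial_average(np.abs(fft.fft2(out.pixels)) ** 2, 3.0).values
            acc = p if acc is None else acc + p
        prof = acc / 50
        inner = prof[2:-2]
        assert np.all(np.abs(inner / inner.mean() - 1.0) < 0.2)

    def test_mask_covering_box_rejected(self):
        img = Image(np.zeros((48, 48)), 3.0)
        with pytest.raises(ValueError, match="background"):
            whiten_background(img, mask_radius=200.0)


class TestInsertion:
    def test_zero_occupancy_is_noop(self, phantom, ctf300):
        acc = ReconstructionAccumulator(48, 3.0)
        img = Image(phantom.analytic_projection(48, 3.0, 0, 0, 0), 3.0)
        insert_particle(acc, img, AlignmentParams(), ctf300, q_ik=0.0)
        assert acc.insert_count == 0
        assert np.all(acc.numerator == 0) and np.all(acc.denominator == 0)

    def test_doubling_sigma_quarters_contribution(self, phantom, ctf300):
        img = Image(phantom.analytic_projection(48, 3.0, 10, 20, 30), 3.0)
        a1 = ReconstructionAccumulator(48, 3.0)
        a2 = ReconstructionAccumulator(48, 3.0)
        insert_particle(a1, img, AlignmentParams(), ctf300, sigma_i=1.0)
        insert_particle(a2, img, AlignmentParams(), ctf300, sigma_i=2.0)
        assert np.allclose(a1.numerator, 4.0 * a2.numerator)
        assert np.allclose(a1.denominator, 4.0 * a2.denominator)

    def test_single_particle_adjoint_roundtrip(self, phantom, cc):
        """Insert one noiseless particle at identity with CTF ~= 1 and a
        huge PSSNR: the central section of the finalized map must match
        the particle."""
        from spcryo.ctf import ctf_grid
        from spcryo.image import fft2c, ifft2c
        unity_ctf = CTFParams(0.0, 0.0, cs=0.0, amplitude_contrast=0.9999,
                              pixel_size=3.0)
        proj = phantom.analytic_projection(48, 3.0, 0, 0, 0)
        # feed the CTF-affected particle, as a real pipeline would
        img = Image(ifft2c(fft2c(proj)
                           * ctf_grid(unity_ctf, 48, 3.0)).real, 3.0)
        acc = ReconstructionAccumulator(48, 3.0)
        insert_particle(acc, img, AlignmentParams(), unity_ctf)
        vol = finalize(acc, high_pssnr())
        section = vol.voxels.sum(axis=0)
        assert cc(section, proj) > 0.99

    def test_nonfinite_rejected(self, ctf300):
        acc = ReconstructionAccumulator(48, 3.0)
        bad = np.zeros((48, 48))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            insert_particle(acc, Image(bad, 3.0), AlignmentParams(), ctf300)

    def test_merge_equals_concatenation(self, phantom, ctf300):
        imgs = [Image(phantom.analytic_projection(48, 3.0, a, 2 * a, 0),
                      3.0) for a in (10.0, 40.0, 70.0, 100.0)]
        both = ReconstructionAccumulator(48, 3.0)
        for im in imgs:
            insert_particle(both, im, AlignmentParams(), ctf300)
        pa = ReconstructionAccumulator(48, 3.0)
        pb = ReconstructionAccumulator(48, 3.0)
        for im in imgs[:2]:
            insert_particle(pa, im, AlignmentParams(), ctf300)
        for im in imgs[2:]:
            insert_particle(pb, im, AlignmentParams(), ctf300)
        pa.merge(pb)
        assert np.allclose(pa.numerator, both.numerator, rtol=1e-12,
                           atol=1e-12)
        assert np.allclose(pa.denominator, both.denominator, rtol=1e-12,
                           atol=1e-12)
        assert pa.insert_count == both.insert_count

    def test_zero_pssnr_gives_zero_map(self, phantom, ctf300):
        acc = ReconstructionAccumulator(48, 3.0)
        img = Image(phantom.analytic_projection(48, 3.0, 0, 0, 0), 3.0)
        insert_particle(acc, img, AlignmentParams(), ctf300)
        zero = RadialProfile(high_pssnr().bin_centers,
                             np.zeros(n_shells(48)))
        vol = finalize(acc, zero)
        assert np.allclose(vol.voxels, 0.0)

    def test_empty_accumulator_rejected(self):
        with pytest.raises(ValueError):
            finalize(ReconstructionAccumulator(48, 3.0), high_pssnr())


class TestScoreWeights:
    def test_bsc_zero_disables_weighting(self):
        g = np.linspace(0, 0.2, 20)
        assert np.allclose(score_weights(87.0, 50.0, 0.0, g), 1.0)

    def test_mean_score_gives_unit_weight(self):
        g = np.linspace(0, 0.2, 20)
        assert np.allclose(score_weights(60.0, 60.0, 10.0, g), 1.0)

    def test_score_span_maps_to_100_A2_bfactor_difference(self):
        """A 10-point score difference at BSC = 10 Å² separates particles
        by an effective B factor of 100 Å²."""
        g = np.linspace(0.01, 0.3, 50)
        ratio = score_weights(60.0, 55.0, 10.0, g) / \
            score_weights(50.0, 55.0, 10.0, g)
        assert np.allclose(ratio, np.exp(-100.0 / 4.0 * g ** 2))


class TestFSC:
    def test_identical_maps_give_unity(self, phantom_volume):
        fsc = compute_fsc(phantom_volume, phantom_volume)
        assert np.allclose(fsc.raw, 1.0, atol=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        a = Volume(rng.normal(size=(48,) * 3), 3.0)
        b = Volume(rng.normal(size=(48,) * 3), 3.0)
        fsc = compute_fsc(a, b)
        # each shell holds >= ~100 samples; |FSC| ~ 1/sqrt(n_shell)
        assert np.all(np.abs(fsc.raw[2:]) < 0.5)
        assert np.abs(fsc.raw[2:]).mean() < 0.1

    def test_constructed_snr_matches_prediction(self, phantom_volume):
        rng = np.random.default_rng(1)
        sig = phantom_volume.voxels
        F = fft3c(sig)
        power = radial_average(np.abs(F) ** 2, 3.0)
        halves = []
        noise_scale = 0.5
        for seed in (1, 2):
            r = np.random.default_rng(seed)
            noise = r.normal(scale=noise_scale * sig.std(),
                             size=sig.shape) * np.sqrt(sig.size) * 0
            halves.append(Volume(sig + r.normal(
                scale=noise_scale * sig.std(), size=sig.shape), 3.0))
        fsc = compute_fsc(*halves)
        # per-shell prediction: FSC = SNR/(SNR+1)
        noise_power = (noise_scale * sig.std()) ** 2 * sig.size
        snr = power.values / (noise_power / n_shells(48) /
                              np.maximum(1, 1))
        # compute noise power per shell from a direct noise transform
        nr = np.random.default_rng(9)
        npow = radial_average(np.abs(fft3c(nr.normal(
            scale=noise_scale * sig.std(), size=sig.shape))) ** 2, 3.0)
        snr = power.values / npow.values
        pred = snr / (snr + 1.0)
        sel = slice(1, 20)
        assert np.allclose(fsc.raw[sel], pred[sel], atol=0.05)

    def test_box_mismatch_rejected(self, phantom_volume):
        with pytest.raises(ValueError):
            compute_fsc(phantom_volume, Volume(np.zeros((32,) * 3), 3.0))

    def test_split_modes(self):
        a, b = split_dataset(10, "even_odd")
        assert np.array_equal(a, [0, 2, 4, 6, 8])
        a, b = split_dataset(1000, "hundred_subsets")
        # 100 equal subsets, even-numbered vs odd-numbered
        assert len(a) == len(b) == 500
        assert np.array_equal(a[:10], np.arange(10))   # subset 0 is even
        with pytest.raises(ValueError):
            split_dataset(10, "thirds")


class TestSolventCorrection:
    def test_f_equal_one_is_identity(self):
        fsc = FSCCurve(np.linspace(0.01, 0.15, 10),
                       np.linspace(0.9, 0.1, 10))
        out = part_fsc(fsc, 1.0)
        assert np.allclose(out.fsc, fsc.fsc)

    def test_unity_fsc_fixed_for_any_f(self):
        fsc = FSCCurve(np.array([0.01, 0.02]), np.array([1.0, 1.0]))
        for f in (1.0, 2.0, 5.0):
            assert np.allclose(part_fsc(fsc, f).fsc, 1.0)

    def test_half_at_f_two_gives_two_thirds(self):
        fsc = FSCCurve(np.array([0.05]), np.array([0.5]))
        assert np.isclose(part_fsc(fsc, 2.0).fsc[0], 2.0 / 3.0)

    def test_model_map_variant_squares_fsc(self):
        fsc = FSCCurve(np.array([0.05]), np.array([0.5]))
        out = part_fsc_model(fsc, 2.0)
        assert np.isclose(out.fsc[0], 2 * 0.25 / (1 + 0.25))

    def test_particle_volume_rule(self):
        assert np.isclose(particle_volume_from_mass(810.0), 1000.0)
        assert np.isclose(particle_volume_from_mass(2.0e5),
                          2 * particle_volume_from_mass(1.0e5))

    def test_f_ratio_composition(self):
        r, mw = 50.0, 3.0e5
        f = mask_particle_ratio(r, mw)
        assert np.isclose(f, (4 / 3 * np.pi * r ** 3) / (mw / 0.81))


class TestResolution:
    def test_unity_curve_returns_nyquist(self):
        dg = 1.0 / (48 * 3.0)
        fsc = FSCCurve(np.arange(25) * dg, np.ones(25))
        assert np.isclose(resolution_at_threshold(fsc, 0.143), 6.0)

    def test_step_curve_crossing(self):
        dg = 0.01
        vals = np.ones(30)
        vals[20:] = 0.0
        fsc = FSCCurve(np.arange(30) * dg, vals)
        res = resolution_at_threshold(fsc, 0.143)
        g_cross = 0.19 + 0.01 * (1.0 - 0.143)
        assert np.isclose(res, 1.0 / g_cross)

    def test_05_crossing_before_0143_crossing(self):
        dg = 0.01
        vals = np.linspace(1.0, -0.2, 30)
        fsc = FSCCurve(np.arange(30) * dg, vals)
        r05 = resolution_at_threshold(fsc, 0.5)
        r0143 = resolution_at_threshold(fsc, 0.143)
        assert 1.0 / r05 <= 1.0 / r0143


class TestPssnrFromFsc:
    def test_zero_fsc_zero_pssnr(self):
        fsc = FSCCurve(np.array([0.01]), np.array([0.0]))
        assert pssnr_from_fsc(fsc).values[0] == 0.0

    def test_one_third_fsc_gives_full_data_ssnr_one(self):
        # half-map FSC 1/3 -> half-set SSNR 0.5 -> full-set SSNR 1
        fsc = FSCCurve(np.array([0.01]), np.array([1.0 / 3.0]))
        assert np.isclose(pssnr_from_fsc(fsc).values[0], 1.0)

    def test_unity_fsc_hits_ceiling_and_monotone(self):
        fsc = FSCCurve(np.linspace(0.01, 0.1, 5),
                       np.array([1.0, 0.8, 0.5, 0.3, 0.0]))
        p = pssnr_from_fsc(fsc, ceiling=100.0)
        assert p.values[0] == 100.0
        assert np.all(np.diff(p.values) <= 0)


class TestBlurredReconstruction:
    def test_delta_likelihood_equals_standard(self, phantom, ctf300):
        img = Image(phantom.analytic_projection(48, 3.0, 10, 20, 30), 3.0)
        p = AlignmentParams(10, 20, 30)
        a = ReconstructionAccumulator(48, 3.0)
        insert_particle(a, img, p, ctf300)
        b = ReconstructionAccumulator(48, 3.0)
        blurred_insert(b, img, p, ctf300, [(0.0, 0.0, 0.0, 1.0)])
        assert np.allclose(a.numerator, b.numerator)
        assert a.insert_count == b.insert_count == 1

    def test_uniform_two_shift_blur_averages_maps(self, phantom, ctf300):
        img = Image(phantom.analytic_projection(48, 3.0, 10, 20, 30), 3.0)
        p = AlignmentParams(10, 20, 30)
        single = []
        for dx in (-3.0, 3.0):
            acc = ReconstructionAccumulator(48, 3.0)
            insert_particle(acc, img,
                            AlignmentParams(10, 20, 30, shift_x=dx),
                            ctf300)
            single.append(acc)
        blurred = ReconstructionAccumulator(48, 3.0)
        blurred_insert(blurred, img, p, ctf300,
                       [(0.0, -3.0, 0.0, 1.0), (0.0, 3.0, 0.0, 1.0)])
        avg_num = 0.5 * (single[0].numerator + single[1].numerator)
        assert np.allclose(blurred.numerator, avg_num, atol=1e-10)

    def test_blurring_never_boosts_shell_power(self, phantom, ctf300):
        img = Image(phantom.analytic_projection(48, 3.0, 10, 20, 30), 3.0)
        p = AlignmentParams(10, 20, 30)
        sharp = ReconstructionAccumulator(48, 3.0)
        insert_particle(sharp, img, p, ctf300)
        blur = ReconstructionAccumulator(48, 3.0)
        grid = [(0.0, dx, dy, 1.0) for dx in (-3, 0, 3) for dy in (-3, 0, 3)]
        blurred_insert(blur, img, p, ctf300, grid)
        vs = finalize(sharp, high_pssnr())
        vb = finalize(blur, high_pssnr())
        ps = radial_average(np.abs(fft3c(vs.voxels)) ** 2, 3.0).values
        pb = radial_average(np.abs(fft3c(vb.voxels)) ** 2, 3.0).values
        assert np.all(pb[1:20] <= ps[1:20] * 1.05)

    def test_degenerate_likelihood_rejected(self, phantom, ctf300):
        img = Image(phantom.analytic_projection(48, 3.0, 0, 0, 0), 3.0)
        acc = ReconstructionAccumulator(48, 3.0)
        with pytest.raises(ValueError, match="degenerate"):
            blurred_insert(acc, img, AlignmentParams(), ctf300,
                           [(0.0, 0.0, 0.0, 0.0)])


class TestSharpen:
    def test_no_op_configuration_is_identity(self, phantom_volume):
        cfg = SharpenConfig(bfactor=0.0, whiten_beyond=None)
        out = sharpen_map(phantom_volume, cfg)
        assert np.allclose(out.voxels, phantom_volume.voxels, atol=1e-9)

    def test_whitening_flattens_power_beyond_cutoff(self, phantom_volume):
        cfg = SharpenConfig(whiten_beyond=12.0)
        out = sharpen_map(phantom_volume, cfg)
        prof = radial_average(np.abs(fft3c(out.voxels)) ** 2, 3.0)
        beyond = prof.bin_centers > 1.0 / 12.0
        vals = prof.values[beyond][:-1]
        assert np.all(np.abs(vals / vals.mean() - 1.0) < 0.05)

    def test_negative_bfactor_closed_form_amplification(self, phantom_volume):
        base = sharpen_map(phantom_volume,
                           SharpenConfig(whiten_beyond=None, bfactor=0.0))
        sharp = sharpen_map(phantom_volume,
                            SharpenConfig(whiten_beyond=None,
                                          bfactor=-100.0))
        Fb = np.abs(fft3c(base.voxels))
        Fs = np.abs(fft3c(sharp.voxels))
        g = freq_magnitude(48, 3.0, 3)
        sel = (Fb > 1e-6) & (g > 0.05) & (g < 0.15)
        ratio = Fs[sel] / Fb[sel]
        assert np.allclose(ratio, np.exp(25.0 * g[sel] ** 2), rtol=1e-6)

    def test_cutoff_beyond_nyquist_rejected(self, phantom_volume):
        with pytest.raises(ValueError, match="Nyquist"):
            sharpen_map(phantom_volume,
                        SharpenConfig(resolution_cutoff=4.0))

    def test_fom_filter_requires_fsc(self, phantom_volume):
        with pytest.raises(ValueError, match="FOM"):
            sharpen_map(phantom_volume, SharpenConfig(fom_filter=True))


class TestFullRecovery:
    def test_true_angle_reconstruction_reaches_two_thirds_nyquist(
            self, phantom, phantom_volume):
        """500 particles at SNR 0.05 with known angles must reconstruct
        the phantom with FSC > 0.5 out to 2/3 of Nyquist."""
        from spcryo import params as pt
        from spcryo.synthetic import simulate_particles
        stack, truth = simulate_particles(phantom, 500, snr=0.05, seed=3)
        rec = reconstruct(stack, pt.from_truth(truth), 3.0,
                          mask_radius=phantom.diameter() / 2)
        fsc = compute_fsc(rec, phantom_volume)
        res = resolution_at_threshold(fsc, 0.5)
        nyquist = 6.0
        assert res <= 1.5 * nyquist
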