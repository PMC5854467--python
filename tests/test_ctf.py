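import numpy as np
import pytest

from spcryo.ctf import (CTFParams, amplitude_spectrum, check_aliasing,
                        ctf_grid, ctf_zero_crossings, evaluate_ctf,
                        exhaustive_ctf_2d, fit_ctf, fit_ctf_1d,
                        goodness_of_fit, refine_ctf_2d, subtract_background)
from spcryo.image import Image, freq_magnitude, radial_average


def simulated_spectrum(params: CTFParams, box: int = 256,
                       envelope_b: float = 0.0, background: float = 2.0,
                       noise_sd: float = 0.0, seed: int = 0) -> Image:
    """Forward-simulated Thon-ring amplitude spectrum."""
    rng = np.random.default_rng(seed)
    g = freq_magnitude(box, params.pixel_size, 2)
    rings = ctf_grid(params, box) ** 2 * np.exp(-envelope_b * g ** 2 / 4)
    bg = background * np.exp(-(g / 0.12) ** 2) + 0.5
    spec = rings + bg
    if noise_sd:
        spec = spec + rng.normal(scale=noise_sd, size=spec.shape)
    return Image(spec, params.pixel_size)


class TestEvaluateCtf:
    def test_no_astigmatism_is_azimuth_independent(self):
        p = CTFParams(15000, 15000, pixel_size=1.0)
        g = np.linspace(0.01, 0.4, 50)
        a = evaluate_ctf(p, g, 0.0)
        b = evaluate_ctf(p, g, 1.1)
        assert np.allclose(a, b)

    def test_bounded_by_one(self):
        p = CTFParams(22000, 18000, astig_angle=30.0, phase_shift=0.5,
                      pixel_size=1.0)
        vals = ctf_grid(p, 256)
        assert np.all(vals ** 2 <= 1.0 + 1e-12)

    def test_zero_count_matches_phase_function_oracle(self):
        p = CTFParams(15000, 15000, pixel_size=1.0)
        g_max = 0.25
        zeros = ctf_zero_crossings(p, g_max)
        # oracle: count how many multiples of pi the aberration phase
        # crosses on a dense grid
        from spcryo.ctf import _phase_aberration
        g = np.linspace(0, g_max, 400000)
        chi = _phase_aberration(p, g, 0.0)
        crossings = np.sum(np.diff(np.floor(chi / np.pi)) != 0)
        assert abs(len(zeros) - crossings) <= 1

    def test_defocus_convention_enforced(self):
        p = CTFParams(10000, 20000, astig_angle=10.0)
        assert p.defocus1 >= p.defocus2
        assert p.defocus1 == 20000


class TestAmplitudeSpectrum:
    def test_white_noise_gives_flat_spectrum(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(1024, 1024))
        spec = amplitude_spectrum(img, pixel_size=2.0, spectrum_box=64)
        prof = radial_average(spec.pixels ** 2, spec.pixel_size)
        inner = prof.values[2:-2]
        assert np.all(np.abs(inner / inner.mean() - 1.0) < 0.05)

    def test_fine_pixels_resampled_to_quarter_angstrom_edge(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(512, 512))
        spec = amplitude_spectrum(img, pixel_size=1.0, spectrum_box=256)
        # the spectrum edge must sit at 1/2.8 1/A, i.e. 1.4 A/pixel
        assert abs(spec.pixel_size - 1.4) < 0.02

    def test_movie_subsums_sharpen_thon_rings(self):
        """With drift, Thon rings blur in the full-exposure sum but are
        retained in short sub-sums; the ring modulation depth must be
        visibly higher for sub-sums."""
        rng = np.random.default_rng(2)
        p = CTFParams(18000, 18000, pixel_size=2.0)
        box = 128
        n_frames = 8
        from spcryo.image import fft2c, ifft2c, shift_image_fourier
        frames = []
        drift = np.cumsum(rng.normal(4.0, 1.0, size=(n_frames, 2)), axis=0)
        base = rng.normal(size=(box, box))
        filt = ifft2c(fft2c(base) * ctf_grid(p, box)).real
        for i in range(n_frames):
            F = shift_image_fourier(fft2c(filt), drift[i, 0], drift[i, 1],
                                    2.0)
            frames.append(ifft2c(F).real
                          + rng.normal(scale=0.3, size=(box, box)))
        frames = np.array(frames)
        model = radial_average(ctf_grid(p, box) ** 2, 2.0).values

        def ring_depth(spec):
            prof = radial_average(subtract_background(spec).pixels,
                                  spec.pixel_size).values
            a, b = prof[15:55], model[15:55]
            a, b = a - a.mean(), b - b.mean()
            return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

        sub = amplitude_spectrum(frames, 2.0, frames_to_sum=2,
                                 spectrum_box=box)
        full = amplitude_spectrum(frames.sum(axis=0), 2.0,
                                  spectrum_box=box)
        assert ring_depth(sub) > ring_depth(full) + 0.03


class TestBackgroundSubtraction:
    def test_constant_spectrum_zeroed(self):
        spec = Image(np.full((128, 128), 5.0), 2.0)
        out = subtract_background(spec)
        assert np.allclose(out.pixels, 0.0, atol=1e-6)

    def test_ring_free_spectrum_mostly_removed(self):
        rng = np.random.default_rng(3)
        g = freq_magnitude(128, 2.0, 2)
        smooth = 4.0 * np.exp(-(g / 0.1) ** 2) + 1.0
        spec = Image(smooth + rng.normal(scale=0.05, size=(128, 128)), 2.0)
        out = subtract_background(spec)
        assert out.pixels.std() < 0.1 * spec.pixels.std()

    def test_ring_positions_unchanged(self):
        p = CTFParams(15000, 15000, pixel_size=2.0)
        spec = simulated_spectrum(p, box=256)
        out = subtract_background(spec)
        prof_in = radial_average(ctf_grid(p, 256) ** 2, 2.0)
        prof_out = radial_average(out.pixels, 2.0)
        # peaks of the background-subtracted profile line up with CTF^2
        # maxima to within one shell
        from scipy.signal import find_peaks
        pk_in, _ = find_peaks(prof_in.values[5:80])
        pk_out, _ = find_peaks(prof_out.values[5:80])
        matched = sum(1 for a in pk_in[:6]
                      if np.min(np.abs(pk_out - a)) <= 1)
        assert matched >= 5


class TestFit1D:
    def test_defocus_recovered_within_grid_step(self):
        p = CTFParams(15000, 15000, pixel_size=2.0)
        spec = subtract_background(simulated_spectrum(p, noise_sd=0.05))
        prof = radial_average(spec.pixels, 2.0)
        df, ps = fit_ctf_1d(prof, p, defocus_range=(5000, 30000),
                            defocus_step=250.0)
        assert abs(df - 15000) <= 250.0

    def test_matching_candidate_wins(self):
        p = CTFParams(12000, 12000, pixel_size=2.0)
        spec = subtract_background(simulated_spectrum(p))
        prof = radial_average(spec.pixels, 2.0)
        df, _ = fit_ctf_1d(prof, p, defocus_range=(12000, 20000),
                           defocus_step=8000.0)
        assert df == 12000

    def test_phase_plate_shift_recovered(self):
        p = CTFParams(12000, 12000, phase_shift=np.pi / 2, pixel_size=2.0)
        spec = subtract_background(simulated_spectrum(p))
        prof = radial_average(spec.pixels, 2.0)
        df, ps = fit_ctf_1d(prof, CTFParams(1, 1, pixel_size=2.0),
                            defocus_range=(8000, 16000), defocus_step=500.0,
                            phase_shift_range=(0.0, np.pi),
                            phase_shift_step=np.pi / 18)
        assert abs(ps - np.pi / 2) <= np.pi / 18 + 1e-9

    def test_degenerate_profile_rejected(self):
        from spcryo.image import RadialProfile
        prof = RadialProfile(np.linspace(0, 0.25, 64), np.zeros(64))
        with pytest.raises(ValueError, match="degenerate"):
            fit_ctf_1d(prof, CTFParams(1, 1, pixel_size=2.0))


class TestRefine2D:
    def test_astigmatic_parameters_recovered(self):
        truth = CTFParams(16000, 14000, astig_angle=30.0, pixel_size=2.0)
        spec = subtract_background(simulated_spectrum(truth, noise_sd=0.02,
                                                      seed=5))
        init = CTFParams(15200, 15200, astig_angle=0.0, pixel_size=2.0)
        fit, _ = refine_ctf_2d(spec, init)
        assert abs(fit.defocus1 - 16000) < 100
        assert abs(fit.defocus2 - 14000) < 100
        assert min(abs(fit.astig_angle % 180 - 30),
                   180 - abs(fit.astig_angle % 180 - 30)) < 3.0

    def test_zero_astigmatism_converges_from_astigmatic_init(self):
        truth = CTFParams(15000, 15000, pixel_size=2.0)
        spec = subtract_background(simulated_spectrum(truth, seed=6))
        init = CTFParams(15600, 14400, astig_angle=45.0, pixel_size=2.0)
        fit, _ = refine_ctf_2d(spec, init)
        assert abs(fit.defocus1 - fit.defocus2) < 100

    def test_objective_never_degrades(self):
        truth = CTFParams(15000, 15000, pixel_size=2.0)
        spec = subtract_background(simulated_spectrum(truth, seed=7))
        init = CTFParams(15000, 15000, pixel_size=2.0)   # already optimal
        from spcryo.ctf import _spectrum_objective, sine_radial_mask
        from spcryo.image import freq_magnitude as fm
        g = fm(spec.box, spec.pixel_size, 2)
        band = (g >= 1 / 30.0) & (g <= 1 / (2 * spec.pixel_size))
        mask = sine_radial_mask(spec.box, spec.pixel_size)
        before = _spectrum_objective(spec, init, mask, band)
        fit, _ = refine_ctf_2d(spec, init)
        after = _spectrum_objective(spec, fit, mask, band)
        assert after >= before - 1e-12


class TestPipelineEquivalence:
    def test_1d_then_2d_matches_exhaustive_2d(self):
        """On astigmatism-free simulations, the fast 1-D pre-search plus
        2-D refinement must land on the same optimum as a direct
        exhaustive 2-D search."""
        truth = CTFParams(17500, 17500, pixel_size=2.0)
        spec = simulated_spectrum(truth, noise_sd=0.05, seed=8)
        template = CTFParams(1, 1, pixel_size=2.0)
        fit_fast, _ = fit_ctf(spec, template,
                              defocus_range=(8000, 28000),
                              defocus_step=500.0)
        from spcryo.ctf import subtract_background as subbg
        fit_slow = exhaustive_ctf_2d(subbg(spec), template,
                                     defocus_range=(8000, 28000),
                                     defocus_step=500.0)
        mean_fast = (fit_fast.defocus1 + fit_fast.defocus2) / 2
        assert abs(mean_fast - fit_slow.defocus1) <= 500.0


class TestDiagnostics:
    def test_perfect_rings_correlate_through_nyquist(self):
        p = CTFParams(15000, 15000, pixel_size=2.0)
        spec = subtract_background(simulated_spectrum(p))
        diag = goodness_of_fit(spec, p)
        inner = diag.ccfit.values[10:-5]
        assert np.median(inner) > 0.9

    def test_damped_rings_limit_fit_resolution(self):
        p = CTFParams(15000, 15000, pixel_size=2.0)
        # strong envelope kills rings beyond ~5 A
        spec = subtract_background(simulated_spectrum(p, envelope_b=900.0,
                                                      noise_sd=0.15,
                                                      seed=9))
        diag = goodness_of_fit(spec, p)
        assert 3.5 < diag.fit_resolution < 8.0

    def test_pure_noise_has_poor_fit_resolution(self):
        rng = np.random.default_rng(10)
        spec = Image(rng.normal(size=(256, 256)) ** 2, 2.0)
        p = CTFParams(15000, 15000, pixel_size=2.0)
        diag = goodness_of_fit(subtract_background(spec), p)
        assert diag.fit_resolution > 10.0

    def test_window_too_small_rejected(self):
        p = CTFParams(15000, 15000, pixel_size=2.0)
        spec = simulated_spectrum(p)
        with pytest.raises(ValueError):
            goodness_of_fit(spec, p, window=2)


class TestAliasing:
    def test_small_box_high_defocus_aliases(self):
        p = CTFParams(30000, 30000, pixel_size=1.0)
        assert check_aliasing(128, p) is True

    def test_large_box_low_defocus_clean(self):
        p = CTFParams(5000, 5000, pixel_size=1.0)
        assert check_aliasing(1024, p) is False

    def test_zero_defocus_never_aliases(self):
        p = CTFParams(0, 0, pixel_size=1.0)
        assert check_aliasing(128, p) is False
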