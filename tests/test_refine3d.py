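import numpy as np
import pytest

from spcryo.ctf import CTFParams
from spcryo.fourier3d import FourierProjector
from spcryo.image import (Image, RadialProfile, Volume, fft2c, n_shells,
                          radial_average, rotation_matrix)
from spcryo.refine3d import (AlignmentParams, MatchedFilterContext,
                             RestraintModel, SearchConfig, global_search,
                             global_search_stack, local_refine,
                             mask_reference_3d, objective_cc, refine_defocus,
                             scale_reference, score_from_objective,
                             shift_restraint, snr_map, whiten_image_matched)


def flat_pssnr(box=48, px=3.0, value=10.0):
    dg = 1.0 / (box * px)
    return RadialProfile(np.arange(n_shells(box)) * dg,
                         np.full(n_shells(box), value))


def measured_pssnr(phantom, truth, n=30, seed=5):
    """Generator-side SSNR: clean projection power over noise power."""
    from spcryo.synthetic import simulate_particles
    clean, _ = simulate_particles(
        phantom, len(truth), snr=np.inf,
        eulers=truth[["phi", "theta", "psi"]].to_numpy(),
        apply_ctf=False, seed=seed)
    sig = np.mean([radial_average(np.abs(fft2c(c)) ** 2, 3.0).values
                   for c in clean], axis=0)
    noise = np.mean(truth["sigma_noise"] ** 2) * 48 * 48
    dg = 1.0 / (48 * 3.0)
    return RadialProfile(np.arange(n_shells(48)) * dg, sig / max(noise, 1e-12))


def angular_error(truth_row, p):
    Rt = rotation_matrix(truth_row["phi"], truth_row["theta"],
                         truth_row["psi"])
    Rf = rotation_matrix(p.phi, p.theta, p.psi)
    c = (np.trace(Rt.T @ Rf) - 1) / 2
    return np.rad2deg(np.arccos(np.clip(c, -1, 1)))


class TestSnrAndScaling:
    def test_snr_zero_at_ctf_zeros_and_dead_shells(self, ctf300):
        from spcryo.ctf import ctf_grid
        pssnr = flat_pssnr(value=1.0)
        m = snr_map(pssnr, ctf300, 48, 3.0)
        ctf2d = ctf_grid(ctf300, 48, 3.0)
        near_zero = np.abs(ctf2d) < 0.01
        assert near_zero.any()
        assert np.all(m[near_zero] < 1e-4)
        # a dead PSSNR shell gives a dead SNR shell
        dead = flat_pssnr(value=1.0)
        dead.values[5] = 0.0
        m2 = snr_map(dead, ctf300, 48, 3.0)
        from spcryo.image import shell_indices
        idx = shell_indices(48, 3.0, 2)
        assert np.all(m2[idx == 5] == 0.0)

    def test_flat_unit_pssnr_gives_ctf_squared(self, ctf300):
        from spcryo.ctf import ctf_grid
        m = snr_map(flat_pssnr(value=1.0), ctf300, 48, 3.0)
        assert np.allclose(m, ctf_grid(ctf300, 48, 3.0) ** 2, atol=1e-10)

    def test_reference_scaled_to_zero_at_zero_snr(self, phantom):
        F = fft2c(phantom.analytic_projection(48, 3.0, 0, 0, 0))
        out = scale_reference(F, np.zeros((48, 48)), 3.0)
        assert np.allclose(out, 0.0)

    def test_whitened_noise_has_flat_unit_power(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(48, 48))
        F = fft2c(img)
        out = whiten_image_matched(F, np.zeros((48, 48)), 3.0)
        prof = radial_average(np.abs(out) ** 2, 3.0)
        inner = prof.values[2:-2]
        assert np.all(np.abs(inner - 1.0) < 0.35)
        assert abs(np.mean(inner) - 1.0) < 0.05


class TestObjective:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.F = fft2c(rng.normal(size=(48, 48)))
        self.config = SearchConfig(R1=300.0, R3=8.0)

    def test_self_match_is_one(self):
        assert np.isclose(objective_cc(self.F, self.F, 3.0, self.config),
                          1.0)

    def test_disjoint_support_is_zero(self):
        from spcryo.image import freq_magnitude
        g = freq_magnitude(48, 3.0, 2)
        lo = np.where((g > 1 / 50) & (g < 1 / 25), self.F, 0)
        hi = np.where((g > 1 / 15) & (g < 1 / 9), self.F, 0)
        assert abs(objective_cc(lo + 0j, hi + 0j, 3.0, self.config)) < 1e-10

    def test_unsigned_band_never_decreases_objective(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            A = fft2c(rng.normal(size=(48, 48)))
            B = fft2c(rng.normal(size=(48, 48)))
            signed = objective_cc(A, B, 3.0,
                                  SearchConfig(R1=300.0, R3=8.0))
            split = objective_cc(A, B, 3.0,
                                 SearchConfig(R1=300.0, R2=15.0, R3=8.0))
            assert split >= signed - 1e-12

    def test_unsigned_band_empty_reduces_to_signed(self):
        rng = np.random.default_rng(3)
        A = fft2c(rng.normal(size=(48, 48)))
        B = fft2c(rng.normal(size=(48, 48)))
        a = objective_cc(A, B, 3.0, SearchConfig(R1=300.0, R3=8.0))
        b = objective_cc(A, B, 3.0,
                         SearchConfig(R1=300.0, R2=8.0, R3=8.0))
        assert a == b

    def test_invalid_band_order_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(R1=8.0, R3=300.0)


class TestRestraint:
    def test_zero_at_mean(self):
        r = RestraintModel((1.0, -2.0), (5.0, 5.0), noise_sd=1.5,
                           mask_pixels=100)
        p = AlignmentParams(shift_x=1.0, shift_y=-2.0)
        assert shift_restraint(p, r) == 0.0

    def test_quadratic_growth(self):
        r = RestraintModel((0.0, 0.0), (5.0, 5.0), noise_sd=1.0,
                           mask_pixels=10)
        p1 = shift_restraint(AlignmentParams(shift_x=2.0), r)
        p2 = shift_restraint(AlignmentParams(shift_x=4.0), r)
        assert np.isclose(p2, 4.0 * p1)
        assert p1 < 0

    def test_perfect_unshifted_match_scores_100(self, phantom, ctf300):
        from spcryo.ctf import ctf_grid
        from spcryo.image import ifft2c
        proj = FourierProjector(phantom.volume(), pad=2)
        F = proj.project_ft(30.0, 60.0, 90.0) * ctf_grid(ctf300, 48, 3.0)
        img = Image(ifft2c(F).real, 3.0)
        ctx = MatchedFilterContext(img, proj, ctf300,
                                   flat_pssnr(value=1e6),
                                   SearchConfig(R1=300.0, R3=8.0),
                                   RestraintModel())
        score = ctx.score(AlignmentParams(30.0, 60.0, 90.0))
        assert abs(score - 100.0) < 0.5


class TestGlobalSearch:
    def test_noiseless_grid_orientation_recovered_exactly(self, phantom,
                                                          ctf300):
        from spcryo.ctf import ctf_grid
        from spcryo.image import ifft2c
        proj = FourierProjector(phantom.volume(), pad=2)
        # orientation on the 15-degree search grid
        F = proj.project_ft(0.0, 15.0, 30.0) * ctf_grid(ctf300, 48, 3.0)
        img = Image(ifft2c(F).real, 3.0)
        cfg = SearchConfig(R1=300.0, R3=8.0, angular_step=15.0,
                           shift_search_radius=6.0)
        p, score = global_search(img, proj, ctf300, flat_pssnr(), cfg,
                                 do_local_refine=False)
        assert (abs(p.theta - 15.0) < 1e-6 and
                abs((p.psi - 30.0) % 360) < 1e-6)
        assert abs(p.shift_x) < 1e-9 and abs(p.shift_y) < 1e-9

    def test_median_error_under_5_degrees_at_snr_01(self, phantom):
        from spcryo.synthetic import simulate_particles
        stack, truth = simulate_particles(phantom, 24, snr=0.1,
                                          shift_sigma=3.0, seed=5)
        ctfs = [CTFParams(d, d, pixel_size=3.0) for d in truth["defocus"]]
        pssnr = measured_pssnr(phantom, truth)
        proj = FourierProjector(phantom.volume(), pad=2)
        cfg = SearchConfig(R1=300.0, R3=8.0, angular_step=15.0,
                           shift_search_radius=10.0)
        params, _ = global_search_stack(stack, 3.0, proj, ctfs, pssnr, cfg)
        errs = [angular_error(truth.iloc[i], p)
                for i, p in enumerate(params)]
        assert np.median(errs) < 5.0

    def test_deterministic(self, phantom, ctf300):
        from spcryo.ctf import ctf_grid
        from spcryo.image import ifft2c
        proj = FourierProjector(phantom.volume(), pad=2)
        F = proj.project_ft(10.0, 40.0, 70.0) * ctf_grid(ctf300, 48, 3.0)
        img = Image(ifft2c(F).real, 3.0)
        cfg = SearchConfig(R1=300.0, R3=8.0, angular_step=20.0)
        a, sa = global_search(img, proj, ctf300, flat_pssnr(), cfg,
                              do_local_refine=False)
        b, sb = global_search(img, proj, ctf300, flat_pssnr(), cfg,
                              do_local_refine=False)
        assert (a.phi, a.theta, a.psi, sa) == (b.phi, b.theta, b.psi, sb)


class TestLocalRefine:
    def test_objective_never_degrades_and_error_shrinks(self, phantom,
                                                        ctf300):
        from spcryo.ctf import ctf_grid
        from spcryo.image import ifft2c
        proj = FourierProjector(phantom.volume(), pad=2)
        truth_angles = (40.0, 70.0, 110.0)
        F = proj.project_ft(*truth_angles) * ctf_grid(ctf300, 48, 3.0)
        img = Image(ifft2c(F).real, 3.0)
        cfg = SearchConfig(R1=300.0, R3=8.0, angular_step=15.0)
        init = AlignmentParams(43.0, 70.0, 110.0)   # 3 degrees off in phi
        ctx = MatchedFilterContext(img, proj, ctf300, flat_pssnr(), cfg)
        before = ctx.objective(init)
        p, after = local_refine(img, proj, ctf300, flat_pssnr(), init, cfg)
        assert after >= before
        err0 = abs(init.phi - truth_angles[0])
        err1 = angular_error({"phi": truth_angles[0],
                              "theta": truth_angles[1],
                              "psi": truth_angles[2]}, p)
        assert err1 <= err0 / 10.0

    def test_init_at_truth_stays(self, phantom, ctf300):
        from spcryo.ctf import ctf_grid
        from spcryo.image import ifft2c
        proj = FourierProjector(phantom.volume(), pad=2)
        F = proj.project_ft(40.0, 70.0, 110.0) * ctf_grid(ctf300, 48, 3.0)
        img = Image(ifft2c(F).real, 3.0)
        cfg = SearchConfig(R1=300.0, R3=8.0, angular_step=15.0)
        init = AlignmentParams(40.0, 70.0, 110.0)
        p, _ = local_refine(img, proj, ctf300, flat_pssnr(), init, cfg)
        assert angular_error({"phi": 40.0, "theta": 70.0, "psi": 110.0},
                             p) < 1.0


class TestDefocusRefine:
    def test_grid_has_21_points_by_default(self):
        cfg = SearchConfig()
        n = len(np.arange(-cfg.defocus_search_range,
                          cfg.defocus_search_range
                          + cfg.defocus_search_step / 2,
                          cfg.defocus_search_step))
        assert n == 21

    def test_known_offset_recovered(self, phantom):
        from spcryo.synthetic import simulate_particles
        eulers = np.array([[50.0, 60.0, 70.0]])
        true_df = 15200.0
        stack, truth = simulate_particles(phantom, 1, snr=10.0,
                                          eulers=eulers,
                                          defocus_range=(true_df, true_df),
                                          seed=8)
        header_ctf = CTFParams(15000.0, 15000.0, pixel_size=3.0)
        proj = FourierProjector(phantom.volume(), pad=2)
        cfg = SearchConfig(R1=300.0, R3=7.0, angular_step=15.0)
        off = refine_defocus(Image(stack[0], 3.0), proj, header_ctf,
                             measured_pssnr(phantom, truth, n=1, seed=8),
                             AlignmentParams(*eulers[0]), cfg)
        assert abs(off - 200.0) <= 50.0

    def test_nominal_defocus_gives_zero_offset(self, phantom, ctf300):
        proj = FourierProjector(phantom.volume(), pad=2)
        from spcryo.image import ifft2c
        from spcryo.ctf import ctf_grid
        F = proj.project_ft(20.0, 30.0, 40.0) * ctf_grid(ctf300, 48, 3.0)
        img = Image(ifft2c(F).real, 3.0)
        cfg = SearchConfig(R1=300.0, R3=7.0)
        off = refine_defocus(img, proj, ctf300, flat_pssnr(),
                             AlignmentParams(20.0, 30.0, 40.0), cfg)
        assert off == 0.0


class TestMaskReference:
    def test_all_positive_mask_is_identity(self, phantom_volume):
        mask = Volume(np.ones((48,) * 3), 3.0)
        out = mask_reference_3d(phantom_volume, mask)
        assert np.allclose(out.voxels, phantom_volume.voxels)

    def test_outside_power_never_grows(self, phantom_volume):
        vox = phantom_volume.voxels
        mask = np.zeros_like(vox)
        mask[10:38, 10:38, 10:38] = 1.0
        out = mask_reference_3d(phantom_volume, Volume(mask, 3.0),
                                falloff_width=6.0)
        outside = mask == 0
        assert (out.voxels[outside] ** 2).sum() <= \
            (vox[outside] ** 2).sum() + 1e-9

    def test_lowpass_retention_outside(self, phantom_volume, cc):
        from spcryo.image import lowpass_filter
        vox = phantom_volume.voxels
        mask = np.zeros_like(vox)
        mask[14:34, 14:34, 14:34] = 1.0
        out = mask_reference_3d(phantom_volume, Volume(mask, 3.0),
                                falloff_width=6.0, outside_lp=30.0,
                                outside_weight=1.0)
        lp = lowpass_filter(vox, 3.0, 30.0)
        far_outside = np.ones_like(vox, dtype=bool)
        far_outside[8:40, 8:40, 8:40] = False
        assert np.allclose(out.voxels[far_outside], lp[far_outside],
                           atol=1e-6)

    def test_empty_mask_rejected(self, phantom_volume):
        with pytest.raises(ValueError, match="empty"):
            mask_reference_3d(phantom_volume,
                              Volume(-np.ones((48,) * 3), 3.0))
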