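"""Projection-matching refinement with a matched-filter objective.

The objective correlates a noise-whitened particle with an SNR-scaled,
CTF-modulated reference projection, optionally taking absolute values of
the cross terms in a high-resolution band to curb noise overfitting, plus
a quadratic restraint on the x,y shifts.  Scores are the objective times
100, so a perfect unshifted self-match scores 100.

A global search evaluates an Euler grid with a translational
cross-correlation search per orientation, locally refines the best h
candidates with a derivative-free simplex and returns the best refined
result.  Per-particle defocus is refined by a 1-D grid search of an offset
applied to both defocus values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as _fft
from scipy import optimize

from .ctf import CTFParams, ctf_grid
from .fourier3d import FourierProjector
from .image import (Image, RadialProfile, Volume, cosine_edge, fft2c, fft3c,
                    freq_magnitude, ifft3c, lowpass_filter, n_shells,
                    radial_average, radius_grid, rotate_image,
                    shell_indices, shift_image_fourier)


@dataclass
class AlignmentParams:
    """Per-particle view, position and optical corrections."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0
    magnification: float = 1.0
    defocus_offset: float = 0.0

    def eulers(self):
        return self.phi, self.theta, self.psi


@dataclass
class RestraintModel:
    """Gaussian restraint on particle x,y positions (Å)."""

    mean_shift: tuple = (0.0, 0.0)
    sd_shift: tuple = (10.0, 10.0)
    noise_sd: float = 1.0
    mask_pixels: int = 1

    def __post_init__(self) -> None:
        if self.sd_shift[0] <= 0 or self.sd_shift[1] <= 0:
            raise ValueError("shift standard deviations must be positive")


@dataclass
class SearchConfig:
    """Resolution band, candidate count and search granularity."""

    R1: float = 300.0          # low-resolution limit, Å
    R3: float = 8.0            # high-resolution limit, Å
    R2: float = None           # signed-CC limit; None -> R3 (all signed)
    top_h: int = 20
    angular_step: float = 15.0          # degrees
    shift_search_radius: float = 10.0   # Å
    defocus_search_range: float = 500.0  # ±Å
    defocus_search_step: float = 50.0

    def __post_init__(self) -> None:
        if self.R2 is None:
            self.R2 = self.R3
        if not (self.R1 >= self.R2 >= self.R3):
            raise ValueError("need R1 >= R2 >= R3 (in Å)")
        if self.top_h < 1:
            raise ValueError("top_h must be >= 1")


# --------------------------------------------------------------------------
# matched-filter scaling
# --------------------------------------------------------------------------

def snr_map(pssnr: RadialProfile, ctf: CTFParams, box: int,
            pixel_size: float) -> np.ndarray:
    """Per-element SSNR on the 2-D grid: PSSNR(g) x CTF²(g, azimuth).

    PSSNR is constant within each Fourier shell (nearest-shell lookup), so
    a dead shell in the profile yields a dead shell in the map.
    """
    idx = np.minimum(shell_indices(box, pixel_size, 2),
                     len(pssnr.values) - 1)
    vals = np.maximum(pssnr.values[idx], 0.0)
    return vals * ctf_grid(ctf, box, pixel_size) ** 2


def _radial_amplitude(F: np.ndarray, pixel_size: float) -> np.ndarray:
    """sqrt of the radially averaged squared amplitudes, expanded to 2-D."""
    box = F.shape[0]
    prof = radial_average(np.abs(F) ** 2, pixel_size)
    idx = shell_indices(box, pixel_size, 2)
    idx = np.minimum(idx, len(prof.values) - 1)
    return np.sqrt(np.maximum(prof.values[idx], 0.0))


def whiten_image_matched(F_img: np.ndarray, snr: np.ndarray,
                         pixel_size: float) -> np.ndarray:
    """Divide by the image's radial amplitude spectrum, then amplify by
    sqrt(1 + SNR).  Zero-amplitude shells are set to zero."""
    amp = _radial_amplitude(F_img, pixel_size)
    out = np.zeros_like(F_img)
    nz = amp > 0
    out[nz] = F_img[nz] / amp[nz]
    return out * np.sqrt(1.0 + snr)


def scale_reference(F_ref: np.ndarray, snr: np.ndarray,
                    pixel_size: float) -> np.ndarray:
    """Scale reference variance per shell proportional to the SNR."""
    amp = _radial_amplitude(F_ref, pixel_size)
    out = np.zeros_like(F_ref)
    nz = amp > 0
    out[nz] = F_ref[nz] / amp[nz]
    return out * np.sqrt(snr)


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------

def _band_masks(box: int, pixel_size: float, config: SearchConfig):
    g = freq_magnitude(box, pixel_size, 2)
    full = (g >= 1.0 / config.R1) & (g <= 1.0 / config.R3)
    signed = full & (g <= 1.0 / config.R2)
    unsigned = full & (g > 1.0 / config.R2)
    return full, signed, unsigned


def objective_cc(F_whitened: np.ndarray, F_scaled_ref: np.ndarray,
                 pixel_size: float, config: SearchConfig) -> float:
    """Normalized cross-correlation with optional unsigned high band."""
    full, signed, unsigned = _band_masks(F_whitened.shape[0], pixel_size,
                                         config)
    cross = np.conj(F_scaled_ref) * F_whitened
    num = float(np.real(cross[signed].sum()))
    if unsigned.any():
        num += abs(float(np.real(cross[unsigned].sum())))
    na = np.sqrt(float((np.abs(F_scaled_ref[full]) ** 2).sum()))
    nb = np.sqrt(float((np.abs(F_whitened[full]) ** 2).sum()))
    if na == 0 or nb == 0:
        raise ValueError("zero-norm input in objective")
    return num / (na * nb)


def shift_restraint(params: AlignmentParams,
                    restraint: RestraintModel) -> float:
    """Quadratic log-prior penalty on the x,y shifts (<= 0)."""
    if restraint is None:
        return 0.0
    dx = params.shift_x - restraint.mean_shift[0]
    dy = params.shift_y - restraint.mean_shift[1]
    s2 = restraint.noise_sd ** 2
    return -s2 / (2.0 * restraint.mask_pixels) * (
        dx ** 2 / restraint.sd_shift[0] ** 2
        + dy ** 2 / restraint.sd_shift[1] ** 2)


def score_from_objective(obj: float) -> float:
    return 100.0 * obj


# --------------------------------------------------------------------------
# single-particle evaluation helpers
# --------------------------------------------------------------------------

class MatchedFilterContext:
    """Caches the whitened particle and reference scaling for one particle."""

    def __init__(self, particle: Image, projector: FourierProjector,
                 ctf: CTFParams, pssnr: RadialProfile, config: SearchConfig,
                 restraint: RestraintModel = None):
        self.projector = projector
        self.pixel_size = particle.pixel_size
        self.box = particle.box
        self.config = config
        self.restraint = restraint
        self.ctf_params = ctf
        self.pssnr = pssnr
        self._set_ctf(ctf)
        F = fft2c(particle.pixels)
        self.F_white = whiten_image_matched(F, self.snr, self.pixel_size)

    def _set_ctf(self, ctf: CTFParams) -> None:
        self.ctf2d = ctf_grid(ctf, self.box, self.pixel_size)
        self.snr = snr_map(self.pssnr, ctf, self.box, self.pixel_size)

    def scaled_projection(self, phi, theta, psi) -> np.ndarray:
        F_proj = self.projector.project_ft(phi, theta, psi) * self.ctf2d
        return scale_reference(F_proj, self.snr, self.pixel_size)

    def objective(self, params: AlignmentParams) -> float:
        ref = self.scaled_projection(*params.eulers())
        ref = shift_image_fourier(ref, params.shift_x, params.shift_y,
                                  self.pixel_size)
        cc = objective_cc(self.F_white, ref, self.pixel_size, self.config)
        return cc + shift_restraint(params, self.restraint)

    def score(self, params: AlignmentParams) -> float:
        return score_from_objective(self.objective(params))


def euler_grid(angular_step: float, psi_step: float = None) -> np.ndarray:
    """Quasi-uniform (phi, theta, psi) grid with the given step (degrees)."""
    if psi_step is None:
        psi_step = angular_step
    out = []
    n_theta = max(1, int(round(180.0 / angular_step))) + 1
    for it in range(n_theta):
        theta = it * 180.0 / (n_theta - 1) if n_theta > 1 else 0.0
        st = np.sin(np.deg2rad(theta))
        if st < 1e-6:
            phis = [0.0]
        else:
            n_phi = max(1, int(round(360.0 * st / angular_step)))
            phis = np.arange(n_phi) * 360.0 / n_phi
        for phi in phis:
            for psi in np.arange(0.0, 360.0, psi_step):
                out.append((phi, theta, psi))
    return np.array(out)


def _shift_window_mask(box: int, pixel_size: float, radius: float):
    r = np.zeros((box, box))
    ax = np.arange(box)
    ax = np.where(ax <= box // 2, ax, ax - box)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    return (np.hypot(yy, xx) * pixel_size) <= radius


def global_search(particle: Image, projector: FourierProjector,
                  ctf: CTFParams, pssnr: RadialProfile, config: SearchConfig,
                  restraint: RestraintModel = None,
                  do_local_refine: bool = True):
    """Exhaustive Euler-grid search with per-orientation shift search.

    The top ``config.top_h`` grid results are locally refined and the best
    refined candidate is returned as ``(AlignmentParams, score)``.  Ties
    break to the lowest grid index, so results are deterministic.
    """
    ctx = MatchedFilterContext(particle, projector, ctf, pssnr, config,
                               restraint)
    grid = euler_grid(config.angular_step)
    box, px = particle.box, particle.pixel_size
    window = _shift_window_mask(box, px, config.shift_search_radius)
    full, signed, unsigned = _band_masks(box, px, config)
    nb = np.sqrt(float((np.abs(ctx.F_white[full]) ** 2).sum()))
    candidates = []
    for gi, (phi, theta, psi) in enumerate(grid):
        ref = ctx.scaled_projection(phi, theta, psi)
        na = np.sqrt(float((np.abs(ref[full]) ** 2).sum()))
        if na == 0:
            continue
        cross = np.conj(ref) * ctx.F_white
        cc_s = _fft.ifft2(np.where(signed, cross, 0)).real * box * box
        if unsigned.any():
            cc_u = _fft.ifft2(np.where(unsigned, cross, 0)).real * box * box
            cc_map = cc_s + np.abs(cc_u)
        else:
            cc_map = cc_s
        cc_map = np.where(window, cc_map, -np.inf)
        iy, ix = np.unravel_index(np.argmax(cc_map), cc_map.shape)
        sy = iy if iy <= box // 2 else iy - box
        sx = ix if ix <= box // 2 else ix - box
        p = AlignmentParams(phi, theta, psi, sx * px, sy * px)
        obj = cc_map[iy, ix] / (na * nb) + shift_restraint(p, ctx.restraint)
        candidates.append((obj, gi, p))
    if not candidates:
        raise ValueError("empty search grid")
    candidates.sort(key=lambda c: (-c[0], c[1]))
    top = candidates[:config.top_h]
    best_params, best_obj = top[0][2], top[0][0]
    if do_local_refine:
        for _, _, cand in top:
            ref_params, ref_obj = local_refine(particle, projector, ctf,
                                               pssnr, cand, config,
                                               restraint, _ctx=ctx)
            if ref_obj > best_obj:
                best_obj, best_params = ref_obj, ref_params
    return best_params, score_from_objective(best_obj)


def local_refine(particle: Image, projector: FourierProjector,
                 ctf: CTFParams, pssnr: RadialProfile,
                 init: AlignmentParams, config: SearchConfig,
                 restraint: RestraintModel = None, max_evals: int = 400,
                 _ctx: MatchedFilterContext = None):
    """Simplex maximization of the objective over Euler angles and shifts.

    Returns ``(AlignmentParams, objective)``; never worse than ``init``.
    """
    ctx = _ctx or MatchedFilterContext(particle, projector, ctf, pssnr,
                                       config, restraint)

    def unpack(x):
        return AlignmentParams(x[0], x[1], x[2], x[3], x[4],
                               init.magnification, init.defocus_offset)

    def cost(x):
        return -ctx.objective(unpack(x))

    x0 = np.array([init.phi, init.theta, init.psi,
                   init.shift_x, init.shift_y])
    init_obj = ctx.objective(init)
    step = max(config.angular_step / 4.0, 1.0)
    simplex = [x0]
    deltas = [step, step, step, particle.pixel_size, particle.pixel_size]
    for i, d in enumerate(deltas):
        v = x0.copy()
        v[i] += d
        simplex.append(v)
    res = optimize.minimize(cost, x0, method="Nelder-Mead",
                            options={"maxfev": max_evals,
                                     "initial_simplex": np.array(simplex),
                                     "xatol": 0.01, "fatol": 1e-8})
    if -res.fun > init_obj:
        return unpack(res.x), float(-res.fun)
    return init, float(init_obj)


def direction_grid(angular_step: float) -> np.ndarray:
    """Quasi-uniform (phi, theta) projection directions (psi = 0)."""
    out = []
    n_theta = max(1, int(round(180.0 / angular_step))) + 1
    for it in range(n_theta):
        theta = it * 180.0 / (n_theta - 1) if n_theta > 1 else 0.0
        st = np.sin(np.deg2rad(theta))
        if st < 1e-6:
            phis = [0.0]
        else:
            n_phi = max(1, int(round(360.0 * st / angular_step)))
            phis = np.arange(n_phi) * 360.0 / n_phi
        for phi in phis:
            out.append((phi, theta))
    return np.array(out)


def _rot2(a_deg: float) -> np.ndarray:
    t = np.deg2rad(a_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def global_search_stack(stack: np.ndarray, pixel_size: float,
                        projector: FourierProjector, ctfs,
                        pssnr: RadialProfile, config: SearchConfig,
                        rng: np.random.Generator = None,
                        randomized_top_fraction: float = None,
                        refine_best: bool = True):
    """Vectorized Euler-grid search over a whole particle stack.

    Reference projections are computed once per direction (psi = 0); the
    in-plane angle is searched by rotating each particle, so the per-
    particle cost is a batch of Fourier products.  With
    ``randomized_top_fraction`` set (e.g. 0.15), the returned orientation
    for each particle is drawn uniformly from all grid results whose score
    lies within that fraction of the best-to-worst score range — the
    stochastic candidate selection used during ab-initio runs; otherwise
    the best candidate is (optionally) locally refined.

    Returns ``(params_list, scores)``.
    """
    n, box = stack.shape[0], stack.shape[1]
    px = pixel_size
    dirs = direction_grid(config.angular_step)
    n_psi = max(1, int(round(360.0 / config.angular_step)))
    psis = np.arange(n_psi) * 360.0 / n_psi
    proj_fts = np.stack([projector.project_ft(phi, theta, 0.0)
                         for phi, theta in dirs])
    full, signed, unsigned = _band_masks(box, px, config)
    window = _shift_window_mask(box, px, config.shift_search_radius)
    nsh = n_shells(box)
    idx = np.minimum(shell_indices(box, px, 2), nsh - 1).ravel()
    onehot = np.zeros((box * box, nsh))
    onehot[np.arange(box * box), idx] = 1.0
    shell_counts = onehot.sum(axis=0)
    out_params, out_scores = [], np.empty(n)
    for i in range(n):
        ctf2d = ctf_grid(ctfs[i], box, px)
        snr = snr_map(pssnr, ctfs[i], box, px)
        refs = proj_fts * ctf2d[None]
        # radial scaling of all references at once
        pwr = (np.abs(refs.reshape(len(dirs), -1)) ** 2) @ onehot
        amp = np.sqrt(pwr / np.maximum(shell_counts[None], 1.0))
        amp2d = amp[:, idx].reshape(len(dirs), box, box)
        with np.errstate(invalid="ignore", divide="ignore"):
            refs = np.where(amp2d > 0, refs / np.maximum(amp2d, 1e-30), 0.0)
        refs = refs * np.sqrt(snr)[None]
        ref_norms = np.sqrt((np.abs(refs) ** 2 * full[None]).sum(axis=(1, 2)))
        best = (-np.inf, 0, 0, 0, 0)      # obj, dir, psi, sx, sy
        cand_scores = []
        cand_info = []
        for pi, psi in enumerate(psis):
            img = rotate_image(stack[i], -psi) if psi else stack[i]
            F = fft2c(img)
            Fw = whiten_image_matched(F, snr, px)
            nb = np.sqrt(float((np.abs(Fw[full]) ** 2).sum()))
            if nb == 0:
                continue
            cross = np.conj(refs) * Fw[None]
            cc = _fft.ifft2(np.where(signed[None], cross, 0),
                            axes=(-2, -1)).real * box * box
            if unsigned.any():
                cc_u = _fft.ifft2(np.where(unsigned[None], cross, 0),
                                  axes=(-2, -1)).real * box * box
                cc = cc + np.abs(cc_u)
            cc = np.where(window[None], cc, -np.inf)
            flat = cc.reshape(len(dirs), -1).argmax(axis=1)
            vals = cc.reshape(len(dirs), -1)[np.arange(len(dirs)), flat]
            objs = np.where(ref_norms > 0, vals / (ref_norms * nb), -np.inf)
            cand_scores.append(objs)
            cand_info.append((pi, flat))
            j = int(objs.argmax())
            if objs[j] > best[0]:
                iy, ix = divmod(int(flat[j]), box)
                best = (float(objs[j]), j, pi,
                        ix if ix <= box // 2 else ix - box,
                        iy if iy <= box // 2 else iy - box)

        def params_from(dir_j, psi_i, sx_pix, sy_pix):
            psi = psis[psi_i]
            # the particle was rotated by -psi before matching psi=0
            # references, so the found shift lives in the rotated frame
            s = _rot2(psi) @ np.array([sx_pix * px, sy_pix * px])
            phi, theta = dirs[dir_j]
            return AlignmentParams(phi, theta, psi, s[0], s[1])

        if randomized_top_fraction is not None:
            allsc = np.concatenate(cand_scores)
            lo, hi = allsc.min(), allsc.max()
            cutoff = hi - randomized_top_fraction * (hi - lo)
            eligible = np.nonzero(allsc >= cutoff)[0]
            pick = int((rng or np.random.default_rng()).choice(eligible))
            blk = pick // len(dirs)
            dir_j = pick % len(dirs)
            pi, flat = cand_info[blk]
            iy, ix = divmod(int(flat[dir_j]), box)
            p = params_from(dir_j, pi,
                            ix if ix <= box // 2 else ix - box,
                            iy if iy <= box // 2 else iy - box)
            out_params.append(p)
            out_scores[i] = score_from_objective(float(allsc[pick]))
        else:
            p = params_from(best[1], best[2], best[3], best[4])
            obj = best[0]
            if refine_best:
                p, obj = local_refine(Image(stack[i], px), projector,
                                      ctfs[i], pssnr, p, config)
            out_params.append(p)
            out_scores[i] = score_from_objective(obj)
    return out_params, out_scores


def _polar_coords(box: int, n_radius: int, n_angle: int):
    half = box // 2
    radii = np.arange(1, n_radius + 1, dtype=float)
    thetas = np.arange(n_angle) * 2.0 * np.pi / n_angle
    rr, tt = np.meshgrid(radii, thetas, indexing="ij")
    # image axes are (y, x); angle measured from +x toward +y
    ys = half + rr * np.sin(tt)
    xs = half + rr * np.cos(tt)
    return np.stack([ys.ravel(), xs.ravel()]), radii


def _to_polar(img: np.ndarray, coords, radii, n_angle: int) -> np.ndarray:
    from scipy import ndimage
    vals = ndimage.map_coordinates(img, coords, order=1, mode="constant",
                                   cval=0.0)
    out = vals.reshape(len(radii), n_angle)
    # weight rows by sqrt(r) so products integrate with the r dr measure
    return out * np.sqrt(radii)[:, None]


def rotational_search_stack(stack: np.ndarray, pixel_size: float,
                            projector: FourierProjector, ctfs,
                            pssnr: RadialProfile, config: SearchConfig,
                            rng: np.random.Generator = None,
                            randomized_top_fraction: float = None,
                            n_defocus_groups: int = 8,
                            refine_shift: bool = True):
    """Fast orientation search via polar cross-correlation.

    Matched-filter-weighted particles and reference projections are
    resampled onto a polar grid; a 1-D FFT over the angular coordinate
    evaluates the zero-shift correlation against every in-plane rotation
    of every projection direction at once.  Defocus values are binned
    into groups sharing reference scaling.  Translations are recovered
    afterwards by a single windowed cross-correlation for the selected
    candidate — appropriate when residual shifts are at most a few
    pixels, as they are for boxed particles.

    Supports the same top-fraction randomized candidate selection as
    :func:`global_search_stack`.  Returns ``(params_list, scores)``.
    """
    import scipy.fft as fft
    n, box = stack.shape[0], stack.shape[1]
    px = pixel_size
    dirs = direction_grid(config.angular_step)
    n_dirs = len(dirs)
    n_radius = box // 2 - 1
    # azimuthal sampling ~1.2 pixel arc at the outermost radius
    n_angle = int(2 ** np.ceil(np.log2(max(64, 1.7 * n_radius))))
    coords, radii = _polar_coords(box, n_radius, n_angle)
    full, _, _ = _band_masks(box, px, config)
    proj_fts = np.stack([projector.project_ft(phi, theta, 0.0)
                         for phi, theta in dirs])
    defoci = np.array([0.5 * (c.defocus1 + c.defocus2) for c in ctfs])
    n_groups = min(n_defocus_groups, n)
    edges = np.quantile(defoci, np.linspace(0, 1, n_groups + 1))
    group_of = np.clip(np.searchsorted(edges, defoci, side="right") - 1,
                       0, n_groups - 1)
    nsh = n_shells(box)
    sh_idx = np.minimum(shell_indices(box, px, 2), nsh - 1).ravel()
    onehot = np.zeros((box * box, nsh))
    onehot[np.arange(box * box), sh_idx] = 1.0
    shell_counts = np.maximum(onehot.sum(axis=0), 1.0)
    # polar coordinates for a whole direction stack in one call
    d_axis = np.repeat(np.arange(n_dirs, dtype=float), coords.shape[1])
    coords3 = np.stack([d_axis, np.tile(coords[0], n_dirs),
                        np.tile(coords[1], n_dirs)])
    sqrt_r = np.sqrt(radii)[:, None]
    group_data = {}
    for gidx in np.unique(group_of):
        members = np.nonzero(group_of == gidx)[0]
        rep = ctfs[members[len(members) // 2]]
        ctf2d = ctf_grid(rep, box, px)
        snr = snr_map(pssnr, rep, box, px)
        refsF = proj_fts * ctf2d[None]
        pwr = (np.abs(refsF.reshape(n_dirs, -1)) ** 2) @ onehot
        amp = np.sqrt(pwr / shell_counts[None])
        amp2d = amp[:, sh_idx].reshape(n_dirs, box, box)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(amp2d > 0,
                              refsF / np.maximum(amp2d, 1e-30), 0.0)
        scaled = scaled * np.sqrt(snr)[None] * full[None]
        r_imgs = _fft.fftshift(_fft.ifft2(scaled, axes=(-2, -1)),
                               axes=(-2, -1)).real
        from scipy import ndimage
        vals = ndimage.map_coordinates(r_imgs, coords3, order=1,
                                       mode="constant", cval=0.0)
        pol = (vals.reshape(n_dirs, n_radius, n_angle)
               * sqrt_r[None]).astype(np.float32)
        polF = fft.fft(pol, axis=-1).astype(np.complex64)
        norms = np.sqrt((pol.astype(np.float64) ** 2).sum(axis=(1, 2)))
        group_data[gidx] = (ctf2d, snr, polF, norms)
    window = _shift_window_mask(box, px, config.shift_search_radius)
    out_params = []
    out_scores = np.empty(n)
    rng = rng or np.random.default_rng()
    n_passes = 2 if refine_shift else 1
    for i in range(n):
        ctf2d, snr, polF, ref_norms = group_data[group_of[i]]
        F0 = fft2c(stack[i])
        Fw0 = whiten_image_matched(F0, snr, px) * full
        sx = sy = 0.0
        obj = -np.inf
        phi = theta = psi = 0.0
        # the polar match assumes a centred particle; alternate match
        # and recentring so residual shifts stop biasing the rotation
        for _pass in range(n_passes):
            Fw = shift_image_fourier(Fw0, -sx, -sy, px)
            img_r = _fft.fftshift(_fft.ifft2(Fw)).real
            pimg = _to_polar(img_r, coords, radii, n_angle)
            pimgF = fft.fft(pimg, axis=-1).astype(np.complex64)
            # c(dir, l) = sum_r sum_th ref(r, th + l) * img(r, th)
            cc = fft.ifft((polF * np.conj(pimgF[None])).sum(axis=1),
                          axis=-1).real
            inorm = np.sqrt((pimg ** 2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                objs = np.where(ref_norms[:, None] > 0,
                                cc / (np.maximum(ref_norms[:, None], 1e-30)
                                      * max(inorm, 1e-30)), -np.inf)
            flat_objs = objs.ravel()
            if randomized_top_fraction is not None and _pass == n_passes - 1:
                hi, lo = flat_objs.max(), flat_objs.min()
                cutoff = hi - randomized_top_fraction * (hi - lo)
                eligible = np.nonzero(flat_objs >= cutoff)[0]
                pick = int(rng.choice(eligible))
            else:
                pick = int(flat_objs.argmax())
            d_j, l = divmod(pick, n_angle)
            psi = l * 360.0 / n_angle
            phi, theta = dirs[d_j]
            obj = float(flat_objs[pick])
            if refine_shift:
                ref = scale_reference(proj_fts[d_j] * ctf2d, snr, px) * full
                ref = _fft.fft2(_fft.ifftshift(
                    rotate_image(_fft.fftshift(_fft.ifft2(ref)).real, psi)))
                cross = np.conj(ref) * Fw0
                ccs = _fft.ifft2(cross).real * box * box
                ccs = np.where(window, ccs, -np.inf)
                iy, ix = np.unravel_index(int(np.argmax(ccs)), ccs.shape)
                sy = (iy if iy <= box // 2 else iy - box) * px
                sx = (ix if ix <= box // 2 else ix - box) * px
                na = np.sqrt(float((np.abs(ref[full]) ** 2).sum()))
                nb = np.sqrt(float((np.abs(Fw0[full]) ** 2).sum()))
                if na > 0 and nb > 0:
                    obj = float(ccs[iy, ix] / (na * nb))
        out_params.append(AlignmentParams(phi, theta, psi, sx, sy))
        out_scores[i] = score_from_objective(obj)
    return out_params, out_scores


def refine_defocus(particle: Image, projector: FourierProjector,
                   ctf: CTFParams, pssnr: RadialProfile,
                   params: AlignmentParams, config: SearchConfig,
                   restraint: RestraintModel = None) -> float:
    """1-D grid search of a defocus offset applied to both defocus values.

    Returns the offset (Å) maximizing the objective; defaults scan
    ±500 Å in 50 Å steps (21 grid points).
    """
    offsets = np.arange(-config.defocus_search_range,
                        config.defocus_search_range
                        + config.defocus_search_step / 2,
                        config.defocus_search_step)
    best = (-np.inf, 0.0)
    for off in offsets:
        ctx = MatchedFilterContext(particle, projector,
                                   ctf.with_defocus_offset(float(off)),
                                   pssnr, config, restraint)
        obj = ctx.objective(params)
        if obj > best[0]:
            best = (obj, float(off))
    return best[1]


# --------------------------------------------------------------------------
# 3-D reference masking
# --------------------------------------------------------------------------

def mask_reference_3d(volume: Volume, mask_volume: Volume,
                      falloff_width: float = 10.0,
                      outside_lp: float = None,
                      outside_weight: float = 0.0) -> Volume:
    """Apply a user 3-D mask to a reference map.

    The mask volume is binarized (voxels > 0 are inside), softened with a
    cosine falloff of ``falloff_width`` Å, and the outside is replaced by
    zero or by a low-pass filtered (``outside_lp`` Å), optionally
    down-weighted copy of the original density, blended smoothly at the
    edge.
    """
    if volume.box != mask_volume.box:
        raise ValueError("volume and mask box sizes differ")
    binary = (mask_volume.voxels > 0).astype(np.float64)
    if binary.sum() == 0:
        raise ValueError("empty mask (all voxels <= 0)")
    # soften: distance-based cosine edge via a normalized smooth kernel
    fw_pix = max(falloff_width / volume.pixel_size, 1e-3)
    from scipy import ndimage as _ndi
    dist_out = _ndi.distance_transform_edt(1.0 - binary)
    soft = cosine_edge(dist_out, fw_pix, fw_pix)
    if outside_lp is not None:
        outside = lowpass_filter(volume.voxels, volume.pixel_size,
                                 outside_lp) * outside_weight
    else:
        outside = np.zeros_like(volume.voxels) * outside_weight
    out = soft * volume.voxels + (1.0 - soft) * outside
    return Volume(out, volume.pixel_size)
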