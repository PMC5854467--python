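"""Maximum-likelihood 2-D classification with a resolution ramp.

Particles are noise-whitened with the radially averaged noise power
spectrum estimated from the area outside the particle mask, then softly
assigned to classes by a Gaussian likelihood marginalized over in-plane
rotations (step dα = R/D radians) and a bounded translation grid.  Class
averages are fully CTF-corrected sums (CTF² accumulated in the
denominator with a Wiener constant).  Early iterations use coarse
resolution limits and random data subsets, ramping to the full data set
and the final resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as _fft
from scipy.special import logsumexp

from .ctf import CTFParams, ctf_grid
from .image import (Image, RadialProfile, cosine_edge, n_shells,
                    radial_average, radius_grid, resolution_limit_mask,
                    rotate_image, shell_indices)


@dataclass
class Classify2DConfig:
    """Controls for one classification run (resolutions in Å)."""

    K: int
    n_particles: int
    mask_radius: float
    iterations: int = 20
    R_start: float = 40.0
    R_finish: float = 8.0
    pixel_size: float = 3.0
    translation_bound: float = None    # Å; default mask_radius / 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("need at least one class")
        if not (self.R_start >= self.R_finish > 2 * self.pixel_size):
            raise ValueError("need R_start >= R_finish > 2x pixel size")
        if self.translation_bound is None:
            self.translation_bound = self.mask_radius / 4.0


def angular_step(R: float, D: float) -> float:
    """Integration step dα = R/D (radians) for resolution R and diameter D."""
    if R <= 0 or D <= 0:
        raise ValueError("R and D must be positive")
    return R / D


def schedule(l: int, config: Classify2DConfig):
    """Resolution limit and subset fraction for iteration l (0-based).

    The resolution ramps linearly from R_start to R_finish.  The subset
    fraction uses the three-tier rule with base 300·K/N: the first half of
    the iterations use the base fraction, the next quarter at least 0.3,
    and the final quarter all particles.  With the default 20 iterations
    the tiers are iterations 0-9, 10-14 and 15-19.
    """
    n = config.iterations
    if not 0 <= l < n:
        raise ValueError("iteration index out of range")
    if n == 1:
        R = config.R_finish
    else:
        R = config.R_start + l * (config.R_finish - config.R_start) / (n - 1)
    base = min(300.0 * config.K / config.n_particles, 1.0)
    if l < n // 2:
        p = base
    elif l < (3 * n) // 4:
        p = base if base >= 0.3 else 0.3
    else:
        p = 1.0
    return R, min(p, 1.0)


@dataclass
class NoiseModel2D:
    """Radial noise power spectrum and per-particle background offsets."""

    nps: RadialProfile
    background_constants: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.nps.values <= 0):
            raise ValueError("noise power must be positive in all shells")


def estimate_noise_and_normalize(stack: np.ndarray, pixel_size: float,
                                 mask_radius: float, max_particles: int = 2000,
                                 seed: int = 0):
    """Estimate the noise spectrum and whiten the stack.

    The noise power spectrum comes from the region outside the circular
    particle mask, averaged over up to 2000 randomly chosen particles;
    every particle is divided by sqrt(NPS) in Fourier space and offset so
    its background averages zero.  Returns ``(whitened_stack, model)``.
    """
    n, box = stack.shape[0], stack.shape[1]
    r = radius_grid(box, pixel_size, 2)
    outside = r >= mask_radius
    if outside.mean() < 0.05:
        raise ValueError("mask covers nearly the whole box; no background")
    rng = np.random.default_rng(seed)
    pick = rng.permutation(n)[:min(n, max_particles)]
    w_out = outside.astype(float)
    frac = w_out.mean()
    acc = None
    for i in pick:
        img = stack[i] - stack[i][outside].mean()
        F = _fft.fft2(_fft.ifftshift(img * w_out))
        p = radial_average(np.abs(F) ** 2, pixel_size).values / frac
        acc = p if acc is None else acc + p
    nps_vals = np.maximum(acc / len(pick), 1e-12)
    dg = 1.0 / (box * pixel_size)
    nps = RadialProfile(np.arange(n_shells(box)) * dg, nps_vals)
    idx = np.minimum(shell_indices(box, pixel_size, 2), n_shells(box) - 1)
    amp = np.sqrt(nps_vals[idx])
    white = np.empty_like(stack, dtype=np.float64)
    consts = np.empty(n)
    for i in range(n):
        F = _fft.fft2(_fft.ifftshift(stack[i]))
        # the extra factor box restores unit *pixel* noise variance
        # (whitening alone leaves unit power per Fourier coefficient)
        img = _fft.fftshift(_fft.ifft2(F / amp)).real * box
        c = img[outside].mean()
        white[i] = img - c
        consts[i] = -c
    return white, NoiseModel2D(nps, consts)


def threshold_averages(averages: np.ndarray) -> np.ndarray:
    """Suppress noise: clamp values below t = −0.3·max to t, per class."""
    out = averages.copy()
    for k in range(out.shape[0]):
        t = -0.3 * out[k].max()
        out[k] = np.maximum(out[k], t)
    return out


def _rotation_angles(d_alpha_rad: float) -> np.ndarray:
    n_rot = max(1, int(np.ceil(2.0 * np.pi / d_alpha_rad)))
    return np.arange(n_rot) * 360.0 / n_rot


def em_iteration(stack: np.ndarray, ctfs, averages: np.ndarray,
                 R_l: float, d_alpha: float, config: Classify2DConfig,
                 priors: np.ndarray = None, sigmas: np.ndarray = None,
                 rng: np.random.Generator = None, hard: bool = False):
    """One expectation-maximization pass over the given particle subset.

    Returns ``(new_averages, q, loglik)`` where ``q`` is the soft class
    assignment (rows sum to 1) and ``loglik`` the summed per-particle
    marginal log-likelihood (up to particle-independent constants).
    With ``hard=True`` the class sums use one-hot assignments (classifi-
    cation EM); early hard passes break the symmetry of mixture-mean
    averages that plain soft updates preserve.
    """
    n, box = stack.shape[0], stack.shape[1]
    px = config.pixel_size
    K = averages.shape[0]
    if priors is None:
        priors = np.full(K, 1.0 / K)
    if sigmas is None:
        sigmas = np.ones(n)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    band = resolution_limit_mask(box, px, R_l, 2)
    mask2d = cosine_edge(radius_grid(box, px, 2), config.mask_radius,
                         2 * px)
    angles = _rotation_angles(d_alpha)
    t_pix = max(1, int(round(config.translation_bound / px)))
    ax = np.arange(box)
    ax = np.where(ax <= box // 2, ax, ax - box)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    window = (np.abs(yy) <= t_pix) & (np.abs(xx) <= t_pix)
    # reference transforms per class and rotation (CTF-free)
    ref_ft = np.empty((K, len(angles), box, box), dtype=complex)
    for k in range(K):
        a_m = averages[k] * mask2d
        for ai, ang in enumerate(angles):
            ref_ft[k, ai] = _fft.fft2(_fft.ifftshift(
                rotate_image(a_m, ang))) * band
    F_stack = np.array([_fft.fft2(_fft.ifftshift(img)) * band
                        for img in stack])
    log_post = np.empty((n, K))
    best_rot = np.empty((n, K), dtype=int)
    best_shift = np.empty((n, K, 2), dtype=int)
    ctf_list = [ctf_grid(c, box, px) for c in ctfs]
    n2 = box * box
    for i in range(n):
        ctf2d = ctf_list[i] * band
        Fi = F_stack[i]
        xnorm = (np.abs(Fi) ** 2).sum() / n2
        s2 = sigmas[i] ** 2
        for k in range(K):
            refs = ref_ft[k] * ctf2d[None]
            cross = np.conj(refs) * Fi[None]
            cc = _fft.ifft2(cross, axes=(-2, -1)).real * n2
            anorm = (np.abs(refs) ** 2).sum(axis=(-2, -1)) / n2
            ssd = (xnorm + anorm[:, None, None] - 2.0 * cc / n2)
            loggrid = -ssd / (2.0 * s2)
            loggrid = np.where(window[None], loggrid, -np.inf)
            log_post[i, k] = logsumexp(loggrid) + np.log(max(priors[k], 1e-300))
            flat = int(np.argmax(np.where(window[None], cc, -np.inf)))
            ai, rem = divmod(flat, n2)
            iy, ix = divmod(rem, box)
            best_rot[i, k] = ai
            best_shift[i, k] = (ix if ix <= box // 2 else ix - box,
                                iy if iy <= box // 2 else iy - box)
    loglik = float(logsumexp(log_post, axis=1).sum())
    q = np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))
    if hard:
        # balanced classification-EM: greedy confidence-ordered
        # assignment with a per-class capacity.  An unbalanced split
        # would hand the larger class a less noisy average, which then
        # wins every comparison regardless of the signal.
        cap = int(np.ceil(n / K))
        order = np.argsort(-(log_post.max(axis=1) - np.median(log_post,
                                                              axis=1)))
        counts = np.zeros(K, dtype=int)
        one_hot = np.zeros_like(q)
        for i in order:
            for k in np.argsort(-log_post[i]):
                if counts[k] < cap:
                    one_hot[i, k] = 1.0
                    counts[k] += 1
                    break
        q = one_hot
    # maximization: CTF-corrected probability-weighted class sums
    num = np.zeros((K, box, box), dtype=complex)
    den = np.zeros((K, box, box))
    for i in range(n):
        for k in range(K):
            if q[i, k] < 1e-6:
                continue
            sx, sy = best_shift[i, k]
            img = np.roll(stack[i], (-sy, -sx), axis=(0, 1))
            img = rotate_image(img, -angles[best_rot[i, k]])
            F = _fft.fft2(_fft.ifftshift(img))
            num[k] += q[i, k] * ctf_list[i] * F
            den[k] += q[i, k] * ctf_list[i] ** 2
    wiener = float(K)
    new_averages = np.empty((K, box, box))
    for k in range(K):
        if q[:, k].sum() < 1e-3:
            # unsupported class: re-seed from random particles
            pickn = rng.integers(0, n, size=max(2, n // 10))
            new_averages[k] = stack[pickn].mean(axis=0)
            continue
        A = _fft.ifft2(num[k] / (den[k] + wiener) * band)
        new_averages[k] = _fft.fftshift(A).real
    return new_averages, q, loglik


@dataclass
class ClassAverages:
    """K class-average images plus per-class weights (occupancy sums)."""

    averages: np.ndarray
    weights: np.ndarray
    pixel_size: float


def classify_2d(stack: np.ndarray, ctfs, config: Classify2DConfig):
    """Full 2-D classification run.

    Returns ``(ClassAverages, q, history)`` with ``q`` the final soft
    assignments over the full stack and ``history`` a list of per-
    iteration (R, p, loglik) tuples.
    """
    rng = np.random.default_rng(config.seed)
    n = stack.shape[0]
    white, _ = estimate_noise_and_normalize(stack, config.pixel_size,
                                            config.mask_radius,
                                            seed=config.seed)
    K = config.K
    # seed classes from single random particles: mixture-mean seeds leave
    # all classes identical and the EM cannot break the symmetry.  Each
    # seed is CTF-corrected (Wiener-style phase flip) so it lives in the
    # same contrast convention as the iterated class averages.
    seeds = rng.permutation(n)[:K]
    box = stack.shape[1]
    averages = np.empty((K, box, box))
    for k, i in enumerate(seeds):
        c2 = ctf_grid(ctfs[i], box, config.pixel_size)
        F = _fft.fft2(_fft.ifftshift(white[i]))
        averages[k] = _fft.fftshift(
            _fft.ifft2(c2 * F / (c2 ** 2 + 1.0))).real
    D = 2.0 * config.mask_radius
    priors = np.full(K, 1.0 / K)
    history = []
    q_full = np.full((n, K), 1.0 / K)
    for l in range(config.iterations):
        averages = threshold_averages(averages)
        R_l, p_l = schedule(l, config)
        subset = rng.permutation(n)[:max(K, int(round(p_l * n)))]
        d_alpha = angular_step(R_l, D)
        averages, q, ll = em_iteration(white[subset],
                                       [ctfs[i] for i in subset],
                                       averages, R_l, d_alpha, config,
                                       priors=priors, rng=rng,
                                       hard=(l < config.iterations // 2))
        priors = np.maximum(q.mean(axis=0), 1e-6)
        priors /= priors.sum()
        history.append((R_l, p_l, ll))
    # final assignment pass over everything at the finishing resolution
    _, q_full, _ = em_iteration(white, ctfs, averages, config.R_finish,
                                angular_step(config.R_finish, D), config,
                                priors=priors, rng=rng)
    return (ClassAverages(averages, q_full.sum(axis=0), config.pixel_size),
            q_full, history)
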