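"""Fourier-insertion 3-D reconstruction, FSC machinery and map sharpening.

Particles are background-whitened (unit pixel noise variance), multiplied
by their CTF and inserted along central slices; the accumulator keeps the
CTF² sum so the final map is a per-element Wiener quotient regularized by
1/PSSNR.  Resolution is assessed by Fourier shell correlation between
half-maps, solvent-corrected for the mask/particle volume ratio, and maps
are sharpened by spectral whitening and/or an explicit B-factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as _fft
from scipy.signal import savgol_filter

from .ctf import CTFParams, ctf_grid
from .fourier3d import insert_slice
from .image import (Image, RadialProfile, Volume, cosine_edge, fft2c, fft3c,
                    freq_magnitude, n_shells, radial_average, radius_grid,
                    shell_indices, shift_image_fourier)
from .refine3d import AlignmentParams


# --------------------------------------------------------------------------
# particle whitening for reconstruction
# --------------------------------------------------------------------------

def background_spectrum(particle: Image, mask_radius: float) -> RadialProfile:
    """Radial power spectrum of the particle's background.

    The disk inside ``mask_radius`` is replaced by the mean of the pixels
    at the mask edge before the spectrum is computed, so particle signal
    does not leak into the background estimate.
    """
    r = radius_grid(particle.box, particle.pixel_size, 2)
    inside = r < mask_radius
    edge = (r >= mask_radius) & (r < mask_radius + 3 * particle.pixel_size)
    if not edge.any() or inside.all():
        raise ValueError("mask leaves no background ring")
    bg = particle.pixels.copy()
    bg[inside] = bg[edge].mean()
    F = fft2c(bg)
    return radial_average(np.abs(F) ** 2, particle.pixel_size)


def whiten_background(particle: Image, mask_radius: float,
                      spectrum: RadialProfile = None,
                      return_filter: bool = False):
    """Whiten with the (optionally particle-averaged) background spectrum
    and rescale to an average pixel variance of 1.

    With ``return_filter=True`` also returns the 2-D Fourier gain that
    was applied, so references can be brought onto the same scale.
    """
    if spectrum is None:
        spectrum = background_spectrum(particle, mask_radius)
    box, px = particle.box, particle.pixel_size
    idx = np.minimum(shell_indices(box, px, 2), len(spectrum.values) - 1)
    amp = np.sqrt(np.maximum(spectrum.values[idx], 0.0))
    F = fft2c(particle.pixels)
    gain = np.where(amp > 0, 1.0 / np.maximum(amp, 1e-300), 0.0)
    img = _fft.fftshift(_fft.ifft2(F * gain)).real
    sd = img.std()
    if sd > 0:
        img = img / sd
        gain = gain / sd
    out = Image(img, px)
    return (out, gain) if return_filter else out


def averaged_background_spectrum(stack: np.ndarray, pixel_size: float,
                                 mask_radius: float,
                                 max_particles: int = 2000,
                                 seed: int = 0) -> RadialProfile:
    """Background spectrum averaged over randomly selected particles."""
    rng = np.random.default_rng(seed)
    n = stack.shape[0]
    pick = rng.permutation(n)[:min(n, max_particles)]
    acc = None
    for i in pick:
        prof = background_spectrum(Image(stack[i], pixel_size), mask_radius)
        acc = prof.values if acc is None else acc + prof.values
    return RadialProfile(prof.bin_centers, acc / len(pick))


# --------------------------------------------------------------------------
# accumulator
# --------------------------------------------------------------------------

@dataclass
class ReconstructionAccumulator:
    """Running Fourier-space sums for one 3-D class reconstruction."""

    box: int
    pixel_size: float
    numerator: np.ndarray = None
    denominator: np.ndarray = None
    insert_count: int = 0

    def __post_init__(self) -> None:
        if self.numerator is None:
            self.numerator = np.zeros((self.box,) * 3, dtype=complex)
        if self.denominator is None:
            self.denominator = np.zeros((self.box,) * 3)

    def merge(self, other: "ReconstructionAccumulator") -> None:
        """Accumulator merge: reconstruction is linear in its inputs."""
        self.numerator += other.numerator
        self.denominator += other.denominator
        self.insert_count += other.insert_count


def score_weights(score: float, score_mean: float, bsc: float,
                  g: np.ndarray) -> np.ndarray:
    """Score-based weighting w(score, g) = exp(-BSC/4 (score - mean) g²).

    ``bsc`` in Å² converts score differences into per-particle B-factor
    differences; bsc = 0 disables the weighting (w = 1).
    """
    return np.exp(-bsc / 4.0 * (score - score_mean) * np.asarray(g) ** 2)


def insert_particle(acc: ReconstructionAccumulator, particle: Image,
                    params: AlignmentParams, ctf: CTFParams,
                    q_ik: float = 1.0, sigma_i: float = 1.0,
                    w_ik: np.ndarray = None) -> None:
    """Insert one whitened particle into the accumulator.

    ``w_ik`` is the score-based weight evaluated on the 2-D grid (or None
    for unweighted).  The particle's shifts are removed before insertion.
    """
    if q_ik == 0.0:
        return
    box, px = particle.box, particle.pixel_size
    if not np.all(np.isfinite(particle.pixels)):
        raise ValueError("non-finite particle pixels")
    F = fft2c(particle.pixels)
    F = shift_image_fourier(F, -params.shift_x, -params.shift_y, px)
    ctf2d = ctf_grid(ctf, box, px)
    w = np.ones((box, box)) if w_ik is None else w_ik
    scale = q_ik / sigma_i ** 2
    values = scale * w * ctf2d * F
    weights = scale * w * ctf2d ** 2
    insert_slice(acc.numerator, acc.denominator, values, weights,
                 *params.eulers())
    acc.insert_count += 1


def finalize(acc: ReconstructionAccumulator, pssnr: RadialProfile,
             pssnr_ceiling: float = 1.0e4) -> Volume:
    """Wiener quotient and inverse transform: V = IFFT(num/(den + 1/PSSNR))."""
    if acc.insert_count < 1:
        raise ValueError("no insertions in accumulator")
    box, px = acc.box, acc.pixel_size
    g = _fft.fftshift(freq_magnitude(box, px, 3))   # centered order
    p = np.clip(pssnr.interp(g), 0.0, pssnr_ceiling)
    invp = np.where(p > 0, 1.0 / np.maximum(p, 1e-30), np.inf)
    den = acc.denominator + invp
    quotient = np.where(np.isfinite(den) & (den > 0),
                        acc.numerator / np.where(den > 0, den, 1.0), 0.0)
    vol = _fft.fftshift(_fft.ifftn(_fft.ifftshift(quotient))).real
    return Volume(vol, px)


def reconstruct(stack: np.ndarray, table, pixel_size: float,
                mask_radius: float, pssnr: RadialProfile = None,
                bsc: float = 0.0, subset: np.ndarray = None,
                whiten: bool = True,
                bg_spectrum: RadialProfile = None,
                sigma_override: float = None) -> Volume:
    """Convenience: reconstruct a volume from a stack + parameter table."""
    n, box = stack.shape[0], stack.shape[1]
    acc = ReconstructionAccumulator(box, pixel_size)
    idx = np.arange(n) if subset is None else np.asarray(subset)
    scores = np.asarray(table["score"], dtype=float)
    mean_score = scores[idx].mean() if len(idx) else 0.0
    g2d = freq_magnitude(box, pixel_size, 2)
    if pssnr is None:
        dg = 1.0 / (box * pixel_size)
        pssnr = RadialProfile(np.arange(n_shells(box)) * dg,
                              np.full(n_shells(box), 100.0))
    if whiten and bg_spectrum is None:
        bg_spectrum = averaged_background_spectrum(stack[idx], pixel_size,
                                                   mask_radius)
    for i in idx:
        row = table.iloc[int(i)]
        img = Image(stack[int(i)], pixel_size)
        if whiten:
            img = whiten_background(img, mask_radius, bg_spectrum)
        p = AlignmentParams(row["phi"], row["theta"], row["psi"],
                            row["shift_x"], row["shift_y"])
        ctf = CTFParams(row["defocus1"], row["defocus2"], row["astig_angle"],
                        row["phase_shift"], pixel_size=pixel_size)
        sigma = sigma_override if sigma_override is not None \
            else max(float(row["sigma"]), 1e-6)
        w = score_weights(row["score"], mean_score, bsc, g2d) if bsc else None
        insert_particle(acc, img, p, ctf, q_ik=row["occupancy"] / 100.0,
                        sigma_i=sigma, w_ik=w)
    return finalize(acc, pssnr)


# --------------------------------------------------------------------------
# FSC and resolution
# --------------------------------------------------------------------------

@dataclass
class FSCCurve:
    """Shell frequencies (Å⁻¹), raw and smoothed FSC values."""

    shells: np.ndarray
    fsc: np.ndarray            # smoothed, reported curve
    raw: np.ndarray = None

    def __post_init__(self) -> None:
        self.shells = np.asarray(self.shells, dtype=np.float64)
        self.fsc = np.asarray(self.fsc, dtype=np.float64)
        if self.raw is None:
            self.raw = self.fsc.copy()


def split_dataset(n: int, mode: str = "hundred_subsets"):
    """Half-dataset split by particle parity or 100-subset parity."""
    idx = np.arange(n)
    if mode == "even_odd":
        key = idx
    elif mode == "hundred_subsets":
        key = (idx * 100) // max(n, 1)     # subset index 0..99
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return idx[key % 2 == 0], idx[key % 2 == 1]


def compute_fsc(half1: Volume, half2: Volume, mask: np.ndarray = None,
                smoothing_window: int = 7) -> FSCCurve:
    """Per-shell normalized correlation of two half-map transforms.

    The reported curve is Savitzky-Golay smoothed (cubic, window 7).
    """
    if half1.box != half2.box:
        raise ValueError("half-map box sizes differ")
    box, px = half1.box, half1.pixel_size
    a, b = half1.voxels, half2.voxels
    if mask is not None:
        a, b = a * mask, b * mask
    F1, F2 = fft3c(a), fft3c(b)
    idx = shell_indices(box, px, 3).ravel()
    nsh = n_shells(box)
    keep = idx < nsh
    cross = np.real(F1 * np.conj(F2)).ravel()[keep]
    p1 = (np.abs(F1) ** 2).ravel()[keep]
    p2 = (np.abs(F2) ** 2).ravel()[keep]
    num = np.bincount(idx[keep], weights=cross, minlength=nsh)
    d1 = np.bincount(idx[keep], weights=p1, minlength=nsh)
    d2 = np.bincount(idx[keep], weights=p2, minlength=nsh)
    denom = np.sqrt(d1 * d2)
    raw = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    raw = np.clip(raw, -1.0, 1.0)
    if smoothing_window and nsh >= smoothing_window:
        smooth = savgol_filter(raw, smoothing_window, 3)
        smooth = np.clip(smooth, -1.0, 1.0)
    else:
        smooth = raw.copy()
    dg = 1.0 / (box * px)
    return FSCCurve(np.arange(nsh) * dg, smooth, raw)


def part_fsc(fsc: FSCCurve, f: float) -> FSCCurve:
    """Solvent-corrected half-map FSC: f·F / (1 + (f−1)·F)."""
    if f < 1:
        raise ValueError("mask/particle volume ratio f must be >= 1")

    def corr(v):
        return f * v / (1.0 + (f - 1.0) * v)

    return FSCCurve(fsc.shells, corr(fsc.fsc), corr(fsc.raw))


def part_fsc_model(fsc: FSCCurve, f: float) -> FSCCurve:
    """Solvent correction against a noise-free (model) map: uses FSC²."""
    if f < 1:
        raise ValueError("mask/particle volume ratio f must be >= 1")

    def corr(v):
        return f * v ** 2 / (1.0 + (f - 1.0) * v ** 2)

    return FSCCurve(fsc.shells, corr(fsc.fsc), corr(fsc.raw))


def particle_volume_from_mass(mw: float) -> float:
    """Particle volume (Å³) from molecular mass: Mw / 0.81 Da per Å³."""
    if mw <= 0:
        raise ValueError("molecular mass must be positive")
    return mw / 0.81


def mask_particle_ratio(mask_radius: float, mw: float) -> float:
    """f = spherical-mask volume over mass-estimated particle volume."""
    vol_mask = 4.0 / 3.0 * np.pi * mask_radius ** 3
    return max(1.0, vol_mask / particle_volume_from_mass(mw))


def resolution_at_threshold(fsc: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (Å) of the first FSC crossing, by linear interpolation.

    Returns the Nyquist resolution if the curve never crosses.
    """
    s, v = fsc.shells, fsc.fsc
    for i in range(1, len(v)):
        if v[i] < threshold <= v[i - 1]:
            frac = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            g = s[i - 1] + frac * (s[i] - s[i - 1])
            return 1.0 / g if g > 0 else np.inf
    return 1.0 / s[-1] if s[-1] > 0 else np.inf


def pssnr_from_fsc(fsc: FSCCurve, ceiling: float = 1.0e4) -> RadialProfile:
    """Full-dataset spectral SNR per shell from a (part-)FSC curve.

    Half-map FSC = SSNR_half/(SSNR_half+1); the full dataset has twice the
    half-dataset SSNR, so PSSNR = 2·FSC/(1−FSC), clipped to a ceiling.
    """
    v = np.clip(fsc.fsc, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        p = np.where(v < 1.0, 2.0 * v / np.maximum(1.0 - v, 1e-12), ceiling)
    return RadialProfile(fsc.shells, np.clip(p, 0.0, ceiling))


# --------------------------------------------------------------------------
# likelihood-based blurring
# --------------------------------------------------------------------------

def blurred_insert(acc: ReconstructionAccumulator, particle: Image,
                   base_params: AlignmentParams, ctf: CTFParams,
                   gamma_grid, q_ik: float = 1.0, sigma_i: float = 1.0,
                   w_ik: np.ndarray = None) -> None:
    """Insert one particle blurred over an (alpha, dx, dy) likelihood grid.

    ``gamma_grid`` is an iterable of ``(alpha_deg, dx, dy, gamma)``;
    gamma values are normalized to sum to 1 before insertion, so a delta
    likelihood reduces exactly to the standard insertion.
    """
    entries = [(a, dx, dy, g) for a, dx, dy, g in gamma_grid]
    total = sum(e[3] for e in entries)
    if total <= 0:
        raise ValueError("degenerate (all-zero) likelihood grid")
    for alpha, dx, dy, gamma in entries:
        p = AlignmentParams(base_params.phi, base_params.theta,
                            base_params.psi + alpha,
                            base_params.shift_x + dx,
                            base_params.shift_y + dy)
        insert_particle(acc, particle, p, ctf, q_ik=q_ik * gamma / total,
                        sigma_i=sigma_i, w_ik=w_ik)
    # blurring inserts the particle len(entries) times but with weights
    # summing to the single-particle weight
    acc.insert_count -= max(len(entries) - 1, 0)


# --------------------------------------------------------------------------
# sharpening
# --------------------------------------------------------------------------

@dataclass
class SharpenConfig:
    """Map sharpening controls (B-factor in Å², resolutions in Å)."""

    bfactor: float = 0.0
    whiten_beyond: float = 8.0          # None disables spectral whitening
    mask_inner: float = 0.0             # hollow-sphere mask radii, Å
    mask_outer: float = None            # None -> no spherical masking
    resolution_cutoff: float = None
    fom_filter: bool = False

    def __post_init__(self) -> None:
        if self.mask_outer is not None and self.mask_outer <= self.mask_inner:
            raise ValueError("mask_outer must exceed mask_inner")


def sharpen_map(volume: Volume, config: SharpenConfig,
                fsc: FSCCurve = None) -> Volume:
    """Mask, whiten the spectrum beyond a resolution, apply a B-factor and
    optionally a figure-of-merit filter sqrt(2·FSC/(1+FSC))."""
    box, px = volume.box, volume.pixel_size
    vox = volume.voxels
    if config.mask_outer is not None:
        r = radius_grid(box, px, 3)
        mask = cosine_edge(r, config.mask_outer, 2 * px)
        if config.mask_inner > 0:
            mask *= 1.0 - cosine_edge(r, config.mask_inner, 2 * px)
        vox = vox * mask
    F = fft3c(vox)
    g = freq_magnitude(box, px, 3)
    if config.whiten_beyond is not None:
        prof = radial_average(np.abs(F) ** 2, px)
        g0 = 1.0 / config.whiten_beyond
        i0 = int(np.searchsorted(prof.bin_centers, g0))
        i0 = min(i0, len(prof.values) - 1)
        target = prof.values[i0]
        gain = np.ones_like(prof.values)
        beyond = prof.bin_centers > g0
        nz = beyond & (prof.values > 0)
        gain[nz] = np.sqrt(target / prof.values[nz])
        idx = np.minimum(shell_indices(box, px, 3), len(gain) - 1)
        F = F * gain[idx]
    if config.resolution_cutoff is not None:
        if config.resolution_cutoff < 2.0 * px:
            raise ValueError("resolution cutoff beyond Nyquist")
        F = F * cosine_edge(g, 1.0 / config.resolution_cutoff + 2.0 / (box * px),
                            2.0 / (box * px))
    if config.bfactor:
        F = F * np.exp(-config.bfactor * g ** 2 / 4.0)
    if config.fom_filter:
        if fsc is None:
            raise ValueError("FOM filter requested without an FSC curve")
        fom = np.sqrt(np.clip(2.0 * fsc.fsc / (1.0 + fsc.fsc), 0.0, 1.0))
        idx = np.minimum(shell_indices(box, px, 3), len(fom) - 1)
        F = F * fom[idx]
    from .image import ifft3c
    return Volume(ifft3c(F).real, px)
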