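"""Matched-filter particle picking with a soft-edged disk template.

The micrograph is Fourier-cropped to half the highest picking resolution,
high-pass filtered, and whitened with the average rotational power
spectrum of its lowest-variance areas.  Correlation against a CTF-blurred
soft disk is normalized so that, absent particles, scores follow a
standard normal distribution — the detection threshold is therefore a
number of standard deviations of the null.  Abnormal local-variance or
local-mean areas (ice, carbon) are excluded via mode/FWHM thresholds on
the local-statistics histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as _fft
from scipy import ndimage

from .ctf import CTFParams, ctf_grid
from .image import (Image, RadialProfile, cosine_edge, fourier_crop,
                    freq_magnitude, highpass_filter, radial_average,
                    radius_grid, shell_indices)


@dataclass
class PickParams:
    """User-facing picking controls (distances in Å)."""

    template_radius: float = 40.0
    max_particle_radius: float = 60.0
    threshold_sd: float = 4.0
    highest_resolution: float = 30.0
    n_background_areas: int = 50
    use_variance_mode_areas: bool = False
    phase_plate_phase: float = None     # radians, or None

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.max_particle_radius < self.template_radius:
            raise ValueError("max_particle_radius must be >= template_radius")


@dataclass
class PickList:
    """Particle coordinates (Å from micrograph pixel (0,0)) with scores."""

    coords: np.ndarray          # (n, 2) x, y in Å
    peak_sd: np.ndarray         # score in null-SD units

    def __len__(self) -> int:
        return len(self.coords)


def preprocess(micrograph: Image, params: PickParams) -> Image:
    """Fourier-crop to the working pixel size and remove density ramps.

    The working pixel size is half the highest resolution used in picking
    (default 30 Å -> 15 Å/pixel); a cosine-edged high-pass removes slow
    intensity ramps from ice-thickness or illumination gradients.
    """
    target_px = params.highest_resolution / 2.0
    if micrograph.pixel_size > target_px:
        raise ValueError("micrograph pixel size exceeds working pixel size")
    work = fourier_crop(micrograph, target_px)
    if work.box < 6 * params.template_radius / work.pixel_size:
        # just a sanity floor; tiny fields cannot support statistics
        if work.box < 16:
            raise ValueError("micrograph too small for picking")
    highpass_res = 4.0 * params.max_particle_radius
    filtered = highpass_filter(work.pixels - work.pixels.mean(),
                               work.pixel_size, highpass_res)
    return Image(filtered, work.pixel_size)


def _disk_offsets(radius_pix: int):
    ax = np.arange(-radius_pix, radius_pix + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    return (yy * yy + xx * xx) <= radius_pix * radius_pix


def local_stats(image: Image, radius: float):
    """Local mean/variance maps over a disk plus histogram mode and FWHM.

    Returns ``(mean_map, var_map, mo_mean, fwhm_mean, mo_var, fwhm_var)``.
    """
    rad_pix = max(2, int(round(radius / image.pixel_size)))
    footprint = _disk_offsets(rad_pix)
    mean_map = ndimage.uniform_filter(image.pixels, 0)  # placeholder
    k = footprint.astype(np.float64)
    k /= k.sum()
    mean_map = ndimage.convolve(image.pixels, k, mode="reflect")
    sq_map = ndimage.convolve(image.pixels ** 2, k, mode="reflect")
    var_map = np.maximum(sq_map - mean_map ** 2, 0.0)
    mo_mean, fwhm_mean = histogram_mode_fwhm(mean_map)
    mo_var, fwhm_var = histogram_mode_fwhm(var_map)
    return mean_map, var_map, mo_mean, fwhm_mean, mo_var, fwhm_var


def histogram_mode_fwhm(values: np.ndarray, bins: int = 128):
    """Mode and full width at half maximum of a value distribution."""
    v = np.asarray(values).ravel()
    lo, hi = np.percentile(v, [0.5, 99.5])
    if hi <= lo:
        return float(v.mean()), 0.0
    hist, edges = np.histogram(v, bins=bins, range=(lo, hi))
    hist = ndimage.gaussian_filter1d(hist.astype(float), 2.0)
    imax = int(np.argmax(hist))
    mode = 0.5 * (edges[imax] + edges[imax + 1])
    half = hist[imax] / 2.0
    left = imax
    while left > 0 and hist[left] > half:
        left -= 1
    right = imax
    while right < bins - 1 and hist[right] > half:
        right += 1
    fwhm = (right - left) * (edges[1] - edges[0])
    return float(mode), float(fwhm)


def background_whitening_filter(image: Image, params: PickParams,
                                var_map: np.ndarray = None,
                                mo_var: float = None,
                                fwhm_var: float = None) -> RadialProfile:
    """Whitening filter from the areas most likely devoid of particles.

    Square tiles of side 2x max_particle_radius are ranked by local
    variance; the ``n_background_areas`` lowest-variance tiles (or those
    closest to the variance mode, if requested) contribute an average
    rotational power spectrum whose inverse square root is the filter.
    """
    if params.n_background_areas < 1:
        raise ValueError("need at least one background area")
    px = image.pixel_size
    # floor the tile size so the background spectrum has enough shells
    tile = max(16, int(round(2 * params.max_particle_radius / px)))
    tile += tile % 2
    box = image.box
    if var_map is None:
        _, var_map, _, _, mo_var, _ = local_stats(
            image, params.max_particle_radius)
    positions = []
    for y0 in range(0, box - tile + 1, tile):
        for x0 in range(0, box - tile + 1, tile):
            c_var = var_map[y0 + tile // 2, x0 + tile // 2]
            positions.append((c_var, y0, x0))
    if params.use_variance_mode_areas and mo_var is not None:
        positions.sort(key=lambda p: abs(p[0] - mo_var))
    else:
        positions.sort(key=lambda p: p[0])
    n_use = min(params.n_background_areas, len(positions))
    power = np.zeros(tile // 2 + 1)
    for _, y0, x0 in positions[:n_use]:
        t = image.pixels[y0:y0 + tile, x0:x0 + tile]
        F = _fft.fft2(t - t.mean())
        power += radial_average(np.abs(F) ** 2, px).values
    power /= n_use
    centers = radial_average(np.zeros((tile, tile)), px).bin_centers
    filt = np.where(power > 0, 1.0 / np.sqrt(np.maximum(power, 1e-30)), 0.0)
    # tiles are mean-subtracted, so the DC shell carries no power; give it
    # the first informative shell's gain instead of an explosive 1/sqrt(0)
    if len(filt) > 1:
        filt[0] = filt[1]
    return RadialProfile(centers, filt)


def soft_disk_template(box: int, pixel_size: float, radius: float,
                       edge_width: float = None) -> np.ndarray:
    """Soft-edged disk template centered in the box."""
    if edge_width is None:
        edge_width = 2.0 * pixel_size
    r = radius_grid(box, pixel_size, 2)
    return cosine_edge(r, radius + edge_width, edge_width)


def match_template(image: Image, whitening: RadialProfile,
                   ctf: CTFParams = None,
                   params: PickParams = None) -> np.ndarray:
    """Matched-filter score map in null-SD units.

    The whitened micrograph is normalized to unit variance and correlated
    with a unit-norm, optionally CTF-blurred disk; under a no-particle
    null the scores are then ~N(0, 1).
    """
    box, px = image.box, image.pixel_size
    F = _fft.fft2(image.pixels - image.pixels.mean())
    g = freq_magnitude(box, px, 2)
    F = F * whitening.interp(g)
    white = _fft.ifft2(F).real
    sd = white.std()
    if sd > 0:
        white /= sd
    tmpl = soft_disk_template(box, px, params.template_radius)
    tmpl -= tmpl.mean()
    Ft = _fft.fft2(_fft.ifftshift(tmpl))
    if ctf is not None:
        ctf_resampled = ctf_grid(ctf, box, px)
        Ft = Ft * np.abs(ctf_resampled)
    # unit-norm template in real space (Parseval: ||t||² = sum|Ft|²/N²)
    norm = np.sqrt((np.abs(Ft) ** 2).sum()) / box
    if norm > 0:
        Ft = Ft / norm
    score = _fft.ifft2(np.conj(Ft) * _fft.fft2(white)).real
    # standardize against the empirical null: the high-pass and whitening
    # leave the noise only approximately white, so the analytic variance
    # is biased; a robust (median absolute deviation) standard deviation
    # is insensitive to the few true particle peaks
    med = np.median(score)
    mad_sd = 1.4826 * np.median(np.abs(score - med))
    if mad_sd > 0:
        score = (score - med) / mad_sd
    return score


def exclusion_mask(mean_map: np.ndarray, var_map: np.ndarray,
                   mo_mean: float, fwhm_mean: float,
                   mo_var: float, fwhm_var: float,
                   phase_plate_phase: float = None) -> np.ndarray:
    """Boolean map of pixels to exclude from picking.

    Variance above mode + k·FWHM (k = 2, or 8 with a phase plate giving a
    phase shift in (0.1π, 0.9π)) or mean outside mode ± 2·FWHM marks an
    abnormal area.  Degenerate histograms (FWHM 0) exclude nothing.
    """
    if fwhm_var <= 0 and fwhm_mean <= 0:
        return np.zeros(var_map.shape, dtype=bool)
    k_var = 2.0
    if phase_plate_phase is not None and \
            0.1 * np.pi < phase_plate_phase < 0.9 * np.pi:
        k_var = 8.0
    bad = np.zeros(var_map.shape, dtype=bool)
    if fwhm_var > 0:
        bad |= var_map > mo_var + k_var * fwhm_var
    if fwhm_mean > 0:
        bad |= np.abs(mean_map - mo_mean) > 2.0 * fwhm_mean
    return bad


def find_peaks(score_map: np.ndarray, exclusion: np.ndarray,
               params: PickParams, pixel_size: float) -> PickList:
    """Greedy descending-score peak selection with distance suppression.

    Excluded pixels are never picked; each pick suppresses its
    neighbourhood of radius ``max_particle_radius``; ties break by scan
    order so the result is deterministic.
    """
    score = score_map.copy()
    score[exclusion] = -np.inf
    min_dist_pix = params.max_particle_radius / pixel_size
    box = score.shape[0]
    order = np.argsort(score, axis=None, kind="stable")[::-1]
    taken = np.zeros_like(score, dtype=bool)
    picks, sds = [], []
    r2 = min_dist_pix ** 2
    for flat in order:
        s = score.flat[flat]
        if s < params.threshold_sd:
            break
        iy, ix = divmod(int(flat), box)
        if taken[iy, ix]:
            continue
        picks.append((ix * pixel_size, iy * pixel_size))
        sds.append(float(s))
        y0, y1 = max(0, int(iy - min_dist_pix)), min(box, int(iy + min_dist_pix) + 1)
        x0, x1 = max(0, int(ix - min_dist_pix)), min(box, int(ix + min_dist_pix) + 1)
        yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1),
                             indexing="ij")
        taken[y0:y1, x0:x1] |= ((yy - iy) ** 2 + (xx - ix) ** 2) <= r2
    return PickList(np.array(picks).reshape(-1, 2), np.array(sds))


def pick_particles(micrograph: Image, params: PickParams,
                   ctf: CTFParams = None) -> PickList:
    """Full picking pipeline on one micrograph; coordinates in original Å."""
    work = preprocess(micrograph, params)
    mean_map, var_map, mo_m, fw_m, mo_v, fw_v = local_stats(
        work, params.max_particle_radius)
    whit = background_whitening_filter(work, params, var_map, mo_v, fw_v)
    score = match_template(work, whit, ctf, params)
    excl = exclusion_mask(mean_map, var_map, mo_m, fw_m, mo_v, fw_v,
                          params.phase_plate_phase)
    return find_peaks(score, excl, params, work.pixel_size)
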