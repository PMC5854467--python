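"""Contrast transfer function model, determination and diagnostics.

The fitting strategy mirrors modern Thon-ring fitting practice: a fast
exhaustive search over a 1-D (azimuthally averaged) CTF with only defocus
and phase shift as parameters, followed by local refinement of the full
astigmatic 2-D model against the background-subtracted amplitude spectrum.
A radial sine-edged mask (0 at the origin, 1 at 1/4 Å⁻¹) emphasises
high-resolution rings during the 2-D refinement; diagnostics always use the
background-subtracted but non-masked spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
import scipy.fft as _fft

from .image import (Image, RadialProfile, freq_grids, freq_magnitude,
                    n_shells, radial_average, radial_expand, shell_indices)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å for voltage in kV."""
    v = voltage_kv * 1000.0
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


@dataclass
class CTFParams:
    """Microscope and per-micrograph CTF description.

    ``defocus1 >= defocus2`` by convention (positive = underfocus, Å);
    ``astig_angle`` in degrees gives the azimuth of ``defocus1``;
    ``phase_shift`` (radians) is an additional phase-plate term.
    """

    defocus1: float
    defocus2: float
    astig_angle: float = 0.0
    phase_shift: float = 0.0
    voltage: float = 300.0          # kV
    cs: float = 2.7                 # mm
    amplitude_contrast: float = 0.07
    pixel_size: float = 1.0         # Å

    def __post_init__(self) -> None:
        if not (0 <= self.amplitude_contrast < 1):
            raise ValueError("amplitude_contrast must be in [0, 1)")
        if self.defocus1 < self.defocus2:
            self.defocus1, self.defocus2 = self.defocus2, self.defocus1
            self.astig_angle += 90.0

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage)

    def with_defocus_offset(self, offset: float) -> "CTFParams":
        """Apply the same defocus offset to both defocus values."""
        return replace(self, defocus1=self.defocus1 + offset,
                       defocus2=self.defocus2 + offset)


def _phase_aberration(params: CTFParams, g, azimuth):
    lam = params.wavelength
    cs_A = params.cs * 1.0e7
    ang = np.deg2rad(params.astig_angle)
    df = 0.5 * (params.defocus1 + params.defocus2
                + (params.defocus1 - params.defocus2)
                * np.cos(2.0 * (azimuth - ang)))
    a = params.amplitude_contrast
    return (np.pi * lam * g ** 2 * df
            - 0.5 * np.pi * cs_A * lam ** 3 * g ** 4
            + params.phase_shift
            + np.arctan2(a, np.sqrt(1.0 - a * a)))


def evaluate_ctf(params: CTFParams, g, azimuth=0.0):
    """CTF value(s) at frequency g (Å⁻¹) and azimuth (radians): −sin(χ)."""
    return -np.sin(_phase_aberration(params, np.asarray(g, dtype=float),
                                     azimuth))


def ctf_grid(params: CTFParams, box: int, pixel_size: float = None) -> np.ndarray:
    """Evaluate the CTF on an FFT-ordered 2-D frequency grid."""
    px = params.pixel_size if pixel_size is None else pixel_size
    gx, gy = freq_grids(box, px, 2)
    g = np.sqrt(gx * gx + gy * gy)
    azimuth = np.arctan2(gy, gx)
    return evaluate_ctf(params, g, azimuth)


def ctf_zero_crossings(params: CTFParams, g_max: float, azimuth: float = 0.0,
                       n_grid: int = 200000) -> np.ndarray:
    """Frequencies of CTF sign changes up to g_max (dense-grid root finder)."""
    g = np.linspace(0.0, g_max, n_grid)
    vals = evaluate_ctf(params, g, azimuth)
    sign = np.sign(vals)
    flips = np.nonzero(sign[1:] * sign[:-1] < 0)[0]
    return 0.5 * (g[flips] + g[flips + 1])


# --------------------------------------------------------------------------
# amplitude spectrum
# --------------------------------------------------------------------------

def amplitude_spectrum(frames, pixel_size: float, frames_to_sum: int = 1,
                       spectrum_box: int = 256, overlap: float = 0.5) -> Image:
    """Tile-averaged amplitude spectrum of an image or movie.

    ``frames`` is a 2-D array or a list/stack of frames.  For movies,
    consecutive groups of ``frames_to_sum`` frames are summed before the
    power spectra are computed (sub-sums amplify Thon rings blurred by
    drift in the full sum).  If the pixel size is finer than 1.4 Å the
    spectrum is resampled so its edge corresponds to 1/2.8 Å⁻¹.

    Returns an Image whose pixels hold the FFT-ordered amplitude spectrum
    and whose ``pixel_size`` is the effective real-space sampling.
    """
    arr = np.asarray(frames, dtype=np.float64)
    if arr.ndim == 2:
        groups = [arr]
    else:
        if frames_to_sum < 1:
            raise ValueError("frames_to_sum must be >= 1")
        groups = [arr[i:i + frames_to_sum].sum(axis=0)
                  for i in range(0, arr.shape[0], frames_to_sum)]
    size = min(spectrum_box, groups[0].shape[0], groups[0].shape[1])
    if size < 32:
        raise ValueError("input smaller than minimum spectrum size")
    step = max(1, int(size * (1.0 - overlap)))
    power = np.zeros((size, size))
    count = 0
    for gimg in groups:
        ny, nx = gimg.shape
        for y0 in range(0, ny - size + 1, step):
            for x0 in range(0, nx - size + 1, step):
                tile = gimg[y0:y0 + size, x0:x0 + size]
                tile = tile - tile.mean()
                F = _fft.fft2(tile)
                power += np.abs(F) ** 2
                count += 1
    power /= max(count, 1)
    amp = np.sqrt(power)
    eff_px = pixel_size
    if pixel_size < 1.4:
        # crop the Fourier field so the new edge sits at 1/2.8 Å⁻¹
        n_out = int(round(size * pixel_size / 1.4 / 2)) * 2
        half = n_out // 2
        keep = np.concatenate([np.arange(half), np.arange(size - half, size)])
        amp = amp[np.ix_(keep, keep)]
        eff_px = size * pixel_size / n_out
    return Image(amp, eff_px)


def subtract_background(spectrum: Image, smoothing_shells: float = None) -> Image:
    """Remove the slowly-varying radial background from an amplitude spectrum.

    The background is the heavily smoothed radial average (Gaussian kernel,
    default ~1/12 of the shell count), expanded back onto the 2-D grid.
    Ring positions are unaffected; the output fluctuates around zero in
    ring-free regions.
    """
    box = spectrum.box
    prof = radial_average(spectrum.pixels, spectrum.pixel_size)
    sigma = smoothing_shells if smoothing_shells else max(3.0, n_shells(box) / 12.0)
    bg_vals = ndimage.gaussian_filter1d(prof.values, sigma, mode="nearest")
    bg = RadialProfile(prof.bin_centers, bg_vals)
    out = spectrum.pixels - radial_expand(bg, box, spectrum.pixel_size, 2)
    return Image(out, spectrum.pixel_size)


def _fitting_band(centers: np.ndarray, low_res: float, high_res: float):
    lo = 1.0 / low_res
    hi = 1.0 / high_res
    return (centers >= lo) & (centers <= hi)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def fit_ctf_1d(profile: RadialProfile, template: CTFParams,
               defocus_range=(2000.0, 40000.0), defocus_step: float = 100.0,
               phase_shift_range=(0.0, 0.0), phase_shift_step: float = 0.1745,
               low_res: float = 30.0, high_res: float = None):
    """Exhaustive 1-D search over (defocus, phase shift).

    Correlates |CTF|² of a zero-astigmatism model with the
    background-subtracted radial profile inside the fitting band and
    returns the grid argmax ``(defocus, phase_shift)``.
    """
    centers = profile.bin_centers
    if high_res is None:
        high_res = 1.0 / centers[-1]
    band = _fitting_band(centers, low_res, high_res)
    if band.sum() < 5:
        raise ValueError("fitting band too narrow")
    data = profile.values[band]
    if np.allclose(data, 0):
        raise ValueError("degenerate (all-zero) profile")
    g = centers[band]
    defoci = np.arange(defocus_range[0], defocus_range[1] + defocus_step / 2,
                       defocus_step)
    if phase_shift_range[1] > phase_shift_range[0]:
        phases = np.arange(phase_shift_range[0],
                           phase_shift_range[1] + phase_shift_step / 2,
                           phase_shift_step)
    else:
        phases = np.array([phase_shift_range[0]])
    best = (-np.inf, defoci[0], phases[0])
    for ps in phases:
        for df in defoci:
            p = replace(template, defocus1=df, defocus2=df, astig_angle=0.0,
                        phase_shift=float(ps))
            model = evaluate_ctf(p, g) ** 2
            score = _ncc(model, data)
            if score > best[0]:
                best = (score, float(df), float(ps))
    return best[1], best[2]


def sine_radial_mask(box: int, pixel_size: float,
                     full_at: float = 0.25) -> np.ndarray:
    """Radial sine mask: 0.0 at the Fourier origin, 1.0 at ``full_at`` Å⁻¹."""
    g = freq_magnitude(box, pixel_size, 2)
    m = np.sin(0.5 * np.pi * np.minimum(g / full_at, 1.0))
    return m


def _spectrum_objective(spectrum: Image, params: CTFParams, mask: np.ndarray,
                        band2d: np.ndarray) -> float:
    model = ctf_grid(params, spectrum.box, spectrum.pixel_size) ** 2
    w = mask[band2d]
    a = (model[band2d] * w)
    b = (spectrum.pixels[band2d] * w)
    return _ncc(a, b)


def refine_ctf_2d(spectrum: Image, initial: CTFParams,
                  low_res: float = 30.0, high_res: float = None,
                  max_evals: int = 2000):
    """Local refinement of (defocus1, defocus2, angle, phase) against the
    masked 2-D background-subtracted spectrum.

    Returns ``(params, converged)``.  The returned objective is never worse
    than at the initial parameters.
    """
    box = spectrum.box
    if high_res is None:
        high_res = 2.0 * spectrum.pixel_size
    g = freq_magnitude(box, spectrum.pixel_size, 2)
    band2d = (g >= 1.0 / low_res) & (g <= 1.0 / high_res)
    mask = sine_radial_mask(box, spectrum.pixel_size)

    def unpack(x):
        return replace(initial, defocus1=max(x[0], x[1]),
                       defocus2=min(x[0], x[1]),
                       astig_angle=x[2] if x[0] >= x[1] else x[2] + 90.0,
                       phase_shift=x[3])

    def cost(x):
        return -_spectrum_objective(spectrum, unpack(x), mask, band2d)

    # the correlation landscape is nearly flat in the astigmatism
    # parameters until they are roughly right, and a 1-D pre-search is
    # biased when astigmatism is large: a coarse pre-scan over mean
    # defocus, astigmatism magnitude and angle gives the simplex a
    # usable start
    mean_df0 = 0.5 * (initial.defocus1 + initial.defocus2)
    best0 = (-np.inf, initial)
    for d_off in (-750.0, -500.0, -250.0, 0.0, 250.0, 500.0, 750.0):
        mean_df = mean_df0 + d_off
        for astig in (0.0, 500.0, 1000.0, 2000.0, 3000.0):
            for ang in np.arange(0.0, 180.0, 15.0) if astig else [0.0]:
                cand = replace(initial, defocus1=mean_df + astig / 2,
                               defocus2=mean_df - astig / 2,
                               astig_angle=ang)
                s = _spectrum_objective(spectrum, cand, mask, band2d)
                if s > best0[0]:
                    best0 = (s, cand)
    initial_scan = best0[1]
    x0 = np.array([initial_scan.defocus1, initial_scan.defocus2,
                   initial_scan.astig_angle, initial_scan.phase_shift])
    # parameter scales differ wildly (A vs degrees vs radians): seed the
    # simplex with physically sensible steps
    steps = [400.0, -400.0, 30.0, 0.3]
    simplex = [x0]
    for i, d in enumerate(steps):
        v = x0.copy()
        v[i] += d
        simplex.append(v)
    res = optimize.minimize(cost, x0, method="Nelder-Mead",
                            options={"maxfev": max_evals, "xatol": 1.0,
                                     "fatol": 1e-7,
                                     "initial_simplex": np.array(simplex)})
    refined = unpack(res.x)
    if -res.fun < _spectrum_objective(spectrum, initial, mask, band2d):
        return initial, False
    return refined, bool(res.success)


def exhaustive_ctf_2d(spectrum: Image, template: CTFParams,
                      defocus_range=(2000.0, 40000.0),
                      defocus_step: float = 100.0,
                      low_res: float = 30.0, high_res: float = None) -> CTFParams:
    """Direct exhaustive 2-D-spectrum search over zero-astigmatism defoci.

    Serves as the independent oracle for the 1-D-then-2-D pipeline on
    astigmatism-free inputs.
    """
    box = spectrum.box
    if high_res is None:
        high_res = 2.0 * spectrum.pixel_size
    g = freq_magnitude(box, spectrum.pixel_size, 2)
    band2d = (g >= 1.0 / low_res) & (g <= 1.0 / high_res)
    mask = sine_radial_mask(box, spectrum.pixel_size)
    defoci = np.arange(defocus_range[0], defocus_range[1] + defocus_step / 2,
                       defocus_step)
    best = (-np.inf, defoci[0])
    for df in defoci:
        p = replace(template, defocus1=df, defocus2=df, astig_angle=0.0)
        s = _spectrum_objective(spectrum, p, mask, band2d)
        if s > best[0]:
            best = (s, float(df))
    return replace(template, defocus1=best[1], defocus2=best[1],
                   astig_angle=0.0)


@dataclass
class FitDiagnostics:
    """Per-shell quality of fit and derived resolution of the CTF fit."""

    ccfit: RadialProfile
    fit_resolution: float
    aliasing_warning: bool = False


def goodness_of_fit(spectrum: Image, params: CTFParams, window: int = 9,
                    cc_threshold: float = 0.3, persistence: int = 3,
                    low_res: float = 30.0) -> FitDiagnostics:
    """Moving-window correlation between fitted CTF² and the radial profile.

    ``fit_resolution`` is the resolution of the first shell where the
    correlation drops below ``cc_threshold`` for ``persistence``
    consecutive shells (shells coarser than ``low_res`` are ignored).
    """
    if window < 3:
        raise ValueError("window must be >= 3 shells")
    prof = radial_average(spectrum.pixels, spectrum.pixel_size)
    nsh = len(prof.values)
    if window > nsh:
        raise ValueError("window larger than profile")
    model2d = ctf_grid(params, spectrum.box, spectrum.pixel_size) ** 2
    model = radial_average(model2d, spectrum.pixel_size).values
    half = window // 2
    cc = np.zeros(nsh)
    for i in range(nsh):
        lo, hi = max(0, i - half), min(nsh, i + half + 1)
        cc[i] = _ncc(model[lo:hi], prof.values[lo:hi])
    centers = prof.bin_centers
    start = np.searchsorted(centers, 1.0 / low_res)
    fit_res = 1.0 / centers[-1]
    run = 0
    for i in range(start, nsh):
        run = run + 1 if cc[i] < cc_threshold else 0
        if run >= persistence:
            first_bad = i - persistence + 1
            fit_res = 1.0 / centers[first_bad] if centers[first_bad] > 0 else np.inf
            break
    alias = check_aliasing(spectrum.box, params,
                           fit_limit=1.0 / fit_res if fit_res > 0 else None)
    return FitDiagnostics(RadialProfile(centers, cc), fit_res, alias)


def check_aliasing(box_size: int, params: CTFParams,
                   fit_limit: float = None) -> bool:
    """True iff the local Thon-ring period undersamples the spectrum.

    The local oscillation period of the CTF follows from the derivative of
    the aberration phase, Δg = π/|dχ/dg|; aliasing is flagged when this
    period falls below two spectrum pixels before the fitting limit.
    """
    lam = params.wavelength
    cs_A = params.cs * 1.0e7
    df = 0.5 * (params.defocus1 + params.defocus2)
    dg_pix = 1.0 / (box_size * params.pixel_size)
    g_ny = 1.0 / (2.0 * params.pixel_size)
    g_max = min(fit_limit, g_ny) if fit_limit else g_ny
    g = np.linspace(dg_pix, g_max, 512)
    dchi = np.abs(2 * np.pi * lam * g * df - 2 * np.pi * cs_A * lam ** 3 * g ** 3)
    period = np.full_like(g, np.inf)
    nz = dchi > 0
    period[nz] = np.pi / dchi[nz]
    return bool(np.any(period < 2.0 * dg_pix))


def fit_ctf(spectrum_or_image, template: CTFParams,
            defocus_range=(2000.0, 40000.0), defocus_step: float = 200.0,
            phase_shift_range=(0.0, 0.0), low_res: float = 30.0,
            high_res: float = None, force_2d_exhaustive: bool = False):
    """Full CTF determination: background subtraction, 1-D exhaustive search,
    2-D refinement and diagnostics.

    Returns ``(CTFParams, FitDiagnostics)``.
    """
    spec = spectrum_or_image
    sub = subtract_background(spec)
    if force_2d_exhaustive:
        init = exhaustive_ctf_2d(sub, template, defocus_range, defocus_step,
                                 low_res, high_res)
    else:
        prof = radial_average(sub.pixels, sub.pixel_size)
        df, ps = fit_ctf_1d(prof, template, defocus_range, defocus_step,
                            phase_shift_range, low_res=low_res,
                            high_res=high_res)
        init = replace(template, defocus1=df, defocus2=df, astig_angle=0.0,
                       phase_shift=ps)
    refined, _ = refine_ctf_2d(sub, init, low_res=low_res, high_res=high_res)
    diag = goodness_of_fit(sub, refined, low_res=low_res)
    return refined, diag
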