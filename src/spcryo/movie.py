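"""Whole-frame movie motion correction and exposure-weighted summation.

Each frame is aligned by cross-correlation against the sum of all other
frames, iterating until the trajectory stops changing; per-iteration
trajectories are smoothed with a Savitzky-Golay filter to suppress spurious
translations.  The final average applies the measured shifts as Fourier
phase ramps and can weight each frame with the published critical-exposure
dose attenuation, restoring per-frequency power after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as _fft
from scipy.signal import savgol_filter

from .image import Image, freq_grids, freq_magnitude


@dataclass
class MovieStack:
    """Stack of equally-sized frames with exposure bookkeeping (e⁻/Å²)."""

    frames: np.ndarray              # (n_frames, box, box)
    pixel_size: float
    exposure_per_frame: float = 1.0
    pre_exposure: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 3:
            raise ValueError("movie needs >= 3 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite pixels in movie")
        if self.exposure_per_frame < 0 or self.pre_exposure < 0:
            raise ValueError("exposures must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def accumulated_exposure(self) -> np.ndarray:
        """Exposure at the (temporal) midpoint of each frame."""
        i = np.arange(self.n_frames)
        return self.pre_exposure + (i + 0.5) * self.exposure_per_frame


@dataclass
class Trajectory:
    """Per-frame (x, y) shifts in Å, gauge-fixed to zero mean."""

    shifts: np.ndarray              # (n_frames, 2)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)

    def gauge_fixed(self) -> "Trajectory":
        return Trajectory(self.shifts - self.shifts.mean(axis=0))


def _parabolic_peak(cc: np.ndarray):
    """Integer argmax of a CC map plus parabolic sub-pixel interpolation."""
    n = cc.shape[0]
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)

    def refine(axis_idx, take):
        c = take(axis_idx)
        m = take((axis_idx - 1) % n)
        p = take((axis_idx + 1) % n)
        denom = m - 2 * c + p
        return 0.0 if denom == 0 else 0.5 * (m - p) / denom

    dy = refine(iy, lambda k: cc[k % n, ix])
    dx = refine(ix, lambda k: cc[iy, k % n])
    # wrap to signed offsets
    sy = iy if iy <= n // 2 else iy - n
    sx = ix if ix <= n // 2 else ix - n
    return sy + dy, sx + dx


def _phase_ramp(box: int, pixel_size: float, sx: float, sy: float) -> np.ndarray:
    gy, gx = freq_grids(box, pixel_size, 2)   # axis0=y, axis1=x
    return np.exp(-2j * np.pi * (gx * sx + gy * sy))


def align_movie(movie: MovieStack, max_iterations: int = 10,
                min_shift_change: float = 0.1,
                smoothing_window: int = None, smoothing_order: int = 3,
                bfactor: float = 1500.0) -> Trajectory:
    """Iterative leave-one-out frame alignment.

    ``min_shift_change`` (Å) is the convergence criterion on the largest
    per-frame shift update; ``bfactor`` (Å²) damps high-frequency noise in
    the correlation maps.  The returned trajectory has zero mean shift.
    """
    n = movie.n_frames
    box = movie.frames.shape[1]
    px = movie.pixel_size
    if smoothing_window is None:
        smoothing_window = min(7, n if n % 2 == 1 else n - 1)
    smoothing_window = max(smoothing_window, smoothing_order + 1)
    if smoothing_window % 2 == 0:
        smoothing_window += 1
    F = np.array([_fft.fft2(f - f.mean()) for f in movie.frames])
    g2 = freq_magnitude(box, px, 2) ** 2
    damp = np.exp(-bfactor * g2 / 4.0)
    shifts = np.zeros((n, 2))     # (x, y) in Å
    for _ in range(max_iterations):
        aligned = np.array([F[i] * _phase_ramp(box, px, -shifts[i, 0],
                                               -shifts[i, 1])
                            for i in range(n)])
        total = aligned.sum(axis=0)
        new_shifts = shifts.copy()
        for i in range(n):
            ref = total - aligned[i]
            cc = _fft.ifft2(ref * np.conj(aligned[i]) * damp).real
            dy, dx = _parabolic_peak(cc)
            # peak offset is the *residual* motion of frame i vs reference
            new_shifts[i, 0] = shifts[i, 0] - dx * px
            new_shifts[i, 1] = shifts[i, 1] - dy * px
        if smoothing_window <= n:
            for ax in range(2):
                new_shifts[:, ax] = savgol_filter(
                    new_shifts[:, ax], smoothing_window,
                    min(smoothing_order, smoothing_window - 1))
        change = np.max(np.abs(new_shifts - shifts))
        shifts = new_shifts
        if change < min_shift_change:
            break
    return Trajectory(shifts).gauge_fixed()


def critical_exposure(g: np.ndarray, a: float = 0.245, b: float = -1.665,
                      c: float = 2.81) -> np.ndarray:
    """Critical exposure Nc(g) = a·g^b + c (g in Å⁻¹, Nc in e⁻/Å²)."""
    g = np.asarray(g, dtype=np.float64)
    out = np.full_like(g, np.inf)
    nz = g > 0
    out[nz] = a * np.power(g[nz], b) + c
    return out


def exposure_weights(movie: MovieStack, g: np.ndarray) -> np.ndarray:
    """Per-frame, per-frequency dose attenuation exp(-d / (2 Nc(g)))."""
    nc = critical_exposure(g)
    d = movie.accumulated_exposure()
    return np.exp(-d[:, None, None] / (2.0 * nc[None]))


def exposure_filtered_sum(movie: MovieStack, trajectory: Trajectory,
                          apply_exposure_filter: bool = True) -> Image:
    """Shift frames per the trajectory and sum, optionally dose-weighted.

    With filtering on, each frame's Fourier amplitudes are attenuated
    according to its accumulated exposure and the sum is re-normalized per
    frequency (×√(n / Σw²)) so the filtered signal power matches an
    unfiltered sum of aligned frames.
    """
    if trajectory.shifts.shape[0] != movie.n_frames:
        raise ValueError("trajectory length does not match frame count")
    if apply_exposure_filter and movie.exposure_per_frame <= 0:
        raise ValueError("exposure filtering requested with zero exposure")
    box = movie.frames.shape[1]
    px = movie.pixel_size
    g = freq_magnitude(box, px, 2)
    if apply_exposure_filter:
        w = exposure_weights(movie, g)
    else:
        w = np.ones((movie.n_frames, box, box))
    total = np.zeros((box, box), dtype=complex)
    for i in range(movie.n_frames):
        Fi = _fft.fft2(movie.frames[i])
        Fi = Fi * _phase_ramp(box, px, -trajectory.shifts[i, 0],
                              -trajectory.shifts[i, 1])
        total += w[i] * Fi
    if apply_exposure_filter:
        norm = np.sqrt(movie.n_frames / np.maximum((w ** 2).sum(axis=0), 1e-30))
        total *= norm
    return Image(_fft.ifft2(total).real, px)
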