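"""Core image/volume containers, Fourier utilities and radial statistics.

Conventions used throughout the package
---------------------------------------
* Real-space origin is at the box centre, element ``side // 2`` along each
  axis (0-based).  ``fft2c``/``fft3c`` therefore wrap ``scipy.fft`` with an
  ``ifftshift`` so that phases refer to the box centre.
* Fourier arrays are stored in standard FFT order: the origin sits at array
  element ``(0, 0)`` and frequencies follow ``scipy.fft.fftfreq``.
* All spatial frequencies are expressed in Å⁻¹; a Fourier shell has width
  ``1 / (side * pixel_size)``.
* FFT normalisation: forward unscaled, inverse ``1/N`` (numpy's default
  "backward" convention).  Parseval then reads
  ``sum |x|² = sum |X|² / N``.
* Euler angles are Z-Y-Z intrinsic ``(phi, theta, psi)`` in degrees; the
  projection direction is the rotated z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as _fft


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

def _check_square(arr: np.ndarray, ndim: int) -> None:
    if arr.ndim != ndim:
        raise ValueError(f"expected {ndim}-D array, got {arr.ndim}-D")
    if len(set(arr.shape)) != 1:
        raise ValueError(f"box must be square/cubic, got shape {arr.shape}")
    if arr.shape[0] % 2 != 0:
        raise ValueError(f"box side must be even, got {arr.shape[0]}")


@dataclass
class Image:
    """A 2-D real-space image with a physical pixel size in Å/pixel."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        _check_square(self.pixels, 2)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def box(self) -> int:
        return self.pixels.shape[0]

    @property
    def box_angstrom(self) -> float:
        return self.box * self.pixel_size

    def copy(self) -> "Image":
        return Image(self.pixels.copy(), self.pixel_size)


@dataclass
class Volume:
    """A 3-D real-space map with a physical voxel size in Å/voxel."""

    voxels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        _check_square(self.voxels, 3)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def box(self) -> int:
        return self.voxels.shape[0]

    def copy(self) -> "Volume":
        return Volume(self.voxels.copy(), self.pixel_size)


@dataclass
class RadialProfile:
    """Radially averaged quantity versus spatial frequency (Å⁻¹)."""

    bin_centers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin_centers and values must match")
        if len(self.bin_centers) > 1 and np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")

    def interp(self, g: np.ndarray) -> np.ndarray:
        """Linear interpolation (constant extrapolation) at frequencies g."""
        return np.interp(g, self.bin_centers, self.values)


@dataclass
class SoftMask:
    """Specification of a soft-edged mask with cosine falloff.

    ``kind`` is one of ``"spherical"``, ``"circular"`` (2-D) or
    ``"custom"`` (caller supplies a volume elsewhere).  ``radius`` and
    ``falloff_width`` are in Å; ``center`` is in Å relative to the box
    centre.
    """

    kind: str = "spherical"
    radius: float = 0.0
    falloff_width: float = 0.0
    center: tuple = field(default_factory=lambda: (0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("mask radius must be positive")
        if self.falloff_width < 0:
            raise ValueError("falloff width must be non-negative")


# --------------------------------------------------------------------------
# FFT plumbing
# --------------------------------------------------------------------------

def _require_even(arr: np.ndarray) -> None:
    if any(s % 2 for s in arr.shape):
        raise ValueError(f"odd box size {arr.shape} not supported")


def fft2c(arr: np.ndarray) -> np.ndarray:
    """2-D FFT with real-space origin at the box centre."""
    _require_even(arr)
    return _fft.fft2(_fft.ifftshift(arr))


def ifft2c(farr: np.ndarray) -> np.ndarray:
    _require_even(farr)
    return _fft.fftshift(_fft.ifft2(farr))


def fft3c(arr: np.ndarray) -> np.ndarray:
    """3-D FFT with real-space origin at the box centre."""
    _require_even(arr)
    return _fft.fftn(_fft.ifftshift(arr))


def ifft3c(farr: np.ndarray) -> np.ndarray:
    _require_even(farr)
    return _fft.fftshift(_fft.ifftn(farr))


def freq_grids(box: int, pixel_size: float, ndim: int = 2):
    """FFT-ordered frequency component grids in Å⁻¹ (one per axis)."""
    f = _fft.fftfreq(box, d=pixel_size)
    if ndim == 2:
        return np.meshgrid(f, f, indexing="ij")
    if ndim == 3:
        return np.meshgrid(f, f, f, indexing="ij")
    raise ValueError("ndim must be 2 or 3")


def freq_magnitude(box: int, pixel_size: float, ndim: int = 2) -> np.ndarray:
    grids = freq_grids(box, pixel_size, ndim)
    return np.sqrt(sum(g * g for g in grids))


def nyquist(pixel_size: float) -> float:
    return 1.0 / (2.0 * pixel_size)


# --------------------------------------------------------------------------
# radial statistics
# --------------------------------------------------------------------------

def shell_indices(box: int, pixel_size: float, ndim: int = 2) -> np.ndarray:
    """Integer shell index per Fourier element; shell width 1/(box·px)."""
    dg = 1.0 / (box * pixel_size)
    g = freq_magnitude(box, pixel_size, ndim)
    return np.rint(g / dg).astype(np.int64)


def n_shells(box: int) -> int:
    return box // 2 + 1


def radial_average(spectrum: np.ndarray, pixel_size: float) -> RadialProfile:
    """Radially average an FFT-ordered 2-D/3-D spectrum into shells.

    Complex input is averaged on its squared magnitude's parent values as
    given (the caller chooses |F|, |F|² …); each shell value is the mean
    over elements whose |g| rounds into that shell.  Empty shells carry the
    previous shell's value forward.
    """
    spectrum = np.asarray(spectrum)
    if np.iscomplexobj(spectrum):
        spectrum = np.abs(spectrum)
    box = spectrum.shape[0]
    idx = shell_indices(box, pixel_size, spectrum.ndim).ravel()
    nsh = n_shells(box)
    keep = idx < nsh
    sums = np.bincount(idx[keep], weights=spectrum.ravel()[keep], minlength=nsh)
    counts = np.bincount(idx[keep], minlength=nsh)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # forward-fill empty shells from the previous shell
    if np.isnan(values).any():
        valid = ~np.isnan(values)
        fill = np.maximum.accumulate(np.where(valid, np.arange(nsh), 0))
        values = np.where(valid, values, np.where(fill > 0, values[fill], 0.0))
        values = np.nan_to_num(values)
    dg = 1.0 / (box * pixel_size)
    centers = np.arange(nsh) * dg
    return RadialProfile(centers, values)


def radial_expand(profile: RadialProfile, box: int, pixel_size: float,
                  ndim: int = 2) -> np.ndarray:
    """Expand a radial profile back onto an FFT-ordered grid (interpolated)."""
    g = freq_magnitude(box, pixel_size, ndim)
    return profile.interp(g)


# --------------------------------------------------------------------------
# masks
# --------------------------------------------------------------------------

def radius_grid(box: int, pixel_size: float, ndim: int,
                center: tuple = None) -> np.ndarray:
    """Real-space distance (Å) from ``center`` (default: box centre)."""
    half = box // 2
    ax = (np.arange(box) - half) * pixel_size
    if center is None:
        center = (0.0,) * ndim
    grids = np.meshgrid(*[ax - c for c in center[:ndim]], indexing="ij")
    return np.sqrt(sum(g * g for g in grids))


def cosine_edge(r: np.ndarray, radius: float, falloff: float) -> np.ndarray:
    """1 inside radius − falloff, 0 outside radius, cosine ramp between.

    The half-power point (value 0.5) sits at ``radius − falloff/2``.
    """
    if falloff <= 0:
        return (r < radius).astype(np.float64)
    m = np.zeros_like(r)
    m[r <= radius - falloff] = 1.0
    ramp = (r > radius - falloff) & (r < radius)
    m[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - (radius - falloff)) / falloff))
    return m


def make_soft_mask(spec: SoftMask, box: int, pixel_size: float,
                   ndim: int = None) -> np.ndarray:
    """Realize a soft mask specification on a grid; values in [0, 1]."""
    if ndim is None:
        ndim = 2 if spec.kind == "circular" else 3
    if spec.radius > box * pixel_size / 2 + 1e-9:
        raise ValueError("mask radius + falloff must fit in the box")
    r = radius_grid(box, pixel_size, ndim, spec.center)
    return cosine_edge(r, spec.radius, spec.falloff_width)


def lowpass_filter(arr: np.ndarray, pixel_size: float, resolution: float,
                   falloff_shells: float = 2.0) -> np.ndarray:
    """Cosine-edged low-pass at ``resolution`` Å on a real array."""
    box = arr.shape[0]
    g = freq_magnitude(box, pixel_size, arr.ndim)
    dg = 1.0 / (box * pixel_size)
    cutoff = 1.0 / resolution
    filt = cosine_edge(g, cutoff + falloff_shells * dg, falloff_shells * dg)
    fwd = fft3c if arr.ndim == 3 else fft2c
    inv = ifft3c if arr.ndim == 3 else ifft2c
    return inv(fwd(arr) * filt).real


def highpass_filter(arr: np.ndarray, pixel_size: float, resolution: float,
                    falloff_shells: float = 2.0) -> np.ndarray:
    """Cosine-edged high-pass removing structure lower-resolution than ``resolution`` Å."""
    return arr - lowpass_filter(arr, pixel_size, resolution, falloff_shells)


def resolution_limit_mask(box: int, pixel_size: float, resolution: float,
                          ndim: int = 2) -> np.ndarray:
    """Hard Fourier mask keeping |g| ≤ 1/resolution (FFT order)."""
    g = freq_magnitude(box, pixel_size, ndim)
    return (g <= 1.0 / resolution).astype(np.float64)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def _centered_crop_indices(n_in: int, n_out: int) -> np.ndarray:
    """Indices of the centered n_out-wide Fourier window in FFT order."""
    half = n_out // 2
    return np.concatenate([np.arange(0, half), np.arange(n_in - half, n_in)])


def fourier_crop(obj, target_pixel_size: float):
    """Resample an Image/Volume to a coarser pixel size by Fourier cropping.

    The output box is the even size closest to
    ``box * pixel_size / target_pixel_size``; the resulting pixel size is
    within one Fourier pixel of the request.  The image mean is preserved.
    """
    if target_pixel_size < obj.pixel_size - 1e-9:
        raise ValueError("fourier_crop cannot upsample; target pixel size "
                         "must be >= source pixel size")
    is_vol = isinstance(obj, Volume)
    arr = obj.voxels if is_vol else obj.pixels
    box = arr.shape[0]
    extent = box * obj.pixel_size
    n_out = int(round(extent / target_pixel_size / 2)) * 2
    n_out = max(2, min(n_out, box))
    if n_out == box:
        return obj.copy()
    F = fft3c(arr) if is_vol else fft2c(arr)
    idx = _centered_crop_indices(box, n_out)
    if is_vol:
        F = F[np.ix_(idx, idx, idx)]
    else:
        F = F[np.ix_(idx, idx)]
    # rescale so the DC term yields the same real-space mean
    F = F * (n_out / box) ** arr.ndim
    out = (ifft3c(F) if is_vol else ifft2c(F)).real
    new_pixel = extent / n_out
    return Volume(out, new_pixel) if is_vol else Image(out, new_pixel)


def fourier_pad(obj, target_box: int):
    """Zero-pad the Fourier transform to ``target_box`` (upsampling)."""
    is_vol = isinstance(obj, Volume)
    arr = obj.voxels if is_vol else obj.pixels
    box = arr.shape[0]
    if target_box < box:
        raise ValueError("target_box smaller than source; use fourier_crop")
    if target_box == box:
        return obj.copy()
    F = fft3c(arr) if is_vol else fft2c(arr)
    shape = (target_box,) * arr.ndim
    out = np.zeros(shape, dtype=complex)
    idx = _centered_crop_indices(target_box, box)
    if is_vol:
        out[np.ix_(idx, idx, idx)] = F
    else:
        out[np.ix_(idx, idx)] = F
    out *= (target_box / box) ** arr.ndim
    res = (ifft3c(out) if is_vol else ifft2c(out)).real
    new_pixel = box * obj.pixel_size / target_box
    return Volume(res, new_pixel) if is_vol else Image(res, new_pixel)


# --------------------------------------------------------------------------
# rotations / shifts
# --------------------------------------------------------------------------

def rotation_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Z-Y-Z intrinsic rotation matrix from Euler angles in degrees."""
    a, b, c = np.deg2rad([phi, theta, psi])

    def rz(t):
        return np.array([[np.cos(t), -np.sin(t), 0],
                         [np.sin(t), np.cos(t), 0],
                         [0, 0, 1.0]])

    def ry(t):
        return np.array([[np.cos(t), 0, np.sin(t)],
                         [0, 1.0, 0],
                         [-np.sin(t), 0, np.cos(t)]])

    return rz(a) @ ry(b) @ rz(c)


def shift_image_fourier(F: np.ndarray, shift_x: float, shift_y: float,
                        pixel_size: float) -> np.ndarray:
    """Apply a real-space shift (Å) to an FFT-ordered 2-D transform.

    Positive shifts move the image content toward larger coordinates.
    """
    box = F.shape[0]
    gy, gx = freq_grids(box, pixel_size, 2)   # axis 0 = y, axis 1 = x
    phase = np.exp(-2j * np.pi * (gx * shift_x + gy * shift_y))
    return F * phase


def rotate_image(img: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Rotate a 2-D image about the box centre (degrees).

    A positive angle moves content at +x toward −y; this matches the
    in-plane Euler angle: the projection at (phi, theta, psi) equals the
    (phi, theta, 0) projection rotated by +psi.
    """
    from scipy import ndimage
    half = img.shape[0] // 2
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    # map output coords -> input coords: inverse rotation about the centre
    offset = np.array([half, half]) - rot.T @ np.array([half, half])
    return ndimage.affine_transform(img, rot.T, offset=offset, order=order,
                                    mode="constant", cval=float(np.mean(img)))
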