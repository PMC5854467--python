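"""Central-slice projection and its adjoint (Fourier insertion).

By the projection-slice theorem, the 2-D transform of a projection along
the rotated z axis equals the central section of the 3-D transform on the
plane perpendicular to that axis.  Slices are extracted with trilinear
interpolation from the (optionally 2x zero-padded) volume transform;
insertion spreads each 2-D sample onto its 8 neighbouring 3-D grid points
with the same trilinear weights, so extraction and insertion form an
adjoint pair.

Axis bookkeeping: images are (y, x), volumes (z, y, x); rotation matrices
act on (x, y, z) column vectors.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _fft
from scipy import ndimage

from .image import Image, Volume, fft3c, ifft2c, rotation_matrix


def _slice_coords(box_out: int, rotation: np.ndarray):
    """3-D Fourier coordinates (in output-grid Fourier pixels, x/y/z) of the
    central slice for a 2-D FFT-ordered output grid."""
    f = _fft.fftfreq(box_out) * box_out      # integer-ish freq indices
    ky, kx = np.meshgrid(f, f, indexing="ij")
    kz = np.zeros_like(kx)
    k2 = np.stack([kx.ravel(), ky.ravel(), kz.ravel()])
    return rotation @ k2                      # (3, box_out^2), rows x,y,z


class FourierProjector:
    """Precomputed 3-D transform of a reference for fast slice extraction."""

    def __init__(self, volume: Volume, pad: int = 2):
        self.box = volume.box
        self.pixel_size = volume.pixel_size
        self.pad = int(pad)
        if self.pad > 1:
            # real-space zero-padding: finer Fourier sampling, so trilinear
            # interpolation between slice samples is more accurate
            big = self.box * self.pad
            lo = big // 2 - self.box // 2
            padded = np.zeros((big,) * 3)
            padded[lo:lo + self.box, lo:lo + self.box,
                   lo:lo + self.box] = volume.voxels
        else:
            padded = volume.voxels
        F = fft3c(padded)
        # centered order so interpolation coordinates are contiguous
        self.F = _fft.fftshift(F)
        self.center = (self.box * self.pad) // 2

    def project_ft(self, phi: float = 0.0, theta: float = 0.0,
                   psi: float = 0.0, rotation: np.ndarray = None) -> np.ndarray:
        """FFT-ordered 2-D transform of the projection at Euler angles
        (or at an explicit rotation matrix)."""
        R = rotation_matrix(phi, theta, psi) if rotation is None else rotation
        k = _slice_coords(self.box, R) * self.pad
        # array order (z, y, x)
        coords = np.stack([k[2] + self.center, k[1] + self.center,
                           k[0] + self.center])
        re = ndimage.map_coordinates(self.F.real, coords, order=1,
                                     mode="constant", cval=0.0)
        im = ndimage.map_coordinates(self.F.imag, coords, order=1,
                                     mode="constant", cval=0.0)
        # centered real-space padding leaves values at matching physical
        # frequencies unchanged, so no rescaling is needed
        return (re + 1j * im).reshape(self.box, self.box)

    def project(self, phi: float, theta: float, psi: float) -> Image:
        """Real-space projection image at the given Euler angles."""
        return Image(ifft2c(self.project_ft(phi, theta, psi)).real,
                     self.pixel_size)


def insert_slice(numerator: np.ndarray, denominator: np.ndarray,
                 slice_values: np.ndarray, slice_weights: np.ndarray,
                 phi: float, theta: float, psi: float) -> None:
    """Spread one 2-D slice into centered 3-D accumulators (in place).

    ``numerator``/``denominator`` are fftshift-centered cubes of side N;
    ``slice_values`` (complex) and ``slice_weights`` (real) are FFT-ordered
    N x N grids.  Trilinear spreading mirrors the extraction kernel.
    """
    n = numerator.shape[0]
    center = n // 2
    R = rotation_matrix(phi, theta, psi)
    k = _slice_coords(slice_values.shape[0], R)
    coords = np.stack([k[2] + center, k[1] + center, k[0] + center])
    base = np.floor(coords).astype(np.int64)
    frac = coords - base
    vals = slice_values.ravel()
    wts = slice_weights.ravel()
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (np.where(dz, frac[0], 1 - frac[0])
                     * np.where(dy, frac[1], 1 - frac[1])
                     * np.where(dx, frac[2], 1 - frac[2]))
                iz = base[0] + dz
                iy = base[1] + dy
                ix = base[2] + dx
                ok = ((iz >= 0) & (iz < n) & (iy >= 0) & (iy < n)
                      & (ix >= 0) & (ix < n) & (w > 0))
                flat = (iz[ok] * n + iy[ok]) * n + ix[ok]
                np.add.at(numerator.ravel(), flat, vals[ok] * w[ok])
                np.add.at(denominator.ravel(), flat, wts[ok] * w[ok])


def rotate_volume(volume: Volume, rotation: np.ndarray,
                  order: int = 1) -> Volume:
    """Rotate a volume about its centre: out(r) = in(R r)."""
    box = volume.box
    half = box // 2
    R = rotation
    P = np.array([[R[2, 2], R[2, 1], R[2, 0]],
                  [R[1, 2], R[1, 1], R[1, 0]],
                  [R[0, 2], R[0, 1], R[0, 0]]])
    c = np.array([half, half, half])
    offset = c - P @ c
    out = ndimage.affine_transform(volume.voxels, P, offset=offset,
                                   order=order, mode="constant", cval=0.0)
    return Volume(out, volume.pixel_size)


def align_volumes(moving: Volume, fixed: Volume, coarse_step: float = 20.0,
                  allow_flip: bool = True):
    """Find the rotation (and optional hand flip) best matching two maps.

    Ab-initio reconstructions emerge in an arbitrary global orientation
    and with an undetermined hand, so any comparison against a reference
    map must first search over global rotations.  Coarse Euler grid
    followed by simplex refinement of the real-space correlation.
    Returns ``(aligned_moving, correlation, flipped)``.
    """
    from scipy import optimize
    from .refine3d import euler_grid   # local import avoids a cycle

    f = fixed.voxels - fixed.voxels.mean()
    fn = np.sqrt((f * f).sum())

    def corr(vol_arr):
        m = vol_arr - vol_arr.mean()
        denom = np.sqrt((m * m).sum()) * fn
        return float((m * f).sum() / denom) if denom > 0 else 0.0

    candidates = [moving]
    if allow_flip:
        candidates.append(Volume(moving.voxels[::-1].copy(),
                                 moving.pixel_size))
    best = (-np.inf, None, False, None)
    for flip_idx, cand in enumerate(candidates):
        grid = euler_grid(coarse_step, psi_step=coarse_step)
        for phi, theta, psi in grid:
            R = rotation_matrix(phi, theta, psi)
            c = corr(rotate_volume(cand, R, order=1).voxels)
            if c > best[0]:
                best = (c, (phi, theta, psi), bool(flip_idx), cand)

        def cost(x, cand=cand):
            return -corr(rotate_volume(cand, rotation_matrix(*x),
                                       order=1).voxels)
    c0, e0, flipped, cand = best
    res = optimize.minimize(lambda x: -corr(
        rotate_volume(cand, rotation_matrix(*x), order=1).voxels),
        np.array(e0), method="Nelder-Mead",
        options={"maxfev": 150, "xatol": 0.5, "fatol": 1e-5})
    R = rotation_matrix(*res.x)
    aligned = rotate_volume(cand, R, order=3)
    return aligned, float(-res.fun), flipped


def project_real_space(volume: Volume, phi: float, theta: float,
                       psi: float, order: int = 3) -> Image:
    """Slow real-space projection (rotate voxels, sum along z).

    Provided as an independent route for cross-checks; the refinement and
    reconstruction paths use the Fourier-slice operators above.
    """
    box = volume.box
    half = box // 2
    R = rotation_matrix(phi, theta, psi)
    # sample V at R r for output coords r; array axes are (z, y, x)
    P = np.array([[R[2, 2], R[2, 1], R[2, 0]],
                  [R[1, 2], R[1, 1], R[1, 0]],
                  [R[0, 2], R[0, 1], R[0, 0]]])
    c = np.array([half, half, half])
    offset = c - P @ c
    rotated = ndimage.affine_transform(volume.voxels, P, offset=offset,
                                       order=order, mode="constant", cval=0.0)
    return Image(rotated.sum(axis=0), volume.pixel_size)
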