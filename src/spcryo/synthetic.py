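"""Ground-truth generators: phantoms, particle stacks, micrographs, movies.

Every generator is deterministic under a fixed seed and returns complete
ground truth (orientations, shifts, defoci, class labels, positions) for
the data it fabricates.  Phantoms are sums of 3-D Gaussian blobs, so their
projections have a closed form; the particle simulator uses that closed
form rather than the package's Fourier-slice projector, keeping the two
code paths independent for cross-checking.

SNR is defined as the ratio of signal variance to noise variance measured
inside the particle mask, after CTF application.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft as _fft

from .ctf import CTFParams, ctf_grid
from .image import (Image, Volume, fft2c, ifft2c, radius_grid,
                    rotation_matrix, shift_image_fourier)


@dataclass
class Phantom:
    """A sum of 3-D Gaussian blobs with optional Cn symmetry about z.

    ``blobs`` rows are ``(cx, cy, cz, sigma, amplitude)`` in Å relative to
    the box centre.  ``volume()`` realizes the density on a voxel grid.
    """

    blobs: np.ndarray               # (n_blobs, 5)
    box: int
    pixel_size: float
    symmetry: str = "C1"

    def __post_init__(self) -> None:
        self.blobs = np.atleast_2d(np.asarray(self.blobs, dtype=np.float64))
        half_extent = 0.4 * self.box * self.pixel_size
        r = np.linalg.norm(self.blobs[:, :3], axis=1)
        if np.any(r > half_extent):
            raise ValueError("phantom primitive outside 0.8x box")

    @property
    def symmetry_order(self) -> int:
        if self.symmetry.upper().startswith("C"):
            return int(self.symmetry[1:])
        raise ValueError(f"unsupported point group {self.symmetry}")

    def replicated_blobs(self) -> np.ndarray:
        """All blobs after applying the point-group replication."""
        order = self.symmetry_order
        if order == 1:
            return self.blobs
        out = []
        for k in range(order):
            R = rotation_matrix(360.0 * k / order, 0.0, 0.0)
            for cx, cy, cz, s, a in self.blobs:
                c = R @ np.array([cx, cy, cz])
                out.append([c[0], c[1], c[2], s, a])
        return np.array(out)

    def volume(self) -> Volume:
        box, px = self.box, self.pixel_size
        ax = (np.arange(box) - box // 2) * px
        # voxel grid indexed (z, y, x) to match MRC section order
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        vol = np.zeros((box, box, box))
        for cx, cy, cz, s, a in self.replicated_blobs():
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
            vol += a * np.exp(-d2 / (2.0 * s * s))
        return Volume(vol, px)

    def diameter(self) -> float:
        """Approximate particle diameter (Å): blob extent + 3 sigma."""
        b = self.replicated_blobs()
        r = np.linalg.norm(b[:, :3], axis=1) + 3.0 * b[:, 3]
        return 2.0 * float(r.max())

    def analytic_projection(self, box: int, pixel_size: float,
                            phi: float, theta: float, psi: float,
                            shift_x: float = 0.0, shift_y: float = 0.0) -> np.ndarray:
        """Closed-form projection along the rotated z axis.

        Matches the voxel-sum convention of a discrete projection: the
        integral over z contributes a factor ``sigma * sqrt(2 pi) /
        pixel_size``.  Image axes are (y, x); shifts in Å move the particle
        toward larger coordinates.
        """
        R = rotation_matrix(phi, theta, psi)
        ax = (np.arange(box) - box // 2) * pixel_size
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        img = np.zeros((box, box))
        for cx, cy, cz, s, a in self.replicated_blobs():
            c = R.T @ np.array([cx, cy, cz])
            amp = a * s * np.sqrt(2.0 * np.pi) / pixel_size
            d2 = (xx - (c[0] + shift_x)) ** 2 + (yy - (c[1] + shift_y)) ** 2
            img += amp * np.exp(-d2 / (2.0 * s * s))
        return img


def make_phantom(box: int = 48, pixel_size: float = 3.0,
                 diameter: float = 120.0, n_lobes: int = 5, n_fine: int = 50,
                 symmetry: str = "C1", seed: int = 0) -> Phantom:
    """Random protein-like phantom.

    Two scales of structure mimic a globular protein: a few large lobes
    (sigma 8 Å) provide the low-resolution shape that drives alignment,
    and many fine blobs (sigma ~2 Å, clustered inside the lobes) provide
    secondary-structure-scale contrast so that reconstructions carry
    meaningful signal out toward Nyquist.
    """
    rng = np.random.default_rng(seed)
    r_lobe = diameter / 2.0 - 25.0
    r_max = diameter / 2.0 - 12.0
    blobs = []
    lobes = []
    for _ in range(n_lobes):
        c = rng.normal(scale=r_lobe / 2.0, size=3)
        if np.linalg.norm(c) > r_lobe:
            c *= r_lobe / np.linalg.norm(c)
        lobes.append(c)
        blobs.append([*c, 8.0, 0.4])
    for _ in range(n_fine):
        L = lobes[rng.integers(n_lobes)]
        c = L + rng.normal(scale=7.0, size=3)
        if np.linalg.norm(c) > r_max:
            c *= r_max / np.linalg.norm(c)
        blobs.append([*c, rng.uniform(1.6, 2.4), rng.uniform(2.5, 4.5)])
    return Phantom(np.array(blobs), box, pixel_size, symmetry)


def make_two_state_phantom(box: int = 64, pixel_size: float = 3.0,
                           seed: int = 0):
    """Two conformations sharing a core, differing in one moved subunit.

    Returns ``(phantom_a, phantom_b, subunit_center)`` where the subunit
    centre (state A, Å) locates the variable region for focused masks.
    """
    rng = np.random.default_rng(seed)
    core = []
    centers = []
    for _ in range(3):
        c = rng.normal(scale=14.0, size=3)
        if np.linalg.norm(c) > 28.0:
            c *= 28.0 / np.linalg.norm(c)
        centers.append(c)
        core.append([*c, 8.0, 0.5])
    for _ in range(24):
        c = centers[rng.integers(3)] + rng.normal(scale=6.0, size=3)
        if np.linalg.norm(c) > 40.0:
            c *= 40.0 / np.linalg.norm(c)
        core.append([*c, rng.uniform(1.8, 2.6), rng.uniform(2.0, 4.0)])
    ca = np.array([36.0, 0.0, 0.0])
    cb = np.array([0.0, 36.0, 0.0])
    sub_fine = rng.normal(scale=5.0, size=(8, 3))
    sub_sigma = rng.uniform(1.8, 2.6, size=8)
    sub_amp = rng.uniform(2.5, 4.5, size=8)

    def subunit(center):
        rows = [[*center, 8.0, 0.6]]
        for k in range(8):
            rows.append([*(center + sub_fine[k]), sub_sigma[k], sub_amp[k]])
        return rows

    a = Phantom(np.array(core + subunit(ca)), box, pixel_size)
    b = Phantom(np.array(core + subunit(cb)), box, pixel_size)
    return a, b, ca


# --------------------------------------------------------------------------
# particle stacks
# --------------------------------------------------------------------------

def random_eulers(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform orientations: phi, psi ~ U(0,360), cos(theta) ~ U(-1,1)."""
    phi = rng.uniform(0, 360, n)
    psi = rng.uniform(0, 360, n)
    theta = np.rad2deg(np.arccos(rng.uniform(-1, 1, n)))
    return np.column_stack([phi, theta, psi])


def simulate_particles(phantom: Phantom, n: int, snr: float = 0.1,
                       box: int = None, pixel_size: float = None,
                       defocus_range=(8000.0, 20000.0),
                       shift_sigma: float = 0.0,
                       eulers: np.ndarray = None,
                       ctf_template: CTFParams = None,
                       apply_ctf: bool = True, seed: int = 0):
    """Simulate a particle stack with known ground truth.

    Returns ``(stack, truth)``; ``truth`` is a DataFrame with columns
    phi/theta/psi/shift_x/shift_y/defocus/class/sigma_noise.  ``snr`` may
    be ``np.inf`` for noiseless particles.
    """
    rng = np.random.default_rng(seed)
    box = box or phantom.box
    pixel_size = pixel_size or phantom.pixel_size
    if eulers is None:
        eulers = random_eulers(n, rng)
    shifts = rng.normal(scale=shift_sigma, size=(n, 2)) if shift_sigma > 0 \
        else np.zeros((n, 2))
    defoci = rng.uniform(*defocus_range, size=n)
    if ctf_template is None:
        ctf_template = CTFParams(15000.0, 15000.0, pixel_size=pixel_size)
    mask_r = phantom.diameter() / 2.0
    r = radius_grid(box, pixel_size, 2)
    inside = r < mask_r
    stack = np.empty((n, box, box))
    sigmas = np.empty(n)
    for i in range(n):
        img = phantom.analytic_projection(box, pixel_size, *eulers[i],
                                          shift_x=shifts[i, 0],
                                          shift_y=shifts[i, 1])
        if apply_ctf:
            p = CTFParams(defoci[i], defoci[i],
                          voltage=ctf_template.voltage, cs=ctf_template.cs,
                          amplitude_contrast=ctf_template.amplitude_contrast,
                          pixel_size=pixel_size)
            img = ifft2c(fft2c(img) * ctf_grid(p, box, pixel_size)).real
        sig_var = img[inside].var()
        if np.isfinite(snr) and snr > 0:
            noise_sd = np.sqrt(sig_var / snr)
            img = img + rng.normal(scale=noise_sd, size=img.shape)
        else:
            noise_sd = 0.0
        stack[i] = img
        sigmas[i] = noise_sd
    truth = pd.DataFrame({
        "phi": eulers[:, 0], "theta": eulers[:, 1], "psi": eulers[:, 2],
        "shift_x": shifts[:, 0], "shift_y": shifts[:, 1],
        "defocus": defoci, "class": np.zeros(n, dtype=int),
        "sigma_noise": sigmas,
    })
    return stack, truth


# --------------------------------------------------------------------------
# micrographs
# --------------------------------------------------------------------------

def simulate_micrograph(phantom: Phantom, n_particles: int,
                        micrograph_box: int = 512, pixel_size: float = 5.0,
                        snr: float = 0.1, ctf: CTFParams = None,
                        ice_blobs: int = 0, min_distance: float = None,
                        noise_sd: float = 1.0, solvent_scale: float = 0.5,
                        seed: int = 0):
    """Synthetic micrograph with particles at known positions.

    Returns ``(Image, coords, truth)`` where ``coords`` is an (n, 2) array
    of (x, y) particle centres in Å measured from pixel (0, 0).  Optional
    ``ice_blobs`` adds high-variance, offset-mean patches that a local
    mean/variance exclusion mask must reject.
    """
    rng = np.random.default_rng(seed)
    if min_distance is None:
        min_distance = phantom.diameter()
    box_A = micrograph_box * pixel_size
    margin = phantom.diameter() / 2.0 + 2 * pixel_size
    coords = []
    for _ in range(20000):
        if len(coords) == n_particles:
            break
        c = rng.uniform(margin, box_A - margin, size=2)
        if all(np.hypot(c[0] - q[0], c[1] - q[1]) >= min_distance
               for q in coords):
            coords.append(c)
    if len(coords) < n_particles:
        raise ValueError("impossible packing: could not place all particles")
    coords = np.array(coords) if coords else np.zeros((0, 2))
    pbox = int(2 ** np.ceil(np.log2(max(
        32, 2 * phantom.diameter() / pixel_size))))
    micro = np.zeros((micrograph_box, micrograph_box))
    eulers = random_eulers(n_particles, rng)
    for i, (cx, cy) in enumerate(coords):
        proj = phantom.analytic_projection(pbox, pixel_size, *eulers[i])
        if ctf is not None:
            proj = ifft2c(fft2c(proj) * ctf_grid(ctf, pbox, pixel_size)).real
        ix, iy = int(round(cx / pixel_size)), int(round(cy / pixel_size))
        y0, x0 = iy - pbox // 2, ix - pbox // 2
        ys, xs = slice(max(0, y0), min(micrograph_box, y0 + pbox)), \
            slice(max(0, x0), min(micrograph_box, x0 + pbox))
        py = slice(ys.start - y0, ys.stop - y0)
        pxs = slice(xs.start - x0, xs.stop - x0)
        micro[ys, xs] += proj[py, pxs]
    if n_particles > 0 and np.isfinite(snr) and snr > 0:
        sig_var = micro[micro != 0].var() if np.any(micro != 0) else 1.0
        noise_sd = float(np.sqrt(sig_var / snr))
    # ice thickness varies across the field, modulating both the shot
    # noise level and the solvent granularity below
    from .image import lowpass_filter
    thick = lowpass_filter(rng.normal(size=micro.shape), pixel_size,
                           80.0 * pixel_size)
    thick = 1.0 + 0.15 * thick / max(thick.std(), 1e-12)
    micro += rng.normal(scale=noise_sd, size=micro.shape) * thick
    # structured background: solvent/ice granularity in the 30-200 A band
    # with slowly varying strength, as real micrographs show.  Without it
    # the local-variance histogram is unrealistically narrow and any
    # particle trips the abnormal-area thresholds.
    gran = lowpass_filter(rng.normal(size=micro.shape), pixel_size, 50.0)
    gran = gran - lowpass_filter(gran, pixel_size, 250.0)
    gran /= max(gran.std(), 1e-12)
    micro += solvent_scale * noise_sd * gran * thick
    ice_coords = []
    for _ in range(ice_blobs):
        c = rng.uniform(margin, box_A - margin, size=2)
        rad = rng.uniform(3, 6) * phantom.diameter() / 2.0
        rpix = int(rad / pixel_size)
        iy, ix = int(c[1] / pixel_size), int(c[0] / pixel_size)
        ys = slice(max(0, iy - rpix), min(micrograph_box, iy + rpix))
        xs = slice(max(0, ix - rpix), min(micrograph_box, ix + rpix))
        micro[ys, xs] += rng.normal(scale=6.0 * noise_sd,
                                    size=(ys.stop - ys.start,
                                          xs.stop - xs.start))
        micro[ys, xs] += 8.0 * noise_sd
        ice_coords.append(c)
    truth = pd.DataFrame({
        "x": coords[:, 0] if len(coords) else [],
        "y": coords[:, 1] if len(coords) else [],
        "phi": eulers[:, 0], "theta": eulers[:, 1], "psi": eulers[:, 2],
    })
    truth.attrs["ice_coords"] = ice_coords
    return Image(micro, pixel_size), coords, truth


# --------------------------------------------------------------------------
# movies
# --------------------------------------------------------------------------

def simulate_movie(image: Image, n_frames: int = 12,
                   drift_amplitude: float = 6.0, noise_sd: float = None,
                   snr: float = 0.1, exposure_per_frame: float = 1.0,
                   seed: int = 0):
    """Split an image into drifting, noisy frames with known trajectory.

    The drift follows a smooth decelerating curve (fast early motion, as
    beam-induced motion behaves); per-frame noise is independent white
    Gaussian scaled so each frame has the requested SNR.  Returns
    ``(MovieStack, true_trajectory)``.
    """
    from .movie import MovieStack, Trajectory
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / max(n_frames - 1, 1)
    direction = rng.uniform(0, 2 * np.pi)
    # decelerating drift plus a gentle curve
    mag = drift_amplitude * (1.0 - np.exp(-2.5 * t)) / (1.0 - np.exp(-2.5))
    sx = mag * np.cos(direction) + 0.15 * drift_amplitude * np.sin(2.5 * t)
    sy = mag * np.sin(direction) + 0.15 * drift_amplitude * np.cos(1.7 * t) \
        - 0.15 * drift_amplitude
    shifts = np.column_stack([sx, sy])
    shifts -= shifts.mean(axis=0)
    frame_signal = image.pixels / n_frames
    if noise_sd is None:
        noise_sd = float(np.sqrt(frame_signal.var() / snr))
    frames = np.empty((n_frames, image.box, image.box))
    F = fft2c(frame_signal)
    for i in range(n_frames):
        shifted = ifft2c(shift_image_fourier(
            F, shifts[i, 0], shifts[i, 1], image.pixel_size)).real
        frames[i] = shifted + rng.normal(scale=noise_sd, size=shifted.shape)
    movie = MovieStack(frames, image.pixel_size,
                       exposure_per_frame=exposure_per_frame)
    return movie, Trajectory(shifts).gauge_fixed()
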