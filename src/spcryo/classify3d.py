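"""Maximum-likelihood 3-D classification with optional focused masks.

Each particle's probability under class k is a Gaussian density of the
masked residual between the whitened image (unit pixel noise variance)
and the CTF-modulated projection of reference V_k at the particle's
current alignment, times a shift prior.  Occupancies are the posterior
over classes given per-class priors; priors are the dataset-average
occupancies.  Alignment parameters are not marginalized over.

A focused spherical mask restricts the residual to the projection of a
user-placed sphere, evaluated per particle at its orientation, so only
variability inside the sphere drives the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .ctf import CTFParams, ctf_grid
from .fourier3d import FourierProjector
from .image import (Image, cosine_edge, fft2c, ifft2c, rotation_matrix)
from .refine3d import AlignmentParams, RestraintModel, shift_restraint, \
    shift_image_fourier


@dataclass
class FocusMask:
    """Sphere (center in Å relative to the map centre, radius in Å)."""

    center: tuple
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("focus mask radius must be positive")

    def projected(self, box: int, pixel_size: float,
                  params: AlignmentParams, edge_pixels: float = 2.0) -> np.ndarray:
        """Soft 2-D mask: projection of the sphere at this orientation.

        The sphere centre follows the particle's rotation and shifts; a
        cosine edge of ~2 pixels avoids ringing.
        """
        R = rotation_matrix(*params.eulers())
        c = R.T @ np.asarray(self.center, dtype=float)
        half = box // 2
        ax = (np.arange(box) - half) * pixel_size
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        r = np.hypot(xx - (c[0] + params.shift_x),
                     yy - (c[1] + params.shift_y))
        edge = edge_pixels * pixel_size
        return cosine_edge(r, self.radius, edge)


@dataclass
class ClassState:
    """Occupancy matrix q (N x K, rows sum to 1) and class priors π."""

    q: np.ndarray
    priors: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("occupancy rows must sum to 1")
        if not np.isclose(self.priors.sum(), 1.0, atol=1e-6):
            raise ValueError("priors must sum to 1")


def log_pdf(particle: Image, params: AlignmentParams,
            projector: FourierProjector, ctf: CTFParams,
            mask_radius: float, restraint: RestraintModel = None,
            focus: FocusMask = None,
            whitening_filter: np.ndarray = None) -> float:
    """Log probability density of the whitened image given (φ, V_k).

    Residual = image − CTF·projection inside the circular particle mask
    (or the projected focus sphere); the density is Gaussian with unit
    pixel variance over the M̃ mask pixels, plus the shift-restraint
    log-prior.  Constant terms in M̃ are kept so focused and unfocused
    values are comparable only within the same mask.
    """
    box, px = particle.box, particle.pixel_size
    F_proj = projector.project_ft(*params.eulers())
    F_proj = F_proj * ctf_grid(ctf, box, px)
    if whitening_filter is not None:
        # bring the reference onto the whitened particle's scale
        F_proj = F_proj * whitening_filter
    F_proj = shift_image_fourier(F_proj, params.shift_x, params.shift_y, px)
    proj = ifft2c(F_proj).real
    if focus is not None:
        mask = focus.projected(box, px, params)
    else:
        half = box // 2
        ax = (np.arange(box) - half) * px
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        mask = cosine_edge(np.hypot(xx, yy), mask_radius, 2 * px)
    m_tilde = float(mask.sum())
    if m_tilde <= 0:
        raise ValueError("empty projected mask")
    resid = (particle.pixels - proj) ** 2 * mask
    ll = -0.5 * float(resid.sum()) - 0.5 * m_tilde * np.log(2.0 * np.pi)
    return ll + shift_restraint(params, restraint)


def update_occupancies(log_pdfs: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Posterior q_ik ∝ Γ_ik·π_k, computed stably in the log domain."""
    logp = np.asarray(log_pdfs, dtype=np.float64)
    with np.errstate(divide="ignore"):
        logpi = np.log(np.asarray(priors, dtype=np.float64))
    a = logp + logpi[None, :]
    norm = logsumexp(a, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        raise ValueError("all-zero posterior row (no supported class)")
    return np.exp(a - norm)


def update_priors(q: np.ndarray) -> np.ndarray:
    """Class priors π_k = dataset mean of q_ik (sums to 1 exactly)."""
    pi = np.asarray(q, dtype=np.float64).mean(axis=0)
    return pi / pi.sum()


def classify_3d(stack: np.ndarray, table, references, pixel_size: float,
                mask_radius: float, n_iterations: int = 5,
                focus: FocusMask = None, restraint: RestraintModel = None,
                pad: int = 2):
    """Iterate occupancy/prior updates for fixed alignments and references.

    ``references`` is a list of Volumes; alignments come from the
    parameter table (already refined).  Returns the final ClassState.
    """
    from .reconstruct3d import whiten_background
    n = stack.shape[0]
    K = len(references)
    projs = [FourierProjector(v, pad=pad) for v in references]
    priors = np.full(K, 1.0 / K)
    logp = np.empty((n, K))
    whitened = [whiten_background(Image(stack[i], pixel_size), mask_radius,
                                  return_filter=True)
                for i in range(n)]
    for i in range(n):
        row = table.iloc[i]
        p = AlignmentParams(row["phi"], row["theta"], row["psi"],
                            row["shift_x"], row["shift_y"])
        ctf = CTFParams(row["defocus1"], row["defocus2"], row["astig_angle"],
                        row["phase_shift"], pixel_size=pixel_size)
        img, gain = whitened[i]
        for k in range(K):
            logp[i, k] = log_pdf(img, p, projs[k], ctf, mask_radius,
                                 restraint, focus, whitening_filter=gain)
    q = update_occupancies(logp, priors)
    for _ in range(n_iterations - 1):
        priors = update_priors(q)
        q = update_occupancies(logp, np.maximum(priors, 1e-12))
    return ClassState(q, update_priors(q))
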