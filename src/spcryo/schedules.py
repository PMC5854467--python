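"""Ab-initio reconstruction and automatic-refinement control loops.

Ab-initio: starting from random angles, iterate global searches on random
data subsets with a resolution ramp, rebuilding and auto-masking the map
after every iteration.  Data-subset fractions ramp linearly from
2500·K/N to 10000·K/N; searches run on a 3x larger pool and keep the
highest-scoring particles.  The per-particle search result is drawn at
random from the top 15% score band of the grid to avoid premature
convergence.  Noise sigmas are reset to 1, score weighting is off, and
the PSSNR is capped by a molecular-weight-based default.

Auto-refine: the subset fraction and resolution limit follow the
estimated resolution of the previous iteration (FSC 0.5 crossing minus a
2/D_mask mask-correlation allowance), growing the subset when resolution
improves and by 1.5x otherwise, with conservative stopping rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ctf import CTFParams
from .fourier3d import FourierProjector, rotate_volume
from .image import (Image, RadialProfile, Volume, cosine_edge, fourier_crop,
                    lowpass_filter, n_shells, radius_grid, rotation_matrix)
from .reconstruct3d import (FSCCurve, compute_fsc, finalize, insert_particle,
                            mask_particle_ratio, part_fsc,
                            particle_volume_from_mass, pssnr_from_fsc,
                            reconstruct, resolution_at_threshold,
                            split_dataset)
from .refine3d import (AlignmentParams, SearchConfig, global_search_stack,
                       local_refine, rotational_search_stack,
                       score_from_objective)
from .synthetic import random_eulers


# --------------------------------------------------------------------------
# ab-initio
# --------------------------------------------------------------------------

@dataclass
class AbInitioConfig:
    """Ab-initio schedule parameters (resolutions in Å)."""

    n_particles: int
    mask_radius: float
    pixel_size: float
    iterations: int = 40
    R_start: float = 20.0
    R_finish: float = 8.0
    K: int = 1
    symmetry: str = "C1"
    apply_symmetry_mode: str = "auto"     # auto | always | never
    molecular_mass: float = 4.0e5         # Da, for the default PSSNR and f
    default_pssnr_value: float = 50.0
    angular_step_floor: float = 6.0       # degrees
    shift_search_radius: float = 10.0
    p_start: float = None      # override 2500 K / N
    p_finish: float = None     # override 10000 K / N
    bsc: float = 10.0          # score-weighting B factor (A^2)
    sigma_weight_gate_A: float = 7.0   # enable weighting below this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 2:
            raise ValueError("need at least two iterations")

    @property
    def osym(self) -> int:
        if self.symmetry.upper().startswith("C"):
            return int(self.symmetry[1:])
        raise ValueError(f"unsupported point group {self.symmetry}")


def abinitio_schedule(l: int, config: AbInitioConfig):
    """(R_l, p_l, pool fraction 3·p_l) for iteration l.

    Both ramps are linear; fractions cap at 1.  The effective particle
    count is N·Osym when symmetry is applied.
    """
    n = config.iterations
    if not 0 <= l < n:
        raise ValueError("iteration index out of range")
    R = config.R_start + l * (config.R_finish - config.R_start) / (n - 1)
    n_eff = config.n_particles * config.osym
    p_start = config.p_start if config.p_start is not None \
        else min(2500.0 * config.K / n_eff, 1.0)
    p_finish = config.p_finish if config.p_finish is not None \
        else min(10000.0 * config.K / n_eff, 1.0)
    p = min(p_start + l * (p_finish - p_start) / (n - 1), 1.0)
    return R, p, min(3.0 * p, 1.0)


def select_pool_and_keep(scores: np.ndarray, pool_indices: np.ndarray,
                         n_keep: int) -> np.ndarray:
    """Keep the highest-scoring particles of the searched pool.

    Ties break by particle index (stable sort), so results are
    deterministic.
    """
    order = np.argsort(-scores, kind="stable")
    return pool_indices[order[:n_keep]]


def randomized_global_result(scores: np.ndarray,
                             rng: np.random.Generator) -> int:
    """Uniform choice among candidates within the top 15% of the score
    range (best − 0.15·(best − worst))."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no candidates")
    hi, lo = scores.max(), scores.min()
    eligible = np.nonzero(scores >= hi - 0.15 * (hi - lo))[0]
    return int(rng.choice(eligible))


def automask(volume: Volume, mask_radius: float = None,
             lowpass_resolution: float = 50.0) -> Volume:
    """Suppress noise outside the main density blob between iterations.

    Voxels below the map mean are reset to the mean; the thresholded map
    is low-pass filtered at 50 Å and binarized at
    t = mean_filtered + 0.03·(mean of top-500 values − mean_filtered);
    everything outside the largest connected component reverts to the
    mean, and a centered soft spherical mask zeroes the exterior.
    """
    v = volume.voxels
    rho_bar = float(v.mean())
    thresholded = np.maximum(v, rho_bar)
    if np.allclose(v, rho_bar):
        return volume.copy()
    filtered = lowpass_filter(thresholded, volume.pixel_size,
                              lowpass_resolution)
    rho_filt = float(filtered.mean())
    top = np.sort(filtered.ravel())[-500:]
    t = rho_filt + 0.03 * (float(top.mean()) - rho_filt)
    binary = filtered > t
    if not binary.any():
        return volume.copy()
    labels, n_lab = ndimage.label(binary)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               np.arange(1, n_lab + 1))
    keep = (labels == (1 + int(np.argmax(sizes))))
    out = np.where(keep, thresholded, rho_bar)
    if mask_radius is None:
        mask_radius = 0.45 * volume.box * volume.pixel_size
    sph = cosine_edge(radius_grid(volume.box, volume.pixel_size, 3),
                      mask_radius, 3 * volume.pixel_size)
    return Volume(out * sph, volume.pixel_size)


def symmetrize(volume: Volume, order: int) -> Volume:
    """Average a map over its Cn rotations about z."""
    if order <= 1:
        return volume.copy()
    acc = volume.voxels.copy()
    for k in range(1, order):
        R = rotation_matrix(360.0 * k / order, 0.0, 0.0)
        acc += rotate_volume(volume, R).voxels
    return Volume(acc / order, volume.pixel_size)


def align_to_symmetry(volume: Volume, point_group: str,
                      coarse_step: float = 10.0, fine_step: float = 2.5):
    """Find the rotation that brings a map's symmetry axis onto z.

    Brute-force grid over x/y tilts: at each candidate the projection
    along (0, 0, 0) (and two fixed extra view angles for robustness) is
    cross-correlated against its symmetry-related projections and the
    peak heights are summed.  Returns ``(rotation_matrix, score)``;
    refuses C1 input.
    """
    import scipy.fft as _fft
    if not point_group.upper().startswith("C"):
        raise ValueError(f"unsupported point group {point_group}")
    order = int(point_group[1:])
    if order <= 1:
        raise ValueError("nothing to align for C1")
    proj = FourierProjector(volume, pad=1)
    test_angles = [(0.0, 0.0, 0.0), (-45.0, -45.0, -45.0), (15.0, 70.0, -15.0)]
    sym_rots = [rotation_matrix(360.0 * k / order, 0.0, 0.0)
                for k in range(1, order)]

    def score(a: float, b: float) -> float:
        Rax = _axis_rotation(a, "x") @ _axis_rotation(b, "y")
        total = 0.0
        box = volume.box
        w = box // 8
        for e in test_angles:
            Re = rotation_matrix(*e)
            F0 = proj.project_ft(rotation=Rax @ Re)
            n0 = np.sqrt((np.abs(F0) ** 2).sum())
            for Rs in sym_rots:
                Fk = proj.project_ft(rotation=Rax @ Rs @ Re)
                cc = _fft.ifft2(F0 * np.conj(Fk)).real
                nk = np.sqrt((np.abs(Fk) ** 2).sum())
                # symmetry mates of a well-centred map should register
                # with at most small shifts; a wide peak search lets
                # wrong axes fake symmetry by sliding
                windowed = np.concatenate([
                    cc[:w + 1, :w + 1].ravel(), cc[:w + 1, -w:].ravel(),
                    cc[-w:, :w + 1].ravel(), cc[-w:, -w:].ravel()])
                denom = max(n0 * nk / cc.size, 1e-30)
                total += float(windowed.max()) / denom
        return total

    best = (-np.inf, 0.0, 0.0)
    grid = np.arange(-90.0, 90.0 + 1e-9, coarse_step)
    for a in grid:
        for b in grid:
            s = score(a, b)
            if s > best[0]:
                best = (s, a, b)
    fine = np.arange(-coarse_step, coarse_step + 1e-9, fine_step)
    a0, b0 = best[1], best[2]
    for da in fine:
        for db in fine:
            s = score(a0 + da, b0 + db)
            if s > best[0]:
                best = (s, a0 + da, b0 + db)
    R = _axis_rotation(best[1], "x") @ _axis_rotation(best[2], "y")
    return R, best[0]


def _axis_rotation(angle_deg: float, axis: str) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def default_pssnr(config: AbInitioConfig, box: int) -> RadialProfile:
    """Molecular-weight-based default PSSNR for early ab-initio rounds.

    The profile decays like the power spectrum of a compact particle,
    PSSNR(g) = P0·exp(−(g·D/2.5)²) with D the mass-estimated particle
    diameter.  Capping the FSC-derived PSSNR with this curve is what
    keeps reference-bias-inflated FSC values from feeding an
    ever-more-overconfident matched filter (self-aligned noise).
    """
    dg = 1.0 / (box * config.pixel_size)
    g = np.arange(n_shells(box)) * dg
    d_est = 2.0 * (3.0 * particle_volume_from_mass(config.molecular_mass)
                   / (4.0 * np.pi)) ** (1.0 / 3.0)
    values = config.default_pssnr_value * np.exp(-(g * d_est / 2.5) ** 2)
    return RadialProfile(g, np.maximum(values, 1e-4))


def abinitio_run(stack: np.ndarray, ctfs, config: AbInitioConfig,
                 callback=None):
    """Full ab-initio loop.

    Returns ``(final_map, params, scores)`` so a subsequent automatic
    refinement can start from the ab-initio alignments.
    ``callback(l, state_dict)`` is invoked per iteration for logging.
    """
    rng = np.random.default_rng(config.seed)
    n, box = stack.shape[0], stack.shape[1]
    px = config.pixel_size
    # random initial reconstruction
    table_eulers = random_eulers(n, rng)
    params = [AlignmentParams(*table_eulers[i]) for i in range(n)]
    scores = np.zeros(n)
    pssnr_def = default_pssnr(config, box)
    pssnr_use = pssnr_def
    current = _reconstruct_subset(stack, ctfs, params, np.arange(n), px,
                                  config.mask_radius, pssnr_def)
    current = automask(current, config.mask_radius)
    sym_start = int(np.ceil(2.0 * config.iterations / 3.0))
    symmetrizing = config.apply_symmetry_mode == "always" \
        and config.osym > 1
    for l in range(config.iterations):
        R_l, p_l, pool_l = abinitio_schedule(l, config)
        diameter = 2.0 * config.mask_radius
        step = max(np.rad2deg(R_l / diameter), config.angular_step_floor)
        sc = SearchConfig(R1=300.0, R3=max(R_l, 2.0 * px + 0.1),
                          angular_step=step,
                          shift_search_radius=config.shift_search_radius)
        pool_idx = rng.permutation(n)[:max(2, int(round(pool_l * n)))]
        # resolution-limited Fourier cropping: search at a working pixel
        # size matched to the iteration's resolution limit
        work_stack, work_px = _crop_stack(stack[pool_idx], px,
                                          target_px=R_l / 2.5)
        work_ref = fourier_crop(current, work_px)
        projector = FourierProjector(work_ref, pad=2)
        new_params, new_scores = rotational_search_stack(
            work_stack, work_px, projector, [ctfs[j] for j in pool_idx],
            pssnr_use, sc, rng=rng, randomized_top_fraction=0.15)
        for j, gi in enumerate(pool_idx):
            params[gi] = new_params[j]
            scores[gi] = new_scores[j]
        n_keep = max(2, int(round(p_l * n)))
        kept = select_pool_and_keep(scores[pool_idx], pool_idx, n_keep)
        if config.apply_symmetry_mode == "auto" and config.osym > 1 \
                and l == sym_start:
            R_align, _ = align_to_symmetry(current, config.symmetry)
            current = rotate_volume(current, R_align)
            symmetrizing = True
        # sigma reset to 1, no score weighting; PSSNR capped by default
        half_a, half_b = kept[::2], kept[1::2]
        va = _reconstruct_subset(stack, ctfs, params, half_a, px,
                                 config.mask_radius, pssnr_def)
        vb = _reconstruct_subset(stack, ctfs, params, half_b, px,
                                 config.mask_radius, pssnr_def)
        fsc = compute_fsc(va, vb)
        if l >= 3:
            derived = pssnr_from_fsc(part_fsc(
                fsc, mask_particle_ratio(config.mask_radius,
                                         config.molecular_mass)))
            pssnr_use = RadialProfile(
                derived.bin_centers,
                np.minimum(derived.values, pssnr_def.values))
        current = _reconstruct_subset(stack, ctfs, params, kept, px,
                                      config.mask_radius, pssnr_use)
        if symmetrizing:
            current = symmetrize(current, config.osym)
        current = automask(current, config.mask_radius)
        if callback:
            callback(l, {"R": R_l, "p": p_l,
                         "fsc05": resolution_at_threshold(fsc, 0.5),
                         "n_kept": len(kept)})
    return current, params, scores


def _crop_stack(stack: np.ndarray, pixel_size: float, target_px: float):
    """Fourier-crop a particle stack to roughly ``target_px`` Å/pixel."""
    from .image import Image
    if target_px <= pixel_size:
        return stack, pixel_size
    first = fourier_crop(Image(stack[0], pixel_size), target_px)
    out = np.empty((stack.shape[0], first.box, first.box))
    out[0] = first.pixels
    for i in range(1, stack.shape[0]):
        out[i] = fourier_crop(Image(stack[i], pixel_size), target_px).pixels
    return out, first.pixel_size


def _reconstruct_subset(stack, ctfs, params, indices, pixel_size,
                        mask_radius, pssnr, scores=None,
                        bsc: float = 0.0) -> Volume:
    from .image import Image, freq_magnitude
    from .reconstruct3d import (ReconstructionAccumulator,
                                averaged_background_spectrum,
                                score_weights, whiten_background)
    box = stack.shape[1]
    acc = ReconstructionAccumulator(box, pixel_size)
    bg = averaged_background_spectrum(stack[indices], pixel_size,
                                      mask_radius)
    g2d = freq_magnitude(box, pixel_size, 2)
    mean_score = float(np.mean([scores[int(i)] for i in indices])) \
        if scores is not None and bsc else 0.0
    for i in indices:
        img = whiten_background(Image(stack[int(i)], pixel_size),
                                mask_radius, bg)
        w = score_weights(scores[int(i)], mean_score, bsc, g2d) \
            if scores is not None and bsc else None
        insert_particle(acc, img, params[int(i)], ctfs[int(i)],
                        q_ik=1.0, sigma_i=1.0, w_ik=w)
    return finalize(acc, pssnr)


# --------------------------------------------------------------------------
# automatic refinement
# --------------------------------------------------------------------------

@dataclass
class AutoRefineState:
    """Mutable schedule state across auto-refinement iterations."""

    iteration: int = 0
    p: float = 0.0
    R: float = 20.0
    resolution_history: list = field(default_factory=list)
    occupancy_change_history: list = field(default_factory=list)
    sigma_and_weighting_enabled: bool = False


def estimate_resolution_limit(fsc: FSCCurve, d_mask: float) -> float:
    """Refinement limit: FSC-0.5 crossing minus a 2/D_mask frequency
    allowance for half-map correlations induced by masking."""
    res05 = resolution_at_threshold(fsc, 0.5)
    g = 1.0 / res05 - 2.0 / d_mask
    return 1.0 / g if g > 0 else 4.0 * d_mask


def autorefine_update(state: AutoRefineState, fsc: FSCCurve, d_mask: float,
                      K: int, N: int, o_sym: int = 1,
                      occupancy_change: float = 0.0):
    """Advance the auto-refine schedule one iteration.

    Returns ``(new_state, stop)``.  When the resolution improved, the
    subset fraction is max(p_R, previous p) with
    p_R = 8000·K·exp(75/R²)/(N·Osym); otherwise it grows by 1.5x.  The
    run stops only after the minimum iteration count (5 single-class, 9
    multi-class) with p = 1, no resolution improvement over the last
    three iterations and (multi-class) occupancy changes of at most 1%.
    """
    raw = resolution_at_threshold(fsc, 0.5)
    R_est = estimate_resolution_limit(fsc, d_mask)
    hist = state.resolution_history + [raw]
    improved = len(hist) < 2 or hist[-1] < min(hist[:-1]) - 1e-9
    if improved:
        p_R = 8000.0 * K * np.exp(75.0 / state.R ** 2) / (N * o_sym)
        p_new = max(p_R, state.p)
    else:
        p_new = 1.5 * state.p
    p_new = min(p_new, 1.0)
    # Desk-scale adaptation: with a mask of ~130 Å the 2/D_mask
    # half-map-correlation allowance spans a large fraction of the whole
    # signal band and would pin the refinement limit far coarser than
    # the (verifiably honest) raw estimate, freezing progress.  The
    # limit therefore ratchets: on improvement it may lead the raw
    # FSC-0.5 crossing by a bounded factor (alignment accuracy at limit
    # R supports map features finer than R), and it never relaxes.
    lead = 0.8 if improved else 1.0
    R_new = min(state.R, lead * raw)
    if K > 1:
        R_new = max(R_new, 8.0)
    new = AutoRefineState(
        iteration=state.iteration + 1, p=p_new, R=R_new,
        resolution_history=hist,
        occupancy_change_history=state.occupancy_change_history
        + [occupancy_change],
        sigma_and_weighting_enabled=R_est < 7.0,
    )
    min_iter = 5 if K == 1 else 9
    no_improvement = len(hist) >= 4 and \
        min(hist[-3:]) >= min(hist[:-3]) - 1e-9
    stop = (new.iteration >= min_iter and new.p >= 1.0 and no_improvement)
    if K > 1:
        stop = stop and occupancy_change <= 1.0
    return new, stop


def autorefine_run(stack: np.ndarray, ctfs, initial_map: Volume,
                   config: AbInitioConfig, max_iterations: int = 15,
                   initial_params=None, initial_limit: float = None,
                   callback=None):
    """Single-class automatic refinement loop.

    Starts from an ab-initio (or imported) map, refining random subsets
    whose size and resolution limit track the estimated resolution.
    Returns ``(final_map, params, state)``.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, box = stack.shape[0], stack.shape[1]
    px = config.pixel_size
    d_mask = 2.0 * config.mask_radius
    pssnr_def = default_pssnr(config, box)
    state = AutoRefineState(p=min(8000.0 * config.K / (n * config.osym), 1.0),
                            R=initial_limit if initial_limit is not None
                            else config.R_start)
    params = list(initial_params) if initial_params is not None else \
        [AlignmentParams() for _ in range(n)]
    scores = np.zeros(n)
    current = automask(initial_map, config.mask_radius)
    pssnr_use = pssnr_def
    for _ in range(max_iterations):
        step = max(np.rad2deg(state.R / d_mask), 5.0)
        sc = SearchConfig(R1=300.0, R3=max(state.R, 2.0 * px + 0.1),
                          angular_step=step,
                          shift_search_radius=config.shift_search_radius)
        subset = rng.permutation(n)[:max(2, int(round(state.p * n)))]
        # resolution-limited working box for the searches
        work_stack, work_px = _crop_stack(stack[subset], px,
                                          target_px=state.R / 2.5)
        work_ref = fourier_crop(current, work_px)
        projector = FourierProjector(work_ref, pad=2)
        # a fresh global search per pass lets particles the ab-initio
        # stage left in wrong orientations escape; a simplex polishes the
        # result, and the previous parameters win if they score better
        cand, _ = rotational_search_stack(
            work_stack, work_px, projector, [ctfs[j] for j in subset],
            pssnr_use, sc, rng=rng)
        for j, gi in enumerate(subset):
            img_w = Image(work_stack[j], work_px)
            p_new, obj = local_refine(img_w, projector, ctfs[gi],
                                      pssnr_use, cand[j], sc)
            prev = local_refine(img_w, projector, ctfs[gi], pssnr_use,
                                params[gi], sc, max_evals=80)
            if prev[1] > obj:
                p_new, obj = prev
            params[gi] = p_new
            scores[gi] = score_from_objective(obj)
        # score-based weighting once the model is of reasonable quality
        weighting_on = bool(state.resolution_history) and \
            min(state.resolution_history) < config.sigma_weight_gate_A
        wargs = dict(scores=scores, bsc=config.bsc) if weighting_on else {}
        half_a, half_b = split_dataset(n)
        va = _reconstruct_subset(stack, ctfs, params, half_a, px,
                                 config.mask_radius, pssnr_use, **wargs)
        vb = _reconstruct_subset(stack, ctfs, params, half_b, px,
                                 config.mask_radius, pssnr_use, **wargs)
        mask = cosine_edge(radius_grid(box, px, 3), config.mask_radius,
                           3 * px)
        fsc = compute_fsc(va, vb, mask=mask)
        f = mask_particle_ratio(config.mask_radius, config.molecular_mass)
        pssnr_use = pssnr_from_fsc(part_fsc(fsc, f))
        if not state.sigma_and_weighting_enabled:
            pssnr_use = RadialProfile(
                pssnr_use.bin_centers,
                np.minimum(pssnr_use.values, pssnr_def.values))
        current = _reconstruct_subset(stack, ctfs, params, np.arange(n), px,
                                      config.mask_radius, pssnr_use,
                                      **wargs)
        current = automask(current, config.mask_radius)
        state, stop = autorefine_update(state, fsc, d_mask, config.K, n,
                                        config.osym)
        if callback:
            callback(state.iteration,
                     {"p": state.p, "R": state.R,
                      "resolution": state.resolution_history[-1]})
        if stop:
            break
    return current, params, state
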