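"""End-to-end demo pipeline on synthetic data.

Stages: simulate -> pick -> classify2d -> abinitio -> autorefine ->
sharpen.  Intermediates are persisted as MRC / TSV files under the work
directory with a JSON manifest, so a run can restart from any stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import mrc, params as param_io
from .ctf import CTFParams
from .image import Image, Volume

_STAGES = ["simulate", "pick", "classify2d", "abinitio", "autorefine",
           "sharpen"]


@dataclass
class ProjectConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    workdir: str
    seed: int = 0
    box: int = 48
    pixel_size: float = 3.0
    n_particles: int = 120
    snr: float = 0.1
    mask_radius: float = 66.0
    molecular_mass: float = 3.0e5
    symmetry: str = "C1"
    classes_2d: int = 3
    iterations_2d: int = 6
    iterations_abinitio: int = 8
    start_from: str = "simulate"
    stop_after: str = "sharpen"

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.start_from not in _STAGES or cfg.stop_after not in _STAGES:
            raise ValueError(f"stages must be one of {_STAGES}")
        return cfg


def run_pipeline(config: ProjectConfig) -> dict:
    """Execute the configured stages in order and return a run report."""
    from .classify2d import Classify2DConfig, classify_2d
    from .pick import PickParams, pick_particles
    from .reconstruct3d import (SharpenConfig, compute_fsc,
                                mask_particle_ratio, part_fsc,
                                resolution_at_threshold, sharpen_map,
                                split_dataset, reconstruct)
    from .schedules import AbInitioConfig, abinitio_run, autorefine_run
    from .synthetic import make_phantom, simulate_micrograph, \
        simulate_particles

    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "stages": {}}
    first = _STAGES.index(config.start_from)
    last = _STAGES.index(config.stop_after)

    def active(stage):
        return first <= _STAGES.index(stage) <= last

    diameter = min(120.0, 0.75 * config.box * config.pixel_size)
    phantom = make_phantom(box=config.box, pixel_size=config.pixel_size,
                           diameter=diameter, symmetry=config.symmetry,
                           seed=config.seed)
    if active("simulate"):
        stack, truth = simulate_particles(phantom, config.n_particles,
                                          snr=config.snr, shift_sigma=3.0,
                                          seed=config.seed)
        mrc.write_mrc(wd / "particles.mrc", stack,
                      pixel_size=config.pixel_size)
        param_io.write_params(wd / "particles.par",
                              param_io.from_truth(truth))
        micro, coords, _ = simulate_micrograph(
            phantom, n_particles=16, snr=0.15, seed=config.seed + 1)
        mrc.write_mrc(wd / "micrograph.mrc", micro)
        np.savetxt(wd / "true_coords.tsv", coords, delimiter="\t")
        report["stages"]["simulate"] = {"n_particles": config.n_particles,
                                        "micrograph_particles": 16}
    if active("pick"):
        data, px = mrc.read_mrc(wd / "micrograph.mrc")
        radius = phantom.diameter() / 2.0
        picks = pick_particles(Image(data, px),
                               PickParams(template_radius=0.7 * radius,
                                          max_particle_radius=radius,
                                          threshold_sd=4.0))
        with open(wd / "picks.tsv", "w") as fh:
            fh.write("x_A\ty_A\tpeak_sd\n")
            for (x, y), s in zip(picks.coords, picks.peak_sd):
                fh.write(f"{x:.1f}\t{y:.1f}\t{s:.2f}\n")
        report["stages"]["pick"] = {"n_picks": len(picks)}
    stack, px = mrc.read_mrc(wd / "particles.mrc")
    table = param_io.read_params(wd / "particles.par")
    ctfs = [CTFParams(r["defocus1"], r["defocus2"], r["astig_angle"],
                      r["phase_shift"], pixel_size=px)
            for _, r in table.iterrows()]
    if active("classify2d"):
        cfg2d = Classify2DConfig(K=config.classes_2d,
                                 n_particles=stack.shape[0],
                                 mask_radius=config.mask_radius,
                                 iterations=config.iterations_2d,
                                 pixel_size=px, seed=config.seed)
        result, q, history = classify_2d(stack, ctfs, cfg2d)
        mrc.write_mrc(wd / "classes2d.mrc", result.averages, pixel_size=px)
        report["stages"]["classify2d"] = {
            "K": config.classes_2d,
            "occupancies": [float(x) for x in result.weights]}
    cfg3d = AbInitioConfig(n_particles=stack.shape[0],
                           mask_radius=config.mask_radius, pixel_size=px,
                           iterations=config.iterations_abinitio,
                           molecular_mass=config.molecular_mass,
                           symmetry=config.symmetry, seed=config.seed)
    if active("abinitio"):
        vol, plist, scores = abinitio_run(stack, ctfs, cfg3d)
        mrc.write_mrc(wd / "abinitio.mrc", vol)
        for i, prm in enumerate(plist):
            for col, val in (("phi", prm.phi), ("theta", prm.theta),
                             ("psi", prm.psi), ("shift_x", prm.shift_x),
                             ("shift_y", prm.shift_y), ("score", scores[i])):
                table.loc[table.index[i], col] = val
        param_io.write_params(wd / "abinitio.par", table)
        report["stages"]["abinitio"] = {
            "iterations": config.iterations_abinitio}
    if active("autorefine"):
        voldata, vpx = mrc.read_mrc(wd / "abinitio.mrc")
        from .refine3d import AlignmentParams
        ptab = param_io.read_params(wd / "abinitio.par")
        init = [AlignmentParams(r["phi"], r["theta"], r["psi"],
                                r["shift_x"], r["shift_y"])
                for _, r in ptab.iterrows()]
        vol, plist, state = autorefine_run(stack, ctfs,
                                           Volume(voldata, vpx), cfg3d,
                                           initial_params=init)
        mrc.write_mrc(wd / "refined.mrc", vol)
        for i, p in enumerate(plist):
            for col, val in (("phi", p.phi), ("theta", p.theta),
                             ("psi", p.psi), ("shift_x", p.shift_x),
                             ("shift_y", p.shift_y)):
                table.loc[table.index[i], col] = val
        param_io.write_params(wd / "refined.par", table)
        report["stages"]["autorefine"] = {
            "iterations": state.iteration,
            "resolution_A": state.resolution_history[-1]}
    if active("sharpen"):
        voldata, vpx = mrc.read_mrc(wd / "refined.mrc")
        table = param_io.read_params(wd / "refined.par")
        ha, hb = split_dataset(stack.shape[0])
        va = reconstruct(stack, table, px, config.mask_radius, subset=ha)
        vb = reconstruct(stack, table, px, config.mask_radius, subset=hb)
        fsc = compute_fsc(va, vb)
        pfsc = part_fsc(fsc, mask_particle_ratio(config.mask_radius,
                                                 config.molecular_mass))
        sharp = sharpen_map(Volume(voldata, vpx),
                            SharpenConfig(whiten_beyond=8.0,
                                          mask_outer=config.mask_radius),
                            fsc=pfsc)
        mrc.write_mrc(wd / "sharpened.mrc", sharp)
        report["stages"]["sharpen"] = {
            "part_fsc_0143_A": resolution_at_threshold(pfsc, 0.143)}
    with open(wd / "manifest.json", "w") as fh:
        json.dump({"config": asdict(config), "report": report}, fh,
                  indent=2, default=float)
    return report
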