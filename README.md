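# spcryo

Desk-scale single-particle cryo-EM processing in Python: motion
correction, CTF determination, matched-filter particle picking,
maximum-likelihood 2-D and 3-D classification, projection-matching
refinement, Fourier-insertion 3-D reconstruction with FSC-based
resolution assessment, ab-initio reconstruction, automatic refinement,
and map sharpening.  Every stage is validated against synthetic data
with known ground truth generated by the built-in simulators, so the
whole pipeline runs on a laptop with no external data.

The package is aimed at people who want readable, testable
implementations of the standard single-particle algorithms — for
teaching, for method prototyping, or as an oracle for pipeline
development — rather than at production processing of real datasets.

## The algorithms

* **CTF model** — `CTF(g,θ) = −sin(πλg²Δf(θ) − (π/2)Cs λ³g⁴ + Δφ + arctan(A/√(1−A²)))`
  with astigmatic defocus `Δf(θ)`; fitting by a fast 1-D exhaustive
  search over (defocus, phase shift) followed by 2-D simplex refinement
  of `(d₁, d₂, α, Δφ)` against the background-subtracted spectrum under
  a radial sine mask, with moving-window fit quality and a CTF-aliasing
  check.
* **Picking** — correlation of the whitened micrograph with a soft-edged
  disk, scores in standard deviations of the no-particle null; abnormal
  local mean/variance areas (mode ± 2·FWHM rules) are excluded.
* **2-D classification** — Gaussian likelihood of noise-whitened
  particles marginalised over in-plane rotations (step `dα = R/D`) and
  bounded shifts; CTF-corrected class averages; linear resolution ramp
  (40 → 8 Å) and the 300·K/N random-subset schedule; class averages
  thresholded at `−0.3·max`.
* **Refinement** — matched filter: particle whitened by its radial
  amplitude spectrum and boosted by `√(1+SNR)`, reference scaled by
  `√SNR` with `SNR = PSSNR·CTF²`; normalised cross-correlation objective
  with optional unsigned high-resolution band and a quadratic shift
  restraint; scores = 100 × objective.
* **Reconstruction** — per-particle weighted central-slice insertion,
  `V = F⁻¹[Σ qᵢ/σᵢ² wᵢ CTFᵢ Fᵢ / (Σ qᵢ/σᵢ² wᵢ CTFᵢ² + 1/PSSNR)]`; FSC
  between half-maps (100-subset split), solvent-corrected
  `Part_FSC = f·FSC/(1+(f−1)FSC)` with the particle volume estimated as
  `Mw/0.81` Å³; `PSSNR = 2·FSC/(1−FSC)`.
* **Ab-initio** — iterative refinement from random angles with
  resolution and subset ramps, randomized top-15% candidate selection,
  score-based particle selection, auto-masking and optional symmetry
  alignment.
* **Auto-refinement** — data fraction `p = max(8000·K·e^(75/R²)/N, p)`
  on improvement (×1.5 otherwise), resolution-estimate-driven limits and
  conservative stopping rules.
* **Sharpening** — spectral whitening beyond 8 Å, explicit B factor
  `e^(−Bg²/4)`, optional `√(2FSC/(1+FSC))` figure-of-merit filter.

See `docs/methods.md` for conventions, numerical choices, what the
synthetic data do and do not emulate, and known limitations.

## Worked example

Simulate a particle stack from a random protein-like phantom, run
ab-initio reconstruction and automatic refinement, and sharpen the
result:

```bash
spcryo simulate --kind particles --out-prefix work/sim --n 150 \
    --box 48 --pixel-size 3.0 --snr 0.5 --seed 11
spcryo abinitio --particles work/sim.mrc --params work/sim.par \
    --out work/abinitio.mrc --iterations 10 --mask-radius 66 --mw 3e5 \
    --p-start 0.2 --p-finish 0.7 --seed 11
spcryo autorefine --particles work/sim.mrc --params work/abinitio.mrc.par \
    --reference work/abinitio.mrc --out-prefix work/refined \
    --mask-radius 66 --mw 3e5
spcryo reconstruct --particles work/sim.mrc --params work/refined.par \
    --out-prefix work/final --mask-radius 66 --mw 3e5
spcryo sharpen --input work/final.mrc --out work/final_sharp.mrc \
    --whiten-beyond 8 --mask-outer 66
```

The ab-initio stage prints its schedule per iteration on stderr:

```
iter 0: R=20.0 A p=0.20 FSC0.5=22.6 A
iter 1: R=18.7 A p=0.26 FSC0.5=20.9 A
...
iter 9: R=8.0 A p=0.70 FSC0.5=19.2 A
```

(`R` is the resolution limit imposed on the search, `p` the fraction of
particles kept for the reconstruction, `FSC0.5` the half-map resolution
estimate).  Auto-refinement then reports its adaptive schedule and the
final estimate:

```
iter 1: p=1.00 R=11.5 res=14.4
...
iter 6: p=1.00 R=10.8 res=13.5
final resolution estimate 13.52 A
```

and the reconstruction step finishes with

```
wrote work/final.mrc; Part_FSC 0.143 at 6.67 A
```

the solvent-corrected half-map resolution at the 0.143 criterion.  At
these very small dataset sizes the half-map number is optimistic —
all particles were refined against a single reference, which correlates
the two halves (see `docs/methods.md`); ground-truth comparisons in the
test suite put this map at roughly 12 Å.  Because ab-initio
reconstructions emerge at an arbitrary orientation and hand,
comparisons against a known reference map should use
`spcryo.fourier3d.align_volumes` first.

The same workflow is available as a single orchestrated run:

```bash
echo '{"workdir": "work/demo", "seed": 3, "n_particles": 120}' > demo.json
spcryo run-pipeline --config demo.json
```

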