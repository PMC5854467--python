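# Methods

`spcryo` implements a complete desk-scale single-particle cryo-EM
processing pipeline — motion correction, CTF determination, particle
picking, 2-D and 3-D maximum-likelihood classification,
projection-matching refinement, Fourier-insertion reconstruction with
FSC-based resolution assessment, ab-initio reconstruction, automatic
refinement, and map sharpening — validated end to end on synthetic data
with known ground truth.  This note records the models, the numerical
choices made where the design was genuinely open, what the synthetic data
do and do not emulate, and the known limitations.

## Conventions

* Real-space origin at the box centre (`side // 2`, 0-based); Fourier
  arrays in standard FFT order with the origin at element (0, 0).
* All spatial frequencies in Å⁻¹; a Fourier shell is `1/(side·pixel)`
  wide.  FFTs are forward-unscaled / inverse-1/N, so Parseval reads
  `Σ|x|² = Σ|X|²/N`.
* Euler angles are Z-Y-Z intrinsic `(φ, θ, ψ)` in degrees; the projection
  direction is the rotated z axis, and the projection at `(φ, θ, ψ)`
  equals the `(φ, θ, 0)` projection rotated in-plane by `+ψ`.
* CTF: `CTF(g, θ) = −sin(πλg²Δf(θ) − (π/2)Csλ³g⁴ + Δφ + arctan(A/√(1−A²)))`
  with astigmatic defocus `Δf(θ) = ½(d₁+d₂+(d₁−d₂)cos 2(θ−α))`, positive
  defocus = underfocus, Cs in mm, phase-plate shift Δφ in radians.

## Motion correction

Each movie frame is aligned to the sum of all other frames (iterated to
convergence, default threshold 0.1 Å) with a B-factor-damped (default
1500 Å²) cross-correlation, parabolic sub-pixel peak interpolation, and
Savitzky–Golay smoothing of the x(t), y(t) trajectories (cubic, window
`min(7, n_frames)` odd).  Trajectories are gauge-fixed to zero mean.  The
exposure filter uses the published critical-exposure curve
`Nc(g) = 0.245·g^(−1.665) + 2.81` (e⁻/Å²), per-frame weights
`exp(−d/(2Nc))` at the frame's accumulated exposure, and per-frequency
renormalisation `√(n/Σw²)` so filtered signal power matches an unweighted
aligned sum.

## CTF determination

Thon-ring fitting proceeds in two stages: an exhaustive 1-D search over
(defocus, phase shift) against the background-subtracted radial average,
then simplex refinement of `(d₁, d₂, α, Δφ)` against the 2-D spectrum
under a radial sine-edged mask (0 at the origin, 1 at 1/4 Å⁻¹).  Because
the correlation landscape is almost flat in the astigmatism parameters
until they are roughly right, the refinement begins with a coarse scan
over astigmatism magnitude (0–3000 Å) and angle (15° steps).  The
background is the heavily smoothed (Gaussian, ≈1/12 of the shell count)
radial average.  Spectra from movies may be computed from sub-sums of
frames; with drift the sub-sums retain ring contrast the full sum loses.
For pixel sizes finer than 1.4 Å the spectrum is resampled so its edge
falls at 1/2.8 Å⁻¹.  Quality of fit is a moving-window (9 shells)
correlation between the fitted CTF² and the radial profile; the fit
resolution is the first shell where it stays below 0.3 for three
consecutive shells.  An aliasing warning fires when the local Thon-ring
period `π/|dχ/dg|` drops below two spectrum pixels inside the fitting
range.  Diagnostics always use the background-subtracted but unmasked
spectrum.

## Particle picking

Micrographs are Fourier-cropped to half the highest picking resolution
(default 30 Å → 15 Å/pixel) and high-pass filtered at four times the
maximum particle radius.  Local mean and variance maps over a disk of the
maximum radius yield mode (Mo) and FWHM statistics; areas with variance
above `Mo + 2·FWHM` (8·FWHM with a phase plate delivering 0.1π–0.9π) or
mean outside `Mo ± 2·FWHM` are excluded.  The background whitening filter
is the inverse root of the average rotational power spectrum of the 50
lowest-variance square tiles (side `2×max radius`, floored at 16 pixels;
the mean-subtracted DC shell inherits the first informative shell's
gain).  Matched filtering correlates the whitened, unit-variance
micrograph with a unit-norm soft-edged disk, optionally blurred by |CTF|,
and standardises the score map with a median/MAD estimate of the null so
scores are in standard deviations of the no-particle distribution.  Peaks
are taken greedily in descending score with a suppression radius equal to
the maximum particle radius; ties break in scan order.

## 2-D classification

Particles are whitened by the radially averaged noise power spectrum of
the area outside the particle mask (averaged over up to 2000 random
particles), rescaled to unit pixel noise variance, and offset to zero
background mean.  Class responsibilities marginalise a Gaussian
likelihood over in-plane rotations at step `dα = R/D` radians (D = twice
the mask radius) and a translation grid bounded by `mask_radius/4`;
class sums are CTF-corrected (CTF² accumulated with a Wiener constant
equal to K, the per-shell whitened noise power times the class count).
The resolution limit ramps linearly from 40 Å to 8 Å over the run
(default 20 iterations); random subsets follow the three-tier 300·K/N
rule; class averages are thresholded at `−0.3·max` at the start of every
iteration.

Two numerical choices matter at small N.  Classes are seeded from single
random particles after a Wiener-style CTF correction, because mixture-
mean seeds leave all classes identical and expectation–maximisation
preserves that symmetry indefinitely.  During the first half of the
iterations the class sums use capacity-balanced hard assignments
(greedy, confidence-ordered, per-class cap ⌈n/K⌉): with tens rather than
thousands of particles per class, an unbalanced split hands the larger
class a less noisy average that then wins every likelihood comparison on
noise grounds alone.  Soft (marginalised) assignments take over for the
second half.

## Projection operators

Projection is central-slice extraction with trilinear interpolation from
the 3-D transform of the reference zero-padded ×2 in real space;
insertion spreads onto the 8 neighbouring voxels with the same weights,
so the pair is adjoint.  A slow real-space route (rotate voxels, sum
along z) and the closed-form projections of the Gaussian-blob phantoms
provide two independent cross-checks.

## Refinement objective and searches

The matched filter whitens the particle by its own radial amplitude
spectrum and amplifies by `√(1+SNR)`, where `SNR(g) = PSSNR(g)·CTF²(g)`;
the reference projection is CTF-modulated, divided by its radial
amplitude and scaled by `√SNR`.  The objective is the normalised real
cross-correlation over a [R1, R3] band, with an optional unsigned
high-resolution band above the signed-CC limit R2, plus the quadratic
shift restraint `−σ²/(2M)·[(x−x̄)²/σx² + (y−ȳ)²/σy²]`; scores are the
objective ×100, so a perfect unshifted match scores 100.

Two global-search implementations exist.  `global_search_stack`
evaluates a quasi-uniform Euler grid with an FFT translation search per
orientation and simplex local refinement of the best candidates; it is
the reference-grade path.  `rotational_search_stack` resamples
matched-filter-weighted images onto a polar grid (1 pixel radial step,
angular sampling ≈1.2-pixel arc at the outer radius) and evaluates all
in-plane rotations of all directions at once with a 1-D angular FFT; a
windowed translation pass then recovers shifts, and a second match on the
recentred particle removes the shift-induced rotation bias.  The polar
route is an order of magnitude faster and powers the ab-initio and
auto-refinement loops, where it is combined with resolution-limited
Fourier cropping of particles and reference to the iteration's limit.
Per-particle defocus refinement is a 1-D grid search of an offset
applied to both defocus values (default ±500 Å in 50 Å steps).

## Reconstruction and resolution

Particles are whitened by the radially- and particle-averaged background
power spectrum (the disk interior is replaced by the mask-edge mean for
the estimate only) and scaled to unit pixel variance.  Each insertion
adds `q/σ²·w·CTF·F{X}` to the numerator and `q/σ²·w·CTF²` to the
denominator along its central slice; the map is the inverse transform of
`numerator/(denominator + 1/PSSNR)`.  Score-based weights follow
`w(score, g) = exp(−(BSC/4)(score−mean)·g²)`.  Accumulators merge by
addition, so partial reconstructions combine exactly.  Likelihood-based
blurring inserts each particle over an (in-plane angle, x, y) grid with
normalised weights.

FSC uses half-maps split by particle parity or by parity of 100 equal
subsets (the default), Savitzky–Golay smoothed (cubic, window 7).
Solvent correction: `Part_FSC = f·FSC/(1+(f−1)·FSC)` for half-maps and
the squared-FSC variant against noise-free model maps, with
`f = mask volume / (Mw/0.81 Å³)`.  PSSNR per shell is `2·FSC/(1−FSC)`
(half→full dataset), clipped at a configurable ceiling.  Resolutions are
linear-interpolated threshold crossings (0.143 reported, 0.5 used by the
auto-refinement schedule).

Sharpening applies, in order: an optional hollow-sphere or custom mask,
spectral whitening beyond a cutoff (default 8 Å), an explicit B-factor
`exp(−Bg²/4)`, an optional figure-of-merit filter
`√(2·FSC/(1+FSC))`, and an optional cosine resolution cutoff.

## 3-D classification

Occupancies are posteriors of a Gaussian density of the masked residual
between the whitened particle and the CTF-modulated projection (the
particle's whitening filter is applied to the reference as well, keeping
both on the same scale — without this the emptier reference always wins);
priors are dataset-average occupancies, iterated to convergence in the
log domain.  Alignment parameters are not marginalised over.  Focused
classification masks the residual with the projection of a user-placed
sphere, evaluated per particle at its orientation with a 2-pixel cosine
edge.

## Ab-initio reconstruction

Random initial angles; per iteration: resolution ramp 20 → 8 Å, subset
ramp `p` from 2500·K/N to 10000·K/N (capped at 1; overridable — see
below) with a 3p search pool, polar global search whose per-particle
result is drawn uniformly from candidates within the top 15% of the
best-to-worst score range, top-p score selection into the
reconstruction, σ reset to 1, score weighting off, auto-masking (mean
threshold, 50 Å low-pass, binarise at
`mean + 0.03·(top-500 mean − mean)`, keep the largest connected
component, spherical mask), and for Cn symmetry an axis alignment at
⌈2n/3⌉ iterations followed by symmetrised reconstructions.

The PSSNR is capped by a molecular-weight default for the whole run and
is taken from the half-map FSC only from the fourth iteration.  The
default profile is `P0·exp(−(g·D/2.5)²)` with `D` the mass-estimated
particle diameter and `P0 = 50`: the cap is the procedure's defence
against reference-bias-inflated FSC values feeding an overconfident
matched filter, and it can only work if the default decays the way a
real particle spectrum does.  At desk-scale N (hundreds of particles)
the 2500·K/N subset ramp saturates at 1 and removes the score-selection
pressure the procedure relies on; `p_start`/`p_finish` are therefore
exposed as configuration (they are user parameters in this kind of
tool), and the validation runs use 0.2 → 0.7.

Ab-initio maps emerge at an arbitrary global orientation and with an
undetermined hand — projections cannot fix either.  All ground-truth
comparisons therefore first align the map to the reference over global
rotations and both hands (`align_volumes`).

## Automatic refinement

Per iteration the selected subset is re-searched globally (polar route,
on a working box Fourier-cropped to the current limit) and
simplex-polished, keeping the previous parameters when they score
better; half-maps, a soft-masked FSC and the solvent-corrected PSSNR
are recomputed; and the schedule advances: on improvement
`p = max(8000·K·e^(75/R²)/(N·Osym), p)`, otherwise `p = 1.5p` (capped
at 1).

The classic resolution-limit rule subtracts a `2/D_mask` frequency
allowance (for mask-induced half-map correlation) from the FSC-0.5
crossing.  At desk scale (`D_mask ≈ 130 Å`) that allowance spans a large
fraction of the entire signal band: applied literally it pins the limit
far coarser than the demonstrably honest raw estimate and freezes — or
even reverses — progress.  The limit here therefore ratchets on the raw
FSC-0.5 crossing: on improvement it may lead the crossing by a bounded
factor (0.8, since alignment at limit R supports map features finer
than R), and it never relaxes to a coarser value than already used.
σ is fixed at 1 and score-based weighting disabled until the resolution
estimate passes a configurable gate (7 Å by default, following the
convention that the model must be of reasonable quality first; desk
runs open it earlier).  Stopping requires at least five iterations
(nine for multiple classes), a full subset (p = 1), no resolution
improvement over the last three iterations, and (multi-class) mean
occupancy changes of at most 1%.

## Synthetic data

Phantoms are sums of 3-D Gaussian blobs at two scales: a few σ = 8 Å
lobes for low-resolution shape and dozens of σ ≈ 2 Å blobs clustered
inside them for secondary-structure-scale contrast, within a ~120 Å
diameter.  Projections are analytic, independent of the package's
Fourier projectors.  Particles get uniform orientations, Gaussian
shifts, uniform defocus in 8000–20000 Å, the full CTF, and white noise
scaled to a target SNR (signal variance over noise variance inside the
particle mask, after CTF).  Micrographs add ice-thickness modulation of
the noise level (±15%, ~400 Å correlation length) and solvent
granularity in the 30–250 Å band; without these, local-variance
histograms are so narrow that the abnormal-area thresholds reject every
particle, which no real micrograph does.  Ice contamination is modelled
as patches of strongly elevated variance and offset mean.  Movies split
an image into frames following a smooth decelerating drift with
independent per-frame noise.

What the generators do not emulate: electron-optical image formation
(no multislice), detector MTF/DQE, structured (non-Gaussian) noise,
particle flexibility or partial occupancy, overlapping/aggregated
particles, and per-particle local motion.  Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model,
not end-to-end performance on real data.

## Problem sizes used in validation

The automated checks run at sizes chosen for minutes-scale turnaround:
box 48–64 at 3 Å/pixel, 20–500 particles per check, ab-initio with 12
iterations on 300 particles at SNR 0.3, auto-refinement for up to 6–8
iterations.  Thresholds (recovery tolerances, classification accuracies,
FSC targets) are never adjusted to the problem size.

## Known limitations

* Magnification is carried in the parameter model but not refined.
* Point groups beyond Cn are not implemented.
* No per-particle motion, beam tilt, or higher-order aberrations.
* The 1-D CTF pre-search can mislead at very large astigmatism; a flag
  forces the exhaustive 2-D search instead.
* Multi-class auto-refinement logic (schedules, stopping) is implemented
  and tested at the unit level, but the orchestrated multi-class loop is
  exercised only through 3-D classification at fixed alignments.
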