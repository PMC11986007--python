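# Methods

`hgiscan` simulates a coherent macroscopic imaging bench in which binary
objects displayed on a DMD (digital micromirror device) are imaged through a
deliberately small aperture, and compares four read-out strategies: direct
imaging (DI) and Hermite–Gaussian imaging (HGI, spatial-mode demultiplexing),
each under widefield and focused scanning illumination with pixel
reassignment. This note records the models, the defaults and the reasoning
behind the choices that the code makes.

## Object and grid conventions

Everything is expressed in physical DMD pixels (7.56 µm pitch). The standard
frame is 210 × 210 physical pixels, built from 10 × 10-pixel binary logical
pixels; the image and object planes share this grid (unit magnification), and
the origin sits at the frame centre (half-integer pixel-centre coordinates on
the even grid). Objects carry a binary amplitude with flat phase — the
simplest reflection model consistent with a DMD illuminated by a single
coherent beam; the coherent two-point examples are therefore in-phase.

Scanning is emulated exactly the way the bench does it: the illumination
profile stays centred while the displayed pattern is the object displaced by
−S for scan shift S (pixels displaced past the frame edge are lost, as on a
physical DMD). The scan raster covers the frame with a 20-pixel step: 11 × 11
= 121 snapshots.

## Optical forward model

The detection amplitude point spread function (APSF) is either

* **Gaussian** (default): `APSF(x, y) ∝ exp(−(x² + y²)/(4σ_det²))`, so the
  intensity PSF `|APSF|²` is a normalised Gaussian of standard deviation
  σ_det per axis. Defaults: σ_det = 30 px (the value estimated from
  NA = 0.71·10⁻³ and λ = 795 nm), with the bench-measured 28 px available as
  a preset.
* **Jinc**: `APSF(r) = 2J₁(v)/v`, `v = 2πNA r/λ` — the circular-aperture
  response, used for the analytic resolution benchmarks.

Image formation follows the standard coherent/incoherent dichotomy:
`I = |obj ⊛ APSF_det|²` or `I = Obj ⊛ PSF_det` in widefield, with the
focused-illumination profile multiplying the (displaced) object before
detection in the scanning case. Convolutions are zero-padded (the DMD is
dark outside the pattern); the Gaussian path uses separable 1D kernels
truncated at 7σ.

Width composition: `σ_ISM = σ_il σ_det / √(σ_il² + σ_det²)` governs the
scanning geometry; equal widths give σ_det/√2, and the pixel-reassignment
rescale factor is `σ_det²/σ_ISM²` (= 2 for matched widths).

## Hermite–Gaussian imaging

The HG basis `φ_mn` uses a single width σ = σ_det in both the Hermite
arguments and the Gaussian envelope (the two symbols that appear in the
field's usual way of writing the basis denote the same width here; the
package treats them as one parameter). Modes are generated by the stable
oscillator recurrence, with the default 21 × 21 = 441 modes (orders 0–20)
and an 882-component real measurement vector (Re/Im interleaved). The grid
for the sampled basis is chosen automatically so that mode (20, 20) keeps
all but 10⁻⁶ of its energy inside (≈ ±338 px at σ = 30); a smaller grid is
rejected with the required extent in the message.

**Measurement.** `c_mn = ⟨φ_mn, E⟩` by grid quadrature. For the separable
Gaussian APSF the package never forms the image field: the overlap of a
separable mode with `APSF ⊛ (obj·A_il)` equals a two-sided contraction of
the illuminated object with the 1D adjoint tables `w_n = u_n ⊛ g`, built
with exactly the same truncated kernel and quadrature as the image-plane
route, so the two paths agree to rounding error (this identity is tested).
Measurement noise is a single per-mode additive complex Gaussian — a
surrogate for local-oscillator shot noise in sequential heterodyne read-out;
acquisition time and photon budget are not modelled.

**Reconstruction.** The "perfect HGI" route discretises the measurement
into a forward operator over a 50 × 50 reconstruction grid spanning the
frame (box pixels of 4.2 px) and inverts it by an SVD pseudoinverse with a
relative singular-value floor. Mode amplitudes decay exponentially with
order, so the floor sets the bias/variance trade-off:

* noiseless: 10⁻³ (resolution-limited by mode truncation);
* under noise: 10⁻² by default — damping comparable to the relative noise
  floor. A much heavier floor (10⁻¹) blurs the reconstruction enough to
  cancel the mode-measurement resolution advantage entirely, which is why
  the default tracks the noise level rather than a fixed large value.

**Noise operating point.** The bench's per-mode noise level is not a
published quantity. The package's default noisy regime sets the per-mode
standard deviation to 0.1% of the strongest widefield mode amplitude of the
object — a strong-local-oscillator heterodyne regime. At this operating
point the simulation lands in the bench's observed regime: widefield HGI
resolves ≈ 53 px (≈ 2× better than widefield DI's ≈ 108 px; the bench
observed 2.4×), and scanning HGI improves on widefield HGI by ≈ 7%,
consistent with the ≤ 8% bound that the width-composition formula gives at
an illumination-to-detection width ratio of 2.4. Noiseless runs resolve
≈ 44 px for both HGI variants.

## Pixel reassignment

Each snapshot is contracted about the illumination axis by
`σ_ISM²/σ_det_eff²` (isotropically — the 1D derivation is applied per axis)
and summed displaced by its scan shift. For HGI snapshots the effective
detection width `σ_det_eff` is fitted by running a single 10-px line through
the noiseless HGI pipeline and fitting the box-convolved Gaussian
line-spread model (the bench does not publish how its HGI snapshots were
rescaled; a fitted effective width is the natural analogue, ≈ 11 px at the
defaults). Shading from the finite raster is flattened by dividing by the
same pipeline's response to a uniform all-on object — exact by construction
for any coherence setting, unlike the infinite-raster Gaussian-integral
constant. Interpolation is bilinear by default (bicubic available).

For identical circular-aperture PSFs the reassignment PSF is **not** the
pointwise product jinc⁴: reassigning each photon to the midpoint of its
excitation and detection coordinates makes the effective PSF the 2D
autoconvolution of the Airy PSF at half scale. Its generalized-Rayleigh
two-point gain over widefield evaluates to 1.54 (FWHM ratio 1.53), the
"about 1.53" of the ISM literature; the pointwise-product comparison would
give 1.39, and only for Gaussians do the two constructions coincide (both
√2). The package computes the correct factor via the Hankel transform of
the squared chinese-hat OTF.

## Resolution metrology

Two-point resolution uses the generalized Rayleigh criterion on line pairs:
the intensity profile across a pair (row-averaged over the central 80% of
the 175-px line length) is spline-interpolated; the saddle-to-peak ratio is
tracked across the 20–130 px separation series and linearly interpolated in
the ratio to the criterion value. The criterion threshold is computed, not
assumed: the saddle-to-peak ratio of two incoherent Airy spots at the
classic Rayleigh separation (0.7350). The reported uncertainty is the
interpolation-bracket half-width — a grid quantity, not a statistical error.
Series whose extreme separations are already resolved (or unresolved) are
flagged `below_range`/`above_range` with the nearest separation, which still
bounds the resolution.

PSF widths are estimated by least squares against the box-convolved Gaussian
line-spread model (amplitudes summed then squared for coherent imaging; a
two-line variant handles pair images). Richardson–Lucy deconvolution is the
standard multiplicative scheme (via scikit-image), 300 iterations by
default, with the PSF for each pipeline fitted from that pipeline's own
line images.

## Image quality (MS-SSIM)

MS-SSIM on 50 × 50 crops cannot support the canonical 5 scales with an
11 × 11 window; the package uses 3 dyadic scales, a 7 × 7 Gaussian window
(σ = 1.5), the first three of the standard five-scale exponents
renormalised, and 2 × 2 mean pooling. Images are max-normalised to [0, 1]
first. The sampled protocol draws seeded random co-located crops from a
central region of a large stitched image (default 1000 crops of 50 px) and
reports mean ± standard error.

The complex-object experiment tiles a synthetic emblem (a generated
logo-like bitmap: border, rings, glyph strokes — the package ships no
third-party artwork) into overlapping 210-px frames (70 px overlap), images
each tile with widefield and scanning HGI under the noisy operating point,
upsamples the reconstructions back to the DMD grid, stitches central crops
(overlap-averaged seams), and scores MS-SSIM against the binary ground
truth. The default emblem for the acceptance-scale experiment is
420 × 280 px (12 tiles); a full-scale 1680 × 630 emblem is a parameter away
but multiplies the scanning cost by ~4.

## Network reconstructor

The MLP (882 → 800 → 400 → 400 → 800 → 2500; tanh, ReLU ×3, sigmoid output;
Adam with lr 10⁻⁴, β = (0.9, 0.999), batch 32, MSE) is implemented directly
in numpy — forward pass, backpropagation and Adam, all seed-controlled.
Choices the architecture description leaves open: fan-in-scaled uniform
initialisation; per-epoch reshuffling from a seed-derived stream; inputs
scaled by the per-component training-set standard deviation (a tanh front
end needs some normalisation). Labels are noiseless perfect-HGI
reconstructions smeared by 1 label pixel (to avoid overfitting to grid
artefacts), faded to black by the illumination envelope for the scanning
variant. Epoch selection: best-validation checkpoint for widefield
training (which overfits early), final epoch for scanning.

Package-scale defaults train on 2000 samples (1000 bitmaps, 500 ellipses,
500 lines) for 50 epochs — enough to show the qualitative behaviour: the
validation MSE falls monotonically (0.09 → 0.013 at seed 1) while remaining
far above the pseudoinverse's residual, i.e. the network approaches but
never beats the physics on clean data. The full recipe (20 000 samples,
5000 epochs) runs through the same interface. The control experiment —
an analogous network mapping DI images to objects — does not improve the DI
resolution estimate (it blurs it), confirming that resolution gains come
from the measurement, not the network.

## Synthetic data: what it does and does not emulate

The generators reproduce the study conditions: logical-pixel bitmaps with
20–80% fill, random ellipses (semi-axes 1–10 logical px, uniform centre and
orientation) and random lines (width 1–3 logical px, uniform endpoints),
line pairs of 175-px length at 20–130 px separations, and a tiled large
object. They do not emulate bench imperfections: aberrations, defocus,
illumination-profile error, detector noise in DI, mode-preparation
crosstalk, or the position-dependent HGI artefacts the bench observes.
Passing tests therefore certify the algorithms and their scaling laws
(width composition, reassignment geometry, resolution orderings), not the
absolute resolutions of any physical instrument; the bench's measured
111/69/46/44/28-px values depend on hardware and are mirrored here only as
orderings and ratios.

## Numerical choices and degenerate inputs

* Convolution boundary: zero padding everywhere (dark DMD surround).
* Reassignment sums snapshots in sorted shift order so results are
  bit-identical under scan-order permutation; integer-pixel shifts take an
  exact copy path, sub-pixel shifts interpolate.
* The pseudoinverse floors singular values even when asked for zero
  regularisation (with a warning) — the operator is exponentially
  ill-conditioned.
* Degenerate inputs: zero-separation pairs are single lines; all-off
  objects produce identically zero images, labels and reconstructions;
  a scan shift moving the whole object out of the illuminated support is
  valid and yields a near-zero snapshot; a bitmap smaller than one frame
  tiles to a single padded tile.
* Problem sizes in the shipped tests are chosen for a single CPU: the
  resolution orderings use the separations that bracket each pipeline's
  criterion crossing, the emblem experiment uses the 420 × 280 emblem with
  200 sampled crops, and the network runs at the 2000-sample/50-epoch
  reduced recipe.

## Known limitations

* Incoherent HGI (intensity-in-mode measurement, augmented odd-moment
  basis) is out of scope; the Jinc-model forward operator exists but the
  fast separable path requires the Gaussian APSF.
* The reconstruction grid (4.2 px boxes) lower-bounds measurable HGI
  widths; effective-width fits are floored at half the grid pitch.
* No aberrations, defocus/3D sectioning, polarisation or photon-budget
  radiometry; DI images are noiseless.
* MS-SSIM absolute values at 3 scales/7×7 window are not comparable to
  5-scale/11×11 published values; only comparisons within the package are
  meaningful.
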