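# Methods

This note documents the models behind `epid2water`, their parameters and
defaults, the design choices that were genuinely open, and what the
synthetic validation does and does not demonstrate.

## Head-fluence model

The incident energy fluence is a two-source model on a square,
CAX-centered, odd-sized grid (so one sample always sits on the central
axis; 1 mm pitch at isocenter scale and ±16 cm extent by default):

* **Focal source.** The jaw aperture (positions in cm at the isocenter
  plane, projected to any other plane by similar triangles, with
  fractional pixel coverage at the edges) is multiplied by the flattened
  beam's radial horn profile `h(r) = 1 + Σ c_k r^(k+1)` (r in cm at
  isocenter scale; default `c₂ = 2.5×10⁻⁴ cm⁻²`, i.e. +2.5 % at 10 cm
  off-axis) and blurred with a Gaussian penumbra of
  `source_sigma_mm = 3 mm` (effective sigma at isocenter, scaled with
  plane distance).  The default horn gives ~0.8 % flatness for a 20×20
  field at shallow depth — typical of a tuned flattened 6 MV beam.
* **Extra-focal source.** The aperture convolved with a broad Gaussian
  (`extrafocal_sigma_mm = 20 mm` at isocenter scale), weighted by
  `extrafocal_fraction = 0.05` of the MU.  This produces the
  collimator-scatter tails outside the geometric field edge.
* **Jaw transmission** is a fixed scalar (0.002); no spectral hardening
  under the jaw is modeled.
* **Steering detune** is a linear off-axis intensity modulation
  `1 + t_cp·x + t_ip·y` (x, y in cm at isocenter).  A steering-angle error
  moves the beam spot on the target; its lowest-order dosimetric effect is
  exactly such a tilt, and a tilt reproduces the observed monotone
  symmetry skew of detuned beams.  The default magnitude `t = 0.002 cm⁻¹`
  was chosen so that the ground-truth water symmetry of a detuned 20×20
  beam falls in the 2–3.5 % band reported for deliberately de-steered
  machines.

Transport between planes is a pure geometric rescale: the grid magnifies
with distance and values scale with the inverse square, so integrated
fluence is conserved exactly and no interpolation error is introduced.

## Detector model

The panel dose image is the fluence resampled to the pixel grid, convolved
with a radially symmetric three-Gaussian kernel — default
`(0.80, 0.8 mm), (0.14, 6 mm), (0.06, 25 mm)`, normalized — and multiplied
by the panel's radial off-axis over-response (default +2.5 % at 10 cm
off-axis).  The sharp core carries the primary dose deposition; the long
25 mm tail is the optical/low-energy glare that makes the panel
non-water-equivalent.

The off-axis over-response is treated as a *characterized* detector
property and is therefore part of the forward model: a model-based
conversion succeeds precisely because it accounts for the detector's
response, whereas raw pixel values keep the full over-response and
misreport water-referenced beam parameters.  What the reconstruction
cannot know is the *residual* state of the panel on the day, which is the
role of the perturbation model below.

Simulated "measured" images add, on top of the forward model:

| perturbation | default | meaning |
|---|---|---|
| kernel sigma scale | 1.05 | true deposition kernel 5 % wider than modeled |
| residual over-response | +0.25 % at 10 cm | uncharacterized drift of the radial response |
| noise fraction | 0.003 | Gaussian sigma as a fraction of CAX signal |
| dark field / pixel gain | none | optional 2D panel structure |

Noise is Gaussian and signal-proportional; at QA dose levels (hundreds of
MU into an integrating panel) Poisson statistics are irrelevant.  The
simulated image is raw: dark-field and pixel-sensitivity corrections are
applied afterwards, exactly as for a real acquisition.  Flood-field
correction is never applied anywhere — it would erase the incident-fluence
profile the method needs.

The default simulation panel is 1 mm pitch, 321×321 pixels (±16 cm); an
aS1200-like spec (0.34 mm pitch, ~43 cm panel) is provided as
`DetectorSpec.as1200()`.  The coarser default keeps closed-loop runs
desk-scale; all results here are insensitive to pitch below ~2 mm because
every compared quantity lives on centimetre scales.

## Fluence reconstruction

Multiplicative fixed point `f ← f · smooth(clip(M/P(f)))` with the ratio
clamped to [0.2, 5], forced to 1 outside the in-field region (pixels below
5 % of the CAX signal), and smoothed with a 1 mm Gaussian.  The
multiplicative form is positivity-preserving and, for smooth kernels whose
low-frequency gain is ~1, converges in a handful of iterations; the
smoothing regularizes the otherwise ill-posed deconvolution so pixel noise
is not amplified.  Convergence is declared when the maximum in-field
image deviation relative to the CAX signal falls below `tol = 0.002`
(cap 25 iterations).  With noisy inputs the deviation floor is the noise
itself (~1 % for 0.3 % pixel noise under max semantics), so noisy runs
terminate at the cap with `converged=False` — a warning, not an error; the
fixed point has still absorbed the systematic discrepancy.  Reconstruction
is performed at the EPID plane; transport to other distances uses the
exact divergence rescale afterwards.

## Dose-to-water engine

Pencil-beam factorization per depth slice:

    D(x, y, z) = [Φ_{ssd+z} ∗ G_{σ(z)}](x, y) · w(z)
    w(z) = (1 − e^{−βz}) e^{−μ_eff z} (1 + s·ESF(field))

with `μ_eff = 0.045 cm⁻¹`, lateral kernel `σ(z) = 2 mm + 0.35 mm/cm · z`,
and a small equivalent-square scatter factor (`s = 0.01`).  The buildup
rate β is calibrated per field size (Brent root-find) so that the CAX
depth-dose maximum — *including* beam divergence at the reference
SSD = 100 cm — falls at the configured d_max: 14 mm for 10×10, 12 mm for
20×20 (linear in equivalent-square side).  Calibrating on the full
divergent product rather than on `w(z)` alone matters: the inverse-square
gradient (−2 %/cm at 100 cm) shifts the maximum of the product ~1.5 mm
shallower than the maximum of the bare weight.

**Electron contamination** is an additive surface term
`0.023·e^{−z/0.5 cm}` (≈ +2.5 % of the PDD maximum at the surface,
negligible beyond ~2 cm).  It exists only in the ground-truth generator:
the reconstruction-side engine deliberately omits it, because kernel-based
transport models do not track contaminant electrons.  The closed-loop PDD
comparison therefore shows the expected ~2.5 % buildup-region discrepancy
while agreeing to ~0.2 % beyond 10 mm.

The virtual water tank defaults to 40×40×40 cm³ at SSD 100 cm with 2 mm
voxels; validation runs use 1 mm depth steps, 2 mm lateral voxels, ±13 cm
lateral extent and 30 cm depth — profiles are interpolated to 1 mm for
metric evaluation, and the compared quantities (flatness, symmetry, PDD)
are fully resolved at that voxelization.  The virtual chamber array is
MatriXX-like: 7.62 mm spacing, 4.5 mm circular apertures (area-averaged on
a 1 mm plane grid), 5 cm buildup plus 0.3 cm inherent water-equivalent
depth (the array's own electronics/buildup — not published, so
config-exposed), 31×31 chambers so a CAX chamber exists.

## QA metrics

Field width is the FWHM of the CAX-normalized profile (linear
interpolation at the 50 % crossings); the evaluation region is the central
80 % of that width, *centered on the CAX* because the symmetry pairs are
defined as equidistant from the central axis.  Flatness is
`100(M−m)/(M+m)` over the region.  Symmetry is evaluated over all
equidistant pairs on the 1 mm interpolated grid and reported **signed**
(`sign(D_left − D_right)`, left = negative coordinates) at the pair with
the largest absolute difference, ties going to the smallest off-axis
distance — the signed value is what distinguishes the two skew directions
of a detuned beam.  An O(n²) brute-force pair scan is kept in the test
suite as the oracle for the implementation.

## What the synthetic validation shows — and what it cannot

The generator stands in for the physical reference instruments: ground
truth plays the scanning water tank / reference chamber array, and the
perturbations (kernel mismatch, residual response drift, noise) play the
unavoidable model error of a real panel.  Closed-loop agreement
demonstrates that the inversion and conversion machinery is correct and
stable under realistic mismatch, and that raw-EPID metrics are visibly
worse than water-equivalent ones for every detuned beam (the raw symmetry
error is dominated by the off-axis response and by unsmoothed pixel noise
under max-pair semantics).

It cannot demonstrate absolute dosimetric accuracy on a particular
machine: the kernel weights, horn coefficients, over-response polynomial
and water-model parameters are physically plausible stand-ins, not fits to
any specific linac/panel pair, and beam-spectrum changes, FFF beams,
MLC-shaped fields, image lag/ghosting and support-arm backscatter are out
of scope.  Contaminant-electron modeling exists only in the generator, so
surface dose from the reconstruction path is known-low by design.

## Numerical notes

* Gaussian convolutions use separable `scipy.ndimage.gaussian_filter`
  with zero padding (constant mode) so interior-supported signals conserve
  integral to <0.5 %; grids are sized with ≥3σ margins.
* All resampling is bilinear; out-of-support values are 0.
* Degenerate inputs raise: zero-area fields, non-positive distances,
  horn/tilt driving in-field fluence non-positive, flood-corrected or
  doubly-corrected images, empty in-field regions, tanks or chamber grids
  larger than the fluence support.
* Reported seeds drive every random draw (`numpy.random.default_rng`);
  pipeline reports hash bit-for-bit reproducibly.
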