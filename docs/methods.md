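# Methods

## The measurement being modelled

In a flash-frozen sample, conformational exchange is arrested and a 2D
¹³C–¹³C correlation cross-peak is the superposition of the shifts of every
trapped conformer, with intensity proportional to each conformation's
population.  The analysis problem is the inverse one: decompose a broad
cross-peak into a small number of Gaussian components, convert component
volumes to fractional populations, and assign each component to a backbone
conformational class (α-helix, random coil, β-strand, positive-φ) by its
chemical-shift position.  A statistical-coil simulation of a host–guest
peptide provides the reference line shape for an unrestrained residue.

## Statistical-coil model

The coil library represents each residue type's backbone preferences as a
mixture of wrapped bivariate Gaussian basins on the Ramachandran torus:

    p(φ, ψ) = Σ_b w_b · N_wrap(φ; φ_b, s_φ,b) · N_wrap(ψ; ψ_b, s_ψ,b)

with four basins per residue type: αR near (−63°, −43°), PPII/extended coil
near (−70°, 145°), β near (−150°, 125°), and the positive-φ (αL-like) region
near (60°, 45°) (glycine: (75°, 30°), with substantially more positive-φ
weight, as expected for the only residue without a Cβ).  Conformers of the
11-residue poly-alanine host–guest peptide (guest central; both are
configurable — the peptide geometry is a modelling choice, not data) are
drawn residue-independently: the analysis reads only the guest residue, so
nearest-neighbour (φ, ψ) coupling is deliberately not modelled.  Sampling is
seeded and bitwise reproducible; the basin drawn for each conformer is
recorded so that empirical occupancies can be checked against the exact
multinomial draw rather than through geometric relabeling (the nearest-basin
labeler `assign_basin` exchanges a small fraction between adjacent basins by
construction).

Basin weights are the calibration knobs of the library.  The shipped values
reproduce, through the *entire* pipeline (sampling → shift prediction →
broadening → 4-Gaussian fit → classification), the reference coil
decompositions for alanine (≈16/60/15/8% α/coil/β/positive-φ) and leucine
(≈8/64/21/7%), and a single ≈3 ppm-wide coil Gaussian at (44.7, 174.2) ppm
for glycine Cα–CO.  Weights are stored as relative values and normalized on
load (the percentage triples they derive from round to 99–102%).

## Shift surface

Chemical shifts are generated by a smooth, 360°-periodic surface per
(residue type, atom) pair, anchored at the four basin centroids:

    δ(φ, ψ) = Σ_b w_b(φ, ψ) · [ a_b + g_φ,b sin(Δφ_b) + g_ψ,b sin(Δψ_b) ],
    w_b ∝ exp(−(Δφ_b² + Δψ_b²) / 2κ²)

where Δφ_b, Δψ_b are wrapped offsets from basin b's centroid, a_b the anchor
shift and g the local slope of the shift with backbone geometry.  Key
properties: at a basin centroid the surface equals that anchor (sin(0) = 0
and, at the shipped κ = 12°, cross-basin kernel weights are negligible); the
slope terms have zero mean over a symmetric basin density, so per-basin
ensemble-average shifts stay at the anchors while the within-basin shift
dispersion is g·σ_angle per axis.  Slopes are calibrated so that, after the
1.5 ppm broadening, fitted component FWHMs land in the observed 2.2–3 ppm
range.  Opposite slope signs on Cβ (and CO) relative to Cα keep the
within-basin Cα/Cβ dispersion uncorrelated, matching the axis-aligned
Gaussian fit model.

The kernel width 12° was chosen because wider kernels blend the PPII and β
basins (≈68° apart): the blending skews each basin's shift cloud toward its
neighbour and visibly biases the fitted class fractions.  Anchor values for
alanine, leucine and glycine are the reference coil-decomposition centers;
serine and threonine anchors (and all CO anchors except glycine's) are
implementer-chosen constants consistent with standard secondary-shift
statistics, shipped as configuration, and are not validated against any
reference decomposition.

The surface is a deliberately minimal stand-in for a full structure-based
shift predictor: it depends only on the backbone dihedrals of the residue
itself.  Ring-current, hydrogen-bonding, temperature and sequence-neighbour
effects are out of scope.

## Cross-peak synthesis

Per-conformer (δ₁, δ₂) pairs are histogrammed onto a uniform ppm grid
(default 0.1 ppm/point, axes stored ascending) with bins centred on grid
points, then convolved with a unit-sum 2D Gaussian kernel of FWHM 1.5 ppm in
both dimensions (homogeneous line width; the value and per-axis symmetry are
configurable).  The total integral before normalization equals the conformer
count × pixel area; spectra for comparison are normalized to unit Riemann
integral.  Out-of-grid shifts raise an error by default (clipping with a
warning is available behind a flag).  Intensity matching between spectra
uses the ratio of ROI integrals.  1D slices are nearest-row (optionally
interpolated) profiles, peak-normalized.

## Mixture decomposition

A region of interest is fit by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) to k ∈ [1, 4]
axis-aligned 2D Gaussians with parameters (c₁, c₂, FWHM₁, FWHM₂, A) each.
Numerical choices:

- **Constrained peak motion.** Centers are bounded to ±1.0 ppm (default)
  around their initial guesses.  The statistical-coil pipeline seeds the
  guesses at the surface's own anchor positions; otherwise guesses come from
  the top-k local maxima of the smoothed ROI, with a seeded jittered
  multistart (3 extra starts by default) keeping the best residual.
- **Widths** bounded to [0.5, 8] ppm; amplitudes non-negative.
- **Fractions** are analytic volumes A·2πσ₁σ₂ normalized over components
  (σ = FWHM/2.355), not pixel sums; the analytic and pixel-summed volumes
  agree to ≪0.5% on a 0.1 ppm grid.
- **Model selection.** When k is not fixed a priori, the BIC over ROI pixels
  chooses it; per-k residuals are reported so the choice can be overridden.
  Experimental practice fixes k per peak; model selection is a convenience,
  not an inference of that practice.
- **Diagonal handling.** Homonuclear spectra can be masked within a band
  |δ₁ − δ₂| < d via fit weights (used for Ser/Thr-style near-diagonal
  peaks).  Above- and below-diagonal ROIs are fit independently with the
  same k; components are matched by swapped-center proximity with a 1.5 ppm
  gate (the reference decompositions are separated by ≳1.5 ppm in at least
  one dimension), and populations reported as mean ± |p_a − p_b|/√2 — the
  two-value sample SD (n−1 denominator).
- **Non-convergence** is flagged (`converged=False`), never silent; a ROI
  whose maximum is below 6× the border-MAD noise floor is reported as
  degenerate rather than fit.

## Classification

Reference windows are per-residue, per-atom (mean, SD) shifts for α-helix,
coil and β-strand; a component's normalized distance to a class is the max
over the two atoms of |center − mean|/SD, and the label is the class of
minimal distance provided it is ≤ 2 (inside the ±2 SD window on both axes).
The positive-φ region enters as an anchor point with a 1.5 ppm proximity
radius, treated as a pseudo-window with SD = radius/2 so the same 2-SD gate
applies.  Components beyond every window are labelled `unclassified` unless
they lie beyond the β mean in the extended-shift direction (lower Cα/CO,
higher Cβ) by more than 2 SD, in which case they are `beta` with an
`extreme_beta` flag.  Classification uses centers only and is exactly
invariant under intensity rescaling.  The shipped window table is
configuration data in the spirit of standard secondary-shift compilations;
the tie-break by minimal normalized distance is a design choice.

## Synthetic data and what passing tests mean

`simulate_crosspeak` draws exact 2D Gaussians at specified centers, widths
and fractions, plus independent Gaussian pixel noise (default 1–5% of the
maximum; SNR 20 = 5%); `simulate_full_spectrum` mirrors components across
the homonuclear diagonal with independent noise per pixel and an optional
Gaussian diagonal ridge.  The fixture catalogue encodes the twelve reference
decompositions (four conditions × three residue types).  FWHMs not stated in
the reference prose (alanine/leucine monomer, leucine/glycine fibril) are
set to 3.0–3.5 ppm consistent with the stated per-condition averages.

These synthetics share the fit model's functional form, so recovery tests
validate the estimator (optimization, volume arithmetic, diagonal pairing,
classification plumbing) — they do not validate the Gaussian line-shape
assumption itself, nor do they emulate correlated (apodization-shaped)
noise, t₁-noise ridges, baseline distortion or asymmetric lines of real
processed spectra.  The statistical-coil end-to-end checks are stronger:
their input spectra are built by histogramming a sampled ensemble, so the
fitted components only recover the calibrated basin parameters if sampling,
surface evaluation, broadening, volume normalization and classification all
compose correctly.

## Problem sizes and determinism

Default ensembles use N = 10,000 conformers (sampling error on a 60% class
≈ 0.5%).  Recovery statistics in the test suite use 25 noisy replicates per
fixture and 100 replicates for the diagonal-estimator bias check.  All
randomness (sampling, noise, multistart jitter) flows through explicit
integer seeds; two runs with the same configuration and seeds are
numerically identical.

## Known limitations

- The dihedral→shift map is basin-anchored interpolation, not a trained
  predictor; absolute shifts for residues/atoms without reference anchors
  are plausible constants, not predictions.
- Axis-aligned Gaussians only: tilted or Lorentzian/Voigt line shapes are
  not modelled, matching the (center, FWHM) reporting convention but not
  every real line.
- Error bars come solely from the above/below-diagonal fit pair (n = 2);
  no bootstrap or covariance-based uncertainty is propagated.
- Inter-residue dihedral coupling and long-range structure are absent from
  the coil model by construction, which is exactly why it serves as the
  unrestrained reference.
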