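# Methods

`fovod` models visual search for objects with a foveated visual system —
high resolution at the point of gaze, coarser pooled representation in the
periphery, saccadic exploration — and compares it against the standard
non-foveated sliding-window (SW) detector built from the same features
and classifiers. This note records the models, the numerical choices, and
what the synthetic experiments do and do not show.

## Foveated visual field

The field is a simplified V1 population-receptive-field layer: pooling
regions whose diameter grows linearly with eccentricity. The fovea
(default radius 2°, at 12.5 px/°, i.e. 0.08°/px) is tiled by 8×8-pixel
regions that coincide with HoG cells (identity pooling). The periphery is
a log-polar lattice out to 10°: eccentricity rings spaced uniformly in
log eccentricity with a spacing derived from the diameter-vs-eccentricity
slope (`v1_scaling`, default 0.25, the V1 value in the physiology
literature), and polar-angle bins sized so that at the foveal border one
angular bin subtends one foveal cell (20 bins by default). Region weights
are flat-top raised-cosine windows in log-eccentricity × angle with a
transition fraction `region_overlap = 0.5`; adjacent windows form a
partition of unity before each region's weights are renormalized to sum
to 1 over its supporting cells. A region's nominal area is that of its
full raised-cosine support, which makes region area non-decreasing in
eccentricity including across the foveal border.

Published descriptions of this geometry disagree internally about the
foveal size (2° at 0.08°/px versus a 52-pixel, 4° fovea).
`FieldConfig()` uses the former; `FieldConfig.preset_52px()` provides the
latter. Small templates fit entirely inside the 52-px fovea, which is the
configuration used to exercise exact foveal/SW score equivalence.

## Features

The 31-channel HoG dialect of mixture-of-templates detectors: per-pixel
[-1, 0, 1] derivatives, orientation snapped to 18 contrast-sensitive
bins, magnitudes distributed bilinearly over 8×8-pixel cells, then
block-normalized by the l2 energy of the four 2×2-cell blocks containing
each cell with values clipped at 0.2; 18 sensitive + 9 insensitive + 4
texture channels. The feature pyramid resamples the image with
anti-aliased bilinear interpolation at scales `2^(-i/scales_per_octave)`.
The desk-scale default is 12 scales at 5 per octave (the full-scale
convention is 40 at 10 per octave; fewer scales keep the experiments
inside a desktop compute budget without changing octave coverage much).

## Retino-specific components and scoring

A component is a linear template bound to a fixed box in the visual
field. Its feature vector stacks the pooled responses (restricted to the
cells under its box and renormalized) of every pooling region covering
more than 1/5 of its weight mass, so foveal templates are
high-dimensional and far-peripheral templates may pool to only a few
values. Components are created by tiling each template shape over all
region centers; a placement survives if the mean coverage of its
intersected regions exceeds 0.75 and the box lies inside the field.

Because pooling and the template are both linear, each component is
compiled once into an equivalent cell-space template; its evaluation is
still costed at one operation per pooling region (pooling and dot product
fused), which is the source of the foveated cost savings.

The single-fixation score of an image box is the maximum of the
calibrated component responses over pyramid scales and over components
whose projected box overlaps it with IoU ≥ 0.7; scale and component are
latent. Ties break toward the lowest scale index, then the lowest
component id.

Templates carry a background **context ring** (`context_frac = 0.15` of
the object size per side): positives are warped including that margin and
reported boxes shrink it away. Without context, crisp partial views of an
object outrank the blurred whole-object view at its matching scale — the
dominant failure mode of a whitened-template detector with no
hard-negative mining.

## Training (latent-LDA)

Per-template LDA directions with a jointly calibrated affine transform:

1. **Stationary background statistics.** Mean cell feature and spatial
   autocovariance `Γ(dy, dx)` up to the template extent, estimated from
   whole training scenes. The biased (zero-padded, common lag-0 divisor)
   estimator on centered features is used because the resulting
   block-Toeplitz covariance is positive semidefinite by construction; a
   ridge of `0.01 ×` the mean channel variance is added. Scenes rather
   than empty backgrounds feed the estimate so that the whitening learns
   edge statistics, as it would from natural images.
2. **Template shapes.** Seeded k-means (k = 2) on the log aspect ratio of
   training boxes; each cluster's geometric-mean box (plus context) is
   scaled to an 80-px budget and snapped to whole cells.
3. **Foveal templates.** `w = Σ⁻¹(μ_pos − μ_neg)` solved by Cholesky,
   with `μ_pos` the mean HoG of warped positives and `μ_neg` the tiled
   stationary mean. Directions are normalized to unit norm — the length
   of an LDA discriminant is arbitrary and is absorbed by the
   calibration, which keeps the calibration objective well-scaled.
4. **Peripheral templates.** Covariances and means are pushed through the
   pooling operator: `Σ_t = P Σ P^T (+ ridge)`, `μ_t = P μ`; no
   per-template estimation. Fully foveal components reuse the (permuted)
   foveal solution exactly.
5. **Calibration.** Per-template scale `α_t ≥ 0` and bias `β_t` minimize
   `½Σ(α² + β²) + C·(hinge terms)` where each positive contributes one
   hinge per feasible aligned placement of each template (the model must
   detect the example from every feasible fixation), and each template
   contributes a background-mean hinge weighted to balance its positive
   count. `C = 1` (the natural scale with unit-norm directions).
   Coordinate descent alternates the latent scale choice with a projected
   subgradient solve (per-group normalized steps, best iterate kept per
   group — the objective is separable across calibration groups), so the
   outer objective is non-increasing by construction and an increase
   raises an error. Calibration is shared among the fully foveal
   components of a shape, whose LDA directions are identical; this also
   makes the foveal/SW equivalence exact.

## Multi-fixation search

The sigmoid of a raw score is the posterior probability of target
presence given one fixation; under conditional independence across
fixations the log posterior ratio of a box is the **sum over fixations**
of its single-fixation scores. Per fixation a box receives exactly one
term (the latent max); an observation identical to one already integrated
(same component and scale landing on the same box, as happens when nearby
fixations snap to the same cell at coarse scales) is not counted twice.
Accumulator slots are canonical box keys — quarter-octave size bins and
quarter-box-size position bins — so that a later foveal look at a
peripherally flagged location combines with (confirms or cancels) the
earlier evidence.

The MAP strategy saccades to the center of the uninhibited box with the
highest accumulated score. Inhibition of return acts twice: a 2°-radius
disc around every previous fixation is excluded from selection, and each
previous fixation lying inside a candidate box reduces that box's
selection priority (`ior_score_penalty = 2`, roughly two strong
observations) — already-foveated locations should not keep attracting the
eye. The final perceptual decision uses the unmodified integrated scores,
followed by non-maxima suppression at IoU > 0.5. The RAND baseline draws
fixations uniformly over the uninhibited image area: a no-guidance null
that carries no information about scene content or its spatial
statistics.

## Sliding-window baseline and cost ledger

SW evaluates each shape's full-resolution calibrated foveal template at
every cell of every pyramid level. The ledger counts dot-product
operations in spatial-cell units: `P×K` per SW evaluation (a 6×8-cell
template costs 48), one per covered pooling region per foveated
evaluation; feature extraction is excluded from both. Reported costs are
normalized so the SW total is 100.

## Saliency

Gabor energy (4 scales one octave apart from wavelength 4 px, 8
orientations, quadrature, zero-mean kernels) is sum-pooled per
orientation into 8-px cells. Iso-orientation suppression subtracts the
mean same-orientation response of the 8 nearest cells (non-foveated) or,
in the periphery, of the 4 nearest pooling regions; saliency is the
maximum over orientations (a `sum` combination is available). Cells whose
receptive fields extend past the image border are excluded in both
models. The foveated model saccades to the current saliency maximum under
2° inhibition of return; each location keeps the value observed at its
smallest eccentricity so far (the finest available estimate — the
integration rule here is an open design choice; mean/sum alternatives
were considered and rejected as mixing estimates of different fidelity).
Agreement is the distance in degrees between the foveated and
non-foveated top locations; cost is the ratio of cumulative suppression
operations.

## Synthetic study conditions

The generator renders two glyph families ("wedge": solid triangles;
"cross": plus/X forms), each with two viewpoints of reciprocal aspect
ratio so the two-shape mixture is exercised, composited on 1/f noise.
Defaults (frozen as the study conditions): 320×320-px scenes; 0, 1 or 2
objects with probabilities 0.25/0.35/0.40; mean normalized box area 0.2
with lognormal jitter 0.15; placement Gaussian with σ = 0.25 of the image
size (a central bias comparable to common benchmark statistics); noise
amplitude 0.07 under glyphs of intensity 1.0 on a 0.45 background. With
the 10°-radius field this reproduces the geometry that matters: the image
is much larger than the field, objects cluster centrally, and a 5-
fixation budget covers only part of the scene at high resolution.
Pop-out images for the saliency study are 512×512 orientation-contrast
patches (orthogonal orientations, shared phase, 24-px patch radius)
placed within reach of the initial central fixation.

What the generator does **not** emulate: photometric clutter, occlusion,
within-class appearance variability beyond two rigid viewpoints, or
object/background texture confusability. Passing the synthetic suite
shows that the machinery (pooling, training, integration, guidance, cost
accounting) behaves as designed, not that the detector would reach any
particular accuracy on natural images; the published full-scale
benchmark numbers live in `fovod.reference` for arithmetic and regression
only.

## Numerical choices and degenerate inputs

- HoG stabilizer ε = 1e-4 inside the block norm; clipping at 0.2.
- Covariance ridge 1% of mean channel variance; Cholesky failures raise
  a `CovarianceError` rather than silently pseudo-inverting.
- Calibration: 5 outer iterations (tolerance 1e-3 relative), 200 inner
  subgradient steps at `0.5/√k`.
- Fixations snap to the containing HoG cell (floor at boundaries).
- Boxes are `(w, h, x, y)`, 0-based, half-open; field boxes are snapped
  to the cell grid.
- Degenerate inputs (images under two cells, empty ground truth, fovea
  larger than field, all candidates inhibited) raise typed errors.

## Known limitations

- The MAP-over-RAND advantage at desk scale is real but small (about one
  mAP point under the default conditions), mirroring the modest gap of
  the full-scale study; with very easy scenes every strategy saturates
  and the ordering can invert within seed noise.
- Training never mines hard negatives (by design); discriminability
  rests entirely on the whitening statistics and the context ring.
- The nonlinear second pooling stage (V2-like) and richer foveal
  classifiers are out of scope; the periphery and fovea share the same
  linear template family.
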