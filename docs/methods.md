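# Methods

This note documents the models, conventions and numerical choices behind
`callothick`, and what the synthetic validation does and does not show
about real data.

## Handedness scoring

The laterality quotient is `LQ = 100 (R − L)/(R + L)` over the nine manual
EHI items, with the "writing" item's points counted twice.  The five-level
answer scale is quantified with the conventional point table

| answer | (L, R) |
|---|---|
| always left | (2, 0) |
| usually left | (1, 0) |
| no preference | (1, 1) |
| usually right | (0, 1) |
| always right | (0, 2) |

Crediting one point per hand for "no preference" guarantees `R + L > 0`
and keeps LQ in [−100, 100].  The exact quantification behind published
nine-item quotients is not standardised across groups, so the table is a
configurable design choice (`POINT_MAPPINGS`); a "strict" variant that
discards neutral answers is provided, under which an all-neutral pattern
has no defined quotient and raises.  Whether double weighting doubles the
writing item's points or duplicates the item is immaterial: the quotient
is a ratio, and both readings multiply the same contribution by two.

Classifier boundaries (|LQ| ≥ 80, and the threshold-sweep cut-offs) are
evaluated on the integer point sums (`LQ ≥ 80 ⇔ R ≥ 9L`), never on the
floating-point quotient, so boundary participants cannot be misclassified
by rounding.

The qualitative consistency rule is deliberately asymmetric, following the
operationalisation it reproduces: a consistent right-hander has no
left-preferent item *and* fewer than five of nine neutral answers, while a
consistent left-hander is any non-cRH pattern without a right-preferent
item, with no neutral-count clause.  Consequently mirroring every answer
maps cRH patterns to cLH, but neutral-heavy cLH patterns mirror to MH; the
property tests assert exactly this asymmetric form.

## Morphometry

**Conventions.** Canonical grids put anterior at low column index and
dorsal at low row index; declared orientations (including transposed axes)
are normalised first.  Pixel `(i, j)` has centre `((j+0.5)·col_mm,
(i+0.5)·row_mm)`; larger `y` is more ventral.

**Cleanup.** Manual mask editing is replaced by a deterministic rule: keep
the largest 4-connected component and fill interior holes, logging both
actions.  Area is the foreground pixel count times the pixel area
(0.49 mm² at the 0.7 × 0.7 mm study resolution), computed after cleanup.

**Outline.** Border pixels (foreground with a background 4-neighbour) are
ordered by Moore neighbour tracing; the tracer is a deterministic map on
(pixel, backtrack) states and the closed boundary is its state cycle.  The
vertex chain of pixel centres systematically underestimates the extent of
the pixel region by about half a pixel per side, so vertices are then
offset half a pixel outward along the local normal, approximating the
boundary of the pixel union.  `boundary_offset=0` restores raw centres;
the default is what makes a 6 mm band measure 6 mm rather than ≈5.3 mm at
0.7 mm pixels.

**Landmarks.** The rostrum tip is the posterior-most outline point within
the anterior–ventral quadrant of the bounding box (the rostrum hook points
posteriorly beneath the genu); the anterior fraction (default 0.5) is
configurable because "anterior half" admits several readings.  A candidate
hugging the quadrant's posterior cutoff (within 1 mm) means there is no
in-bend — convex shapes such as rectangles are rejected with a landmark
error.  The splenium base is the ventral-most point of the posterior half.
Manual overrides (coordinates mapped to the nearest outline vertex) mirror
the manual-correction step of segmentation protocols and are recorded in
provenance.

**Profile.** The outline is split at the two landmarks; the arc containing
the most dorsal point is the dorsal outline.  Both arcs are resampled to
100 points at equal arc-length spacing (linear interpolation, endpoints
preserved) running rostrum → splenium, so segment 1 ≈ genu/rostrum and
segment 100 ≈ splenium, matching the anterior-to-posterior layout of
published segment maps.  The midline is the pointwise mean of the paired
resampled points.  Tangents come from centred differences on a 5-point
moving-average-smoothed midline (one-sided at the termini, which are
flagged `terminal`); raw resampled midlines give noisy normals at pixel
resolution, hence the smoothing default.  Thickness is measured against
the full-resolution arcs (more accurate than the 100-point resampling; the
resampled alternative sits behind `use_full_resolution=False`).

**Degenerate cuts.** An orthogonal cut is accepted only if (a) both
outlines are intersected, (b) the two nearest intersections lie on
opposite sides of the midline point, and (c) the cut length is at most 1.5
times the sum of the nearest-outline distances on the two sides.  Near a
shared end cap the two arcs run almost parallel through the same pixels
and conditions (b)/(c) fail; such segments fall back to the nearest-point
distance and are flagged `fallback` and enumerated in provenance.  On the
flat-cut half-annulus phantom this flags roughly the first and last ten
segments — the price of splitting a capped band at its cap midpoints — and
every unflagged segment then measures the true 6 mm thickness within one
pixel.  Flagged values should be treated as unreliable, exactly as
terminal segments are.

## Brain-size normalization

FBV (mm³) is raised to 2/3 for area analyses and 1/3 for thickness
analyses so the covariate has the same physical dimension as the dependent
measure.  Relative measures divide by the converted FBV; the global scale
constant (default 100) only sets the magnitude of the unitless relative
area (≈6.8 at a 1.0×10⁶ mm³ forebrain) and cancels from every F, p and d —
asserted by test.

## Group statistics

The model is `y ~ group * sex (+ converted FBV)`, Type III sums of squares
under sum-to-zero contrasts — the convention under which estimated
marginal means are customarily computed in unbalanced two-factor designs.
EMMs are model predictions averaged with equal weight over sex at the
grand covariate mean (the standard ANCOVA convention).  Cohen's *d* is the
EMM difference divided by the model residual SD; the residual SD rather
than a pooled raw SD because the means themselves are model-based (the two
differ slightly in unbalanced designs).  The 95% CI is a normal
approximation, `d ± 1.96·se(Δ)/σ̂`, treating σ̂ as fixed; at the sample
sizes this package targets (hundreds per group) the extra variance from
estimating σ is negligible relative to the ±0.02 documented tolerance.
Sign conventions: group *d* < 0 means the right-handed group (cRH/dRH) has
the larger mean; sex *d* is female − male.  The interaction is summarised
as η² = SS(interaction)/SS(total).

A constant dependent returns a flagged zero-variance result (F = 0, p = 1)
instead of erroring, so segment loops and sweeps degrade gracefully.

Segment-wise analyses share one design matrix across the 100 segments, so
they are fitted in a single vectorized pass (±1 factor coding, partial F
by column deletion); this path is cross-checked against the
statsmodels-based single fit to 10⁻⁸ in the test suite.  Group-effect
p-values are Benjamini–Hochberg adjusted at q = 0.05 across the 100
segments of one analysis (one comparison × one dependent-variable
variant); families are never pooled across analyses.  Segments nominally
significant at α = 0.05 are flagged separately, and every FDR-significant
segment is by construction also nominally significant (asserted at run
time).  Age is deliberately not a covariate: in the young-adult range the
cohort design targets, age explains no substantial callosal variance.

## Synthetic cohorts

The generator encodes the study conditions the analysis assumes:

* latent handedness mixture 0.60 / 0.365 / 0.035 (consistent right, mixed,
  consistent left), female fraction 581/1057;
* class-conditional answer emissions (documented in `CLASS_EMISSIONS`)
  that produce the J-shaped LQ distribution; a bounded rejection step
  redraws patterns whose qualitative label disagrees with the latent
  class, making class recovery exact while keeping the emission
  distributions as documented;
* callosal area 691.3 ± 94.1 mm² with a male-larger shift of d = 0.23;
* FBV ≈ 1.03×10⁶ mm³ with FBV^(2/3) SD 480 (≈5% CV), a male-larger
  component beyond the shared-size channel, and an in-sample FBV–area r²
  of exactly 0.13 by construction (the noise component is orthogonalised
  against area and sex);
* thickness profiles from a genu/splenium-bulged template scaled by each
  participant's relative callosal size plus spatially smooth subject noise
  and white measurement noise (per-segment SD ≈ 1.1 mm), floored at
  0.3 mm.

What this does *not* emulate: real answer-pattern heterogeneity (the
generator's qualitative and quantitative classifications disagree for only
≈4% of participants, versus >25% in real cohorts), anatomical shape
variability beyond geometric similarity scaling, spatially structured
segmentation error, and any true handedness effect (the default cohort is
null).  Passing tests therefore demonstrate that the pipeline measures
what it claims on known geometry and controls its error rates under its
model assumptions — not that those assumptions hold in any given MRI
sample.

The phantom is an arch-shaped cubic-spline midline with an anterior hook,
thickened by a prescribed t(s) and rasterized by distance thresholding
(round end caps; recorded analytic area includes the two half-disc caps).
Bands thicker than twice the local curvature radius are rejected as
self-intersecting.  Because the measured midline's arc parameterisation
differs slightly from the analytic one (the caps extend it), ground-truth
comparisons use `PhantomTruth.thickness_at_points`, which evaluates t at
the arc position nearest each measured midline point.

## Problem sizes and calibration checks

The validation suites use: exhaustive 5⁴ answer-pattern enumeration
against brute-force classifier oracles; a 0.7 mm half-annulus phantom
(area within 2%, profile within one pixel on unflagged segments) with
resolution convergence checked at 1.4/0.7/0.35 mm; a moment-matched
cohort (EMMs 694 vs 690, residual SD 94, cells 636/385) reproducing
d = −0.04 with CI ≈ (−0.17, 0.09); 2,000 null cohorts of n = 200 for the
5% type-I error and 500 for the family-wise BH rate (which sits below 5%
because the smooth profiles make the step-up conservative under positive
dependence — the suite accepts 1–9%); and d = 0.5 injected over segments
40–60 recovered at n = 500/group (detection) and n = 2,000/group
(|d̂ − 0.5| < 0.1).  These sizes keep the full suite around half a minute
on one CPU while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* Thickness at terminal and flagged segments is ill-defined by
  construction; downstream statistics include them, so segment-map
  conclusions about the extreme rostrum/splenium tips should be read with
  the flags in hand.
* The rostrum-tip rule is bounding-box based; unusually shaped masks may
  need the manual override.
* The CI for Cohen's *d* ignores the sampling variability of σ̂ (see
  above) and the d-scale noncentrality; for very small cells a
  noncentral-t interval would be preferable.
* `LQRecord.from_lq` reconstructs point sums from a bare quotient for
  classification of externally supplied LQ values; values not expressible
  at the chosen denominator are rounded through a rational approximation.
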