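# Methods

## Metrics

For binary masks of matching shape we write `X`, `Y` for the sets of
positive elements.  All four coefficients live in `[0, 1]` and are
symmetric in their arguments.

**DSC** is `2|X∩Y|/(|X|+|Y|)`.

**WDC** fixes an integer `n ≥ 0` and weights `0 < νₙ < … < ν₁ < 1`, and
builds nested environments `X = X₀ ⊆ X₁ ⊆ … ⊆ Xₙ` where `Xᵢ` is `Xᵢ₋₁`
dilated once by the structuring element.  The implementation computes the
weight map (1 on `X`, `νᵢ` on the ring `Xᵢ∖Xᵢ₋₁`, 0 elsewhere) for each
mask and returns `2s/(s_X+s_Y)` with `s` the sum of the element-wise
minimum map.  A literal set-formulation (`wdc_setform`) is retained and the
two are asserted to agree to 1e-12 in the tests; the agreement is an
algebraic identity, so any disagreement indicates a coding bug, not a
numerical issue.

**LDC** is `2|X∩Y|/(|X|+|Y|+|X∖Y*|+|Y∖X*|)` with `X* = X_k`.  Since the
added terms are non-negative, LDC ≤ DSC always, with equality exactly when
both loss terms are empty.

**Hybrid WDC** returns the WDC when DSC > 0 and 0 otherwise.  WDC alone can
reward a prediction that merely approaches the reference; when comparing
predictions with no true overlap that behaviour inverts the intuitive
ranking, and the hybrid rule removes it.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_env` | 3 | number of dilation environments (elements of distance) |
| `weights` | (0.7, 0.5, 0.3) | ring weights ν₁…νₙ, dividing (0,1) evenly |
| `connectivity` | edge | 4-neighborhood (2-D) / 6-neighborhood (3-D); `full` adds diagonals |
| `ldc_env_index` | 3 | `k` in `X* = X_k` for the LDC loss term |

Weight validation is strict — non-decreasing sequences or values outside
(0, 1) are rejected — because the `[0, 1]` range of WDC depends on
`νₙ < … < ν₁ < 1`.  WDC values computed under different parameter sets are
not comparable; the appropriate magnitudes depend on image resolution and
how far annotators plausibly disagree (the defaults correspond to
tolerating disagreements of a few pixels/voxels).

### Numerical and boundary choices

* Dilations are clipped at the array border: environments never leave the
  grid.  This matches standard binary-dilation behaviour.
* 3-D dilation treats voxels as isotropic (one step = one voxel along any
  axis).  NIfTI voxel spacing is read and logged, with a warning when
  anisotropic, but does not alter the metrics.
* Empty-mask semantics: both masks empty → 1.0 (flagged `both_empty`);
  exactly one empty → 0.0 (flagged `one_empty`).  The both-empty case is a
  total-function choice — perfect agreement plus a degeneracy flag is the
  least surprising completion.
* Weight sums accumulate in double precision; equality tests in the suite
  use absolute tolerance 1e-12.

## Preprocessing

`resize_mask` interpolates a 2-D mask to the target shape as a real field
and binarizes with a strict `> threshold` comparison (default 0.25).  For
integer downscale factors the field is an exact block mean, making the
threshold a fractional-coverage rule (an output pixel is positive when more
than a quarter of its source pixels were); non-integer factors use bilinear
interpolation.  Area averaging is our choice — nearest-neighbour or spline
schemes would change which boundary pixels survive — and tests use
coverage values away from the threshold boundary.  `min_positive_filter`
(default minimum 6 positives) and `stack_slices` (slice index on axis 0)
complete the pipeline.  Intensity-image preprocessing is out of scope; only
masks are handled.

## Synthetic validation experiment

Phantom references are unions of randomly placed filled ellipses
(ellipsoids in 3-D) — adequate stand-ins for tumor masks because all four
metrics depend only on set geometry, not texture.  Defaults: one blob with
semi-axes drawn from 3–8 elements on a 64×64 grid, mirroring small lesions
occupying a few percent of a cropped field of view; every phantom has at
least 6 positives so it would pass the inclusion filter.

`degrade` manufactures a prediction for a target quality class:

* **4 (excellent):** flip a random subset (up to ~12% of `|X|`) of
  one-step boundary sites; detached specks are removed so no fully-FP
  component arises.
* **3 (good):** dilate the mask two steps on a random half-plane and erode
  one step on the rest, so the outlines clearly intersect and the areas
  mostly overlap, with no fully-FP/FN components.
* **2 (decent):** uniform over-/under-segmentation by 2–3 steps (outlines
  nested, nowhere touching), or the union with one substantial disjoint
  component placed more than 7 dilation steps away.
* **1 (poor):** translate the mask until only a minority (≤ 45%) of the
  smaller area overlaps; sometimes extra small disjoint components are
  added.
* **0 (fully wrong):** relocate the whole mask with a clearance above 7
  dilation steps (guaranteeing WDC = 0 under the defaults), or an
  all-negative prediction; relocation falls back to the empty prediction on
  grids too small to clear the gap.

`rubric_score` inverts this with a decision ladder evaluated top-down:
no overlap → 0; overlap below half the smaller mask → 1; any connected
component of either mask with zero overlap of the other ("fully FP/FN") →
2; all errors inside a one-step boundary band and `|XΔY| ≤ 0.15|X|` → 4;
one outline strictly nested in the other with the boundaries nowhere
touching → 2; otherwise → 3.  The constants (majority fraction 0.5, band
width 1, near-perfect budget 0.15) operationalize qualitative rubric
wording and are exposed on `RubricConfig`; they are modelling choices, not
claims about how human raters decide.  On seeded suites the rubric recovers
the generating class for ≥ 90% of pairs per class; the residual mismatches
are geometric edge cases (e.g. a heavy class-4 noise draw crossing the
near-perfect budget).

What passing this experiment shows — and does not.  The generator emulates
the *geometry* of graded segmentation failures (boundary noise, systematic
over/under-segmentation, dislocation, spurious components).  It does not
emulate PET intensity statistics, partial-volume blur, anatomy-correlated
error patterns, or rater disagreement; agreement between the metric
ordering here (Spearman of WDC with scores above that of DSC, and smaller
within-class spread of WDC in the two best classes) and the corresponding
result on clinical data is a qualitative, not quantitative, reproduction.

## Statistics

* Spearman rank correlation uses average ranks with tie correction; the
  two-sided p-value comes from the t-approximation with n−2 degrees of
  freedom, adequate at the sample sizes used here (~200).  An exact
  permutation p-value is available for n ≤ 10.
* The variance-equality test is the classical two-sided F-test:
  `F = s²_a/s²_b` (n−1 denominators), `p = 2·min(P(F≤f), P(F≥f))` capped at
  1, with a 5% significance flag.  It is undefined (raises) when both
  samples have zero variance, as happens in a score class where two metrics
  are identically 0.
* FDR correction is Benjamini–Hochberg step-up with monotonicity
  enforcement, computed via `statsmodels.multipletests`; the family is all
  per-class metric-pair F-tests in a report.
* Class summaries report min/mean/max and the n−1 standard deviation; a
  single-member class reports sd as NaN, and empty classes are omitted.

## Problem sizes

The shipped experiments use 200 scored pairs on 64×64 grids and
formulation-equivalence suites of 100 random pairs (16×16 and 8×8×8),
sizes at which every reported quantity is stable across seeds while the
whole battery runs in seconds.

## Known limitations

* The rubric is a programmatic surrogate; its thresholds were not fitted
  to human raters.
* WDC values are comparable only within one parameter set; no guidance is
  provided for choosing weights on new resolutions beyond the qualitative
  considerations above.
* Anisotropic voxel spacing is ignored by the metrics (a warning is
  logged); strongly anisotropic volumes would need spacing-aware
  environments.
* Multi-class and probabilistic (soft) masks, surface/boundary metrics,
  and differentiable training losses are out of scope.
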