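# envdice

Distance-aware Dice coefficients for evaluating 2-D and 3-D binary
segmentation masks.

## Why

The Sørensen–Dice similarity coefficient,

```
DSC = 2|X ∩ Y| / (|X| + |Y|),
```

is the standard score for comparing a predicted segment `Y` against a
reference `X`, but it only counts misplaced elements — it ignores *where*
they are.  For imaging modalities without sharp object boundaries (PET
tumors blurred by the partial-volume effect, where even two experienced
radiologists draw different outlines), a prediction whose errors hug the
reference boundary and one whose errors are far away can receive the same
DSC, although a human rater would call the first one much better.

`envdice` implements two modifications that fold distance into a single
overlap score, for researchers evaluating medical-image segmentation
(human- or CNN-generated masks):

* **Weighted Dice coefficient (WDC).**  Surround each mask with `n` nested
  morphological dilations (`X = X₀ ⊆ X₁ ⊆ … ⊆ Xₙ`, one dilation step per
  level) carrying strictly decreasing weights `1 > ν₁ > … > νₙ > 0`:

  ```
  WDC = 2 (|X∩Y| + Σᵢ νᵢ |XᵢᶜYᵢ ring overlaps|) / (s_X + s_Y)
  ```

  or, equivalently and efficiently: build a weight map per mask (1 on the
  mask, `νᵢ` on the i-th dilation ring, 0 outside `Xₙ`), let `s_X`, `s_Y`
  be their totals and `s` the total of their element-wise minimum; then
  `WDC = 2s / (s_X + s_Y)`.  Near-misses earn partial credit.

* **Loss-based Dice coefficient (LDC).**  Keep the DSC numerator but add to
  the denominator the elements of each mask falling outside the other
  mask's dilated environment `X* = Xₖ`:

  ```
  LDC = 2|X ∩ Y| / (|X| + |Y| + |X \ Y*| + |Y \ X*|) ≤ DSC.
  ```

* **Hybrid WDC**: WDC set to 0 whenever DSC is 0, removing the small
  positive values WDC can give to predictions that merely *approach* the
  reference without touching it.

Defaults: `n = 3`, weights `(0.7, 0.5, 0.3)`, edge-sharing connectivity
(4-neighborhood in 2-D, 6-neighborhood in 3-D), `X* = X₃`.

The package also ships the surrounding machinery: mask preprocessing
(threshold resizing, minimum-positive filtering, slice stacking), a seeded
synthetic-phantom generator with graded degradations and a programmatic
0–4 quality rubric, and the statistics used to validate a metric against
ordinal quality scores (Spearman rank correlation, per-class summaries,
two-sided F-tests of equal variances with Benjamini–Hochberg FDR
correction).

## Worked example

Two 3×3 squares on a 10×10 grid overlapping in exactly 2 pixels:

```python
import numpy as np
from envdice import dsc, wdc_fast, ldc, hybrid_wdc

x = np.zeros((10, 10), bool); x[1:4, 1:4] = True
y = np.zeros((10, 10), bool); y[2:5, 3:6] = True

for metric in (dsc, wdc_fast, ldc, hybrid_wdc):
    print(metric.__name__, f"{metric(x, y).value:.3f}")
```

prints

```
dsc 0.222
wdc_fast 0.637
ldc 0.222
hybrid_wdc 0.637
```

DSC sees only 2 shared pixels out of 18 (`2·2/18 = 0.222`).  WDC is much
higher because the two squares are close: most of each mask lies inside the
other's weighted environment.  LDC equals DSC here since no pixel of either
mask is more than 3 dilation steps from the other mask.

The same computation from the shell:

```
envdice eval reference.png prediction.png
envdice batch manifest.csv --report report.json
envdice simulate --n-pairs 200 --seed 1 --out sim.json
envdice fixtures out_dir --n-pairs 10 --seed 1
```

where `manifest.csv` has columns `id, reference_path, prediction_path` and
optionally `score` (ordinal 0–4), which switches on the statistical report.
Masks are read from PNG/TIFF (2-D) or NIfTI (3-D); any nonzero value is
positive.  3-D arrays use 0-based (slice, row, column) indexing.

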