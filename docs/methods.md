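# Methods

## Pixel classification

All stain segmentation works in HSV space. The region of interest (ROI)
is tissue versus background: a pixel is background iff S < 0.08 **and**
V > 0.90 (`roi.bg_sat_max`, `roi.bg_val_min`) — slide glass is bright and
nearly achromatic, while both counterstained and DAB-stained tissue are
chromatic or darker. This is deliberately a tissue/background split only;
no membrane-specific filtering is attempted, because the features
downstream are themselves membrane-pattern summaries.

A pixel is *stained* at threshold t iff it is in the ROI, its hue lies in
the DAB band [10°, 50°] (`stain.hue_low_deg/high_deg`; bands may wrap
through 0°, membership is modulo 360), its value is ≤ 0.98
(`stain.val_max`, glare exclusion), and S ≥ t. The inclusive comparison
makes the nesting contract exact: stain(t₂) ⊆ stain(t₁) whenever t₂ ≥ t₁,
which in turn guarantees every characteristic curve is non-increasing —
an invariant, not a statistical tendency.

Colour conversions (RGB→HSV, sRGB→CIE-Lab under D65, HSV→RGB in the
generator) use scikit-image; tests cross-check them against `colorsys`
and hand-rolled sRGB→XYZ→Lab formulas.

Tiles whose ROI fraction falls below 0.40 (`tiles.min_roi_frac`) are
dropped before feature extraction, mirroring the usual whole-slide tiling
step that discards mostly-glass patches; the boundary is kept (≥).

## Characteristic curves

p(t) = 100·|stain(t)|/|ROI| on the grid 0.10…0.50 step 0.02 (21 points).
A tile with an empty ROI raises an error rather than returning 0/0. The
area statistic is the trapezoidal integral over the grid — simple,
monotone under pointwise curve dominance, and at the curve's own
resolution (no interpolation).

Downsampling to n points: for the default 10-of-21 case (2n = L−1) every
second grid point is taken starting at the first — the lowest threshold
carries the most staining information — giving indices 0, 2, …, 18; any
other n uses evenly spaced indices round(k·(L−1)/(n−1)), which keeps both
endpoints (n = 2 yields exactly the endpoints, n = L the identity). The
two regimes exist because the even-spacing formula would scatter the
10-point selection irregularly (0, 2, 4, 7, …), whereas uniform stride
preserves the grid's spacing.

Polynomial refits of the curve are deliberately not offered; sampled
points are the representation.

## Uniform local binary patterns

At each grid threshold the texture substrate is the binary stain mask
(configurable to the saturation channel masked by the stain mask,
`ulbp.substrate`). For every interior pixel whose centre lies in the ROI,
the 8 radius-1 neighbours are compared with ≥ (ties count as 1, the
standard convention); a pattern is uniform iff its circular bit sequence
has at most two 0↔1 transitions, and uniform patterns are binned by
popcount into U0…U8, with non-uniform patterns pooled separately so the
histogram sums to 1 and normalisation is testable. Border pixels are
never centres; neighbours may lie outside the ROI.

On a binary mask this has a crisp reading: a stained centre with m
stained neighbours lands in U_m, while every unstained centre ties all
its ≤-valued neighbours and lands in U8 unless adjacent staining lifts
some bits. U8 therefore absorbs featureless regions and is discarded. As
t rises past the strongest staining the mask empties and U0…U7 decay to
zero — asserted as the decay property rather than monotonicity, which the
curves do not have.

Curve reduction is two-fold, both steps exploiting geometry: (i) each
retained curve is sampled at grid indices {0, 5, 10, 15, 20} (low
curvature makes 5 points sufficient; least-squares slope/intercept fits
are computed as diagnostics but not used as features, since sampled
points preserved accuracy better); (ii) only U0…U4 are kept, because the
pairwise similarity analysis (mean per-sample Pearson correlation,
constant curves skipped per pair, redundancy threshold 0.95,
`ulbp.similarity_threshold`) shows the higher components largely
duplicate retained ones. The fixed U0…U4 selection is applied regardless
of which exact pairs a given dataset flags — the reduction is part of the
descriptor definition, not refitted per dataset.

## Connectedness

100 × (largest connected component of stain(0.10)) / |ROI|, with
8-connectivity by default: membrane staining forms thin, often diagonal
strands that 4-adjacency would fragment. The denominator is the ROI pixel
count, not the tile area, so the measure is comparable across tiles with
different tissue coverage. It is bounded above by p(0.10) by construction.
Components are labelled with `scipy.ndimage.label`; tests compare against
an independent breadth-first flood fill.

## Histogram statistics

The tile is converted to CIE-Lab and b\* is mapped to grey levels by
g = clamp(round(b\* + 128), 0, 255), which covers the sRGB-attainable b\*
range with integer bins. The histogram is taken over the whole tile (not
the ROI): background contributes a fixed near-neutral peak, and the
statistics respond to how staining widens the blue–yellow distribution.
Entropy uses base-2 logarithms (bits; any fixed base only rescales) with
0·log 0 := 0; energy is Σ pᵢ². Bounds: 0 ≤ H ≤ 8, 1/256 ≤ E ≤ 1.

## Feature vector and classification

The 38 columns are fixed:
`cc_00..cc_09, ulbp_00..ulbp_24, conn, entropy, energy` (10 + 25 + 1 + 2).
Curve area, line fits and the full 168-value ULBP set are diagnostics,
emitted only on request. CSV exports carry a provenance comment line
(config hash + seed) and 9-significant-digit floats, so re-running with
the same inputs reproduces files bit-for-bit.

Learners are deliberately plain — the features, not the classifier, are
the object of study: one-vs-rest logistic regression (L2, C = 1) and an
RBF-kernel SVM (C = 1, scale gamma), both on z-scored features with the
scaler fitted inside the training data of each split or fold (no
leakage). Prediction is the argmax of the four binary decision scores;
numpy's argmax resolves ties to the lowest class index. Protocols:
stratified 70/30 holdout, and stratified k-fold CV (k = 5) repeated with
fresh shuffles (50 by default), each trial pooling its out-of-fold
predictions into one accuracy; the report carries the per-trial series
and the final trial's confusion matrix (rows = actual, columns =
predicted; precision column-wise, recall row-wise). No class reweighting
is applied — the intended datasets are balanced by construction. All
randomness derives from a single seed via `numpy.random.SeedSequence`.

## Synthetic tile generator

The generator emulates exactly the statistics the features respond to,
per class:

| class | stain_frac | sat_mean | sat_spread | connectivity_scale (px) |
|-------|-----------:|---------:|-----------:|------------------------:|
| 0     | 0.05       | 0.20     | 0.05       | 4                        |
| 1+    | 0.12       | 0.25     | 0.06       | 6                        |
| 2+    | 0.30       | 0.50     | 0.10       | 10                       |
| 3+    | 0.55       | 0.75     | 0.07       | 16                       |

Construction: (1) a background field (Gaussian-filtered uniform noise,
correlation length size/4 — glass and lumen form a few large contiguous
areas, and smaller background blobs would unrealistically carve the
stained region apart) is thresholded at the exact 0.25 quantile to paint
25% of the tile near-white; (2) a stain field at the class's correlation
length is thresholded at the exact quantile giving `stain_frac` of the
ROI, so the achieved fraction is pinned by construction; (3) stained
pixels get hue ~ N(30°, 7°) (DAB brown), saturation ~ clipped
N(sat_mean, sat_spread), value ~ N(0.55, 0.05); (4) remaining tissue gets
a bluish counterstain (hue ~ N(240°, 10°), S ≈ 0.25, V ≈ 0.75);
(5) background pixels are near-white (S < 0.04, V > 0.94). Per-tile
streams derive from SeedSequence(master, (class, index)), so datasets are
reproducible and tiles decoupled; identical inputs give byte-identical
PNGs.

The class parameters were chosen once to realise the clinical curve-shape
semantics: score 0 below the 10% line everywhere; 1+ above it only on an
initial segment (with stain_frac 0.15 / sat_mean 0.30 the curve would
stay above 10% until t ≈ 0.33, hence the lower 0.12 / 0.25); 2+ spanning
a wide intermediate range; 3+ above 30% everywhere with a dominant
connected component. Saturation means rise with class because staining
intensity does.

The default tile size is 256 × 256 (64 minimum). All features are
per-ROI fractions and therefore scale-free; 256 was chosen as the
package's standard problem size for dataset-level experiments, and the
ground-truth consistency contract (achieved stain fraction at t = 0.10
within 2 percentage points of target) holds from 256 up.

What the generator does **not** emulate: nuclei and cell-level membrane
geometry, stain deconvolution physics, chromatic aberration, focus and
compression artefacts, and the label noise of real pathologist scoring.
Consequently the synthetic classes are close to linearly separable, and
classification results on them validate the pipeline's plumbing and the
features' ordinal behaviour — not clinical accuracy. Statistical
acceptance checks run on the default dataset of 200 tiles per class
(seed 1), with 10 CV repeats; these sizes are the package's chosen
standard experiment, small enough to run anywhere.

## Numerical and degenerate-input choices

- Empty ROI: explicit error everywhere a denominator would be |ROI|
  (curves, connectedness, feature assembly); never a silent 0/0.
- Empty ULBP evaluation set: all-zero histogram flagged `empty`.
- Constant curves in the similarity analysis: skipped per pair
  (correlation undefined); a pair with no valid samples is NaN, never 0.
  Constancy is tested with a 1e-12 tolerance on the standard deviation
  because an exactly repeated float value can still carry ~1e-17 roundoff.
- Curve values are validated to [0, 100], ULBP fractions to [0, 1] with
  1e-9 slack for float arithmetic.
- Hue of achromatic pixels is 0 by convention; alpha channels are dropped
  with a warning on read.

## Known limitations

- The ROI definition is tissue-versus-background only; real membrane
  filtering would need a counterstain-aware segmentation.
- The ULBP substrate on real tiles may be better served by the saturation
  channel than the binary mask; both are available but only the mask
  substrate is exercised by the default tests.
- Connectedness uses a single threshold (0.10); no multi-threshold
  morphology profile is computed.
- Whole-slide reading (NDPI pyramids) and slide-level score aggregation
  are out of scope; the unit of analysis is the pre-extracted tile.
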