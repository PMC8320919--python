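# her2feat

Biomarker-specific feature extraction and scoring for HER2 assessment of
immunohistochemistry (IHC) histology image tiles.

HER2 (human epidermal growth factor receptor 2) overexpression in breast
cancer is scored 0, 1+, 2+ or 3+ from IHC slides, where the DAB chromogen
marks positive membranes brown against a blue haematoxylin counterstain.
Pathologists judge the *percentage*, *intensity* and *pattern* of membrane
staining; `her2feat` computes image features that map directly onto those
visual criteria, rather than opaque pixel-level descriptors, and validates
them with simple one-vs-all classifiers. It is aimed at digital-pathology
researchers working with tiles extracted from whole-slide images.

## Features computed per tile (38 values)

With S the HSV saturation, ROI the tissue (non-background) pixels and
stain(t) the brown-hued ROI pixels with S ≥ t:

1. **Characteristic curve** — p(t) = 100·|stain(t)|/|ROI| on the threshold
   grid t = 0.10, 0.12, …, 0.50 (21 points). Non-increasing by mask
   nesting; downsampled to 10 points. Its area under the curve is a useful
   single-number summary.
2. **Rotation-invariant uniform LBP curves** — for each t, the uniform
   local-binary-pattern histogram U0…U8 of the stain mask over interior
   ROI pixels (8-neighbour ring, ties count as 1; uniform = at most two
   circular 0↔1 transitions; U8, mostly featureless regions, is
   discarded). The 8×21 curve set is reduced to 25 values: curves U0…U4 at
   5 thresholds, justified by the curves' low curvature and high pairwise
   correlation among U5…U7.
3. **Connectedness** — 100·(largest connected stain component at
   t = 0.10)/|ROI|, 8-connectivity.
4. **Histogram statistics** — entropy −Σ pᵢ log₂ pᵢ and energy Σ pᵢ² of
   the 256-bin histogram of the CIE-Lab b\* channel (blue–yellow axis).

Classification is one-vs-all logistic regression or SVM on z-scored
features, evaluated by stratified 70/30 holdout or repeated stratified
5-fold cross-validation.

A synthetic-tile generator (`her2feat.synthetic`) produces IHC-like tiles
whose staining fraction, saturation, contiguity and colour split are
controlled per class, so the whole pipeline is testable without clinical
data.

## Worked example

```python
from her2feat import (LABELS, generate_tile, compute_curve,
                      area_under_curve, connectedness,
                      bstar_histogram, entropy, energy)

for label in LABELS:
    tile, _ = generate_tile(label, seed=1)
    curve = compute_curve(tile)
    print(label, round(curve.p[0], 1), round(area_under_curve(curve), 2),
          round(connectedness(tile), 1))
```

prints (class, percent stained at t = 0.10, curve area, connectedness %):

```
0 4.9 0.5 0.5
1+ 11.9 1.78 2.4
2+ 29.8 10.74 4.9
3+ 54.7 21.89 31.4
```

Each statistic increases with HER2 class: a score-0 tile stays below the
10% staining line at every threshold, while the 3+ tile stays above 30%
and its staining forms one large connected region. Running
`examples/04_classification.py` extracts the full 38-feature table for
120 synthetic tiles and reaches holdout accuracy 1.000 — the synthetic
classes are linearly separable by design, which checks the plumbing, not
clinical difficulty.

The `examples/` directory has one short script per capability
(characteristic curves, ULBP texture and reduction, connectedness and
histogram statistics, classification, and the curve-sampling sweep), and
the `her2feat` command exposes the same pipeline as subcommands
`synth`, `extract`, `train`, `eval`, `sweep`.

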