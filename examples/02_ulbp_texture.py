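"""ULBP texture curves, their line fits, and similarity-based reduction.

Computes the 8 rotation-invariant uniform LBP component curves of a tile
(one value per saturation threshold), summarises each by a least-squares
line, and shows the 168 -> 25 reduction used in the final descriptor.
"""

import numpy as np

from her2feat import (
    generate_tile,
    linear_parameterize,
    pairwise_curve_similarity,
    reduce_ulbp,
    ulbp_curves,
)

tile, _ = generate_tile("2+", seed=1)
cset = ulbp_curves(tile)
print(f"full curve set: {cset.curves.shape[0]} components x "
      f"{cset.curves.shape[1]} thresholds = {cset.curves.size} values")

print(f"\n{'comp':>4} {'mean':>8} {'slope':>8} {'intercept':>9}")
for i in range(8):
    fit = linear_parameterize(cset.curves[i], cset.t)
    print(f"  U{i} {cset.curves[i].mean():8.4f} {fit.slope:8.3f} {fit.intercept:9.4f}")

reduced = reduce_ulbp(cset)
print(f"\nreduced descriptor: {reduced.size} values "
      "(curves U0..U4 at thresholds 0.10, 0.20, 0.30, 0.40, 0.50)")

# similarity across a small dataset justifies dropping U5..U7
sets = [ulbp_curves(generate_tile(l, seed=s)[0])
        for l in ("1+", "2+", "3+") for s in range(4)]
matrix, redundant = pairwise_curve_similarity(sets)
print("\nmean pairwise curve correlations (upper triangle):")
with np.printoptions(precision=2, suppress=True):
    print(np.triu(matrix, 1))
print("pairs above the 0.95 redundancy threshold:", redundant or "none")
print("\nThe low curvature of each curve (small |slope|) is what makes the")
print("5-point sampling lossless in practice; highly correlated pairs mark")
print("components that add no independent texture information.")
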