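"""Characteristic curves: percent staining versus saturation threshold.

Generates one synthetic tile per HER2 class and prints each class's curve
endpoints and area.  The curve is non-increasing; its height tracks how
much membrane is stained and its drop-off how intense the staining is —
score 0 stays below 10% everywhere, score 3+ above 30%.
"""

from her2feat import LABELS, area_under_curve, compute_curve, generate_tile

print(f"{'class':>5} {'p(0.10)':>8} {'p(0.50)':>8} {'area':>7}")
for label in LABELS:
    tile, _ = generate_tile(label, seed=1)
    curve = compute_curve(tile)
    print(f"{label:>5} {curve.p[0]:8.1f} {curve.p[-1]:8.1f} "
          f"{area_under_curve(curve):7.2f}")

print("\nArea under the curve alone already orders the classes: more and")
print("stronger membrane staining keeps the curve high across thresholds.")
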