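"""Region connectedness and b*-histogram statistics per HER2 class.

Connectedness is the largest stained connected component at saturation
0.1, as a percent of the tissue area: complete membrane staining (3+)
forms one large region.  Entropy and energy of the CIE-Lab b* histogram
summarise how spread the blue-vs-brown colour distribution is.
"""

from her2feat import (
    LABELS,
    bstar_histogram,
    connectedness,
    energy,
    entropy,
    generate_tile,
)

print(f"{'class':>5} {'connectedness %':>15} {'entropy bits':>13} {'energy':>8}")
for label in LABELS:
    tile, _ = generate_tile(label, seed=1)
    hist = bstar_histogram(tile)
    print(f"{label:>5} {connectedness(tile):15.1f} "
          f"{entropy(hist):13.3f} {energy(hist):8.4f}")

print("\nConnectedness rises sharply for 3+ (one contiguous stained region);")
print("entropy rises and energy falls with score as brown staining widens")
print("the b* colour distribution — the two statistics are anticorrelated.")
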