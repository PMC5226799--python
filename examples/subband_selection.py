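"""Inspect the wavelet sub-band kurtosis ranking behind the stain estimate.

Decomposes the optical-density image of a phantom tile into 20 composed
sub-bands (4 orientations x 5 levels) and prints them ordered by the
non-Gaussianity score |K| that drives sub-band selection.
"""

import stainwave as sw
from stainwave.subband import decompose, select_subbands

phantom = sw.render(sw.PhantomSpec(seed=0))
od = sw.rgb_to_od(phantom.image)
stack = decompose(od, wavelet="db2", levels=5)

print("band (level, orientation)   coefficients   excess kurtosis")
for band in stack.ranking():
    print(
        f"  ({band.level}, {band.orientation})"
        f"{band.p:>20d}{band.kurtosis:>18.2f}"
    )

obs = select_subbands(stack, n=20)
print(f"\nfiltered observation matrix D': 3 x {obs.p} coefficients")
# Sparse, edge-dominated detail bands carry the largest |K|; Gaussian-like
# bands score near zero. ICA is run on the concatenation of the top-n bands
# (all 20 by default), where the stain signals are most separable.
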