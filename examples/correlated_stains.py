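"""Why sub-band filtering helps: correlated stain densities.

Renders phantoms whose H and E density fields are correlated (rho = 0.6,
mimicking tissue where nuclei density and surrounding cytoplasm co-vary)
and compares the stain-matrix recovery error of sub-band ICA with plain
ICA applied directly to the raw optical-density pixels.
"""

import numpy as np

import stainwave as sw
from stainwave.estimation import plain_ica_baseline

sub_err, plain_err = [], []
for seed in range(10):
    phantom = sw.render(sw.PhantomSpec(seed=seed, rho=0.6))
    od = sw.rgb_to_od(phantom.image)

    result = sw.deconvolve_tile(phantom.image, seed=seed)
    a = sw.stain_vector_angle(result.stain_matrix, phantom.m_true)
    sub_err.append((a["haematoxylin"] + a["eosin"]) / 2)

    b = sw.stain_vector_angle(plain_ica_baseline(od, seed=seed), phantom.m_true)
    plain_err.append((b["haematoxylin"] + b["eosin"]) / 2)

print("mean H/E angular error over 10 phantoms with rho = 0.6:")
print(f"  sub-band ICA : median {np.median(sub_err):5.2f} deg")
print(f"  plain ICA    : median {np.median(plain_err):5.2f} deg")
# Plain ICA assumes independent sources and degrades when the densities are
# correlated. The correlated part of the phantom lives at low spatial
# frequencies, so the kurtosis-selected sub-bands see more nearly
# independent sources and the mixing matrix estimate improves.
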