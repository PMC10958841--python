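"""Radial ring occupancy of a peripherally enriched signal.

Builds a nucleus mask, paints it with a signal concentrated at the
periphery (like a lamina-proximal chromosome territory), and reports the
fraction of signal per concentric ring before and after the 2k - 1
annulus-area normalization. Ring 1 is the nuclear center, ring 10 the
periphery.
"""

import numpy as np

from nucleodyn.geometry import make_rings
from nucleodyn.spatial import ring_occupancy
from nucleodyn.synthetic import gen_nucleus_mask, gen_radial_image

mask = gen_nucleus_mask(256, 256, 100.0, (10_000.0, 9_000.0))
rings = make_rings(mask, K=10)

# signal density increasing with normalized radius (peripheral enrichment)
image = gen_radial_image(mask, profile=lambda rho: rho**4,
                         total_intensity=1e6, noise_model="poisson", seed=2)

prof = ring_occupancy(image, rings)
print("ring   f_k (raw fraction)   g_k = f_k/(2k-1)")
for k in range(10):
    print(f"{k + 1:>4}   {prof.f[k]:>17.4f}   {prof.g[k]:>16.5f}")
print(f"\nsum f_k = {prof.f.sum():.6f} (fractions partition the signal)")
print("g_k rises with k: after area correction the signal is genuinely "
      "enriched at the periphery, not just spread over larger rings.")
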