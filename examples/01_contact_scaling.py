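"""Segment-classified contact-probability scaling.

Generates a synthetic chromosome whose LAD and non-LAD segments decay with
different power-law exponents, then recovers both exponents from the
stratified P(s) curves. A lower |s| means contact frequency decays more
slowly with genomic distance -- the signature of denser, heterochromatin-
like packing inside LADs.
"""

from nucleodyn.hic import BinLabels, fit_exponent, scaling_curve
from nucleodyn.synthetic import gen_cis_contact_map

# 600 bins at 15 kb with LADs covering two blocks; LAD contacts decay
# with |s| = 0.86, non-LAD with |s| = 1.15
matrix, classes = gen_cis_contact_map(
    n_bins=600,
    resolution=15_000,
    lad_layout=[(0, 200), (380, 600)],
    exponents={"lad": 0.86, "nonlad": 1.15, "cross": 1.0},
    total_contacts=2e6,
    seed=1,
)
labels = BinLabels(classes, 0.5, 15_000)

for segment in ("LAD", "nonLAD", "cross", "all"):
    curve = scaling_curve(matrix, labels, segment)
    fit = fit_exponent(curve, n_min=1e5, n_max=1e6)
    print(f"{segment:>7}: |s| = {fit.s_abs:.3f}  (R^2 = {fit.r_squared:.4f})")

print("\nLAD segments show the lower |s| (slower contact decay), as planted.")
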