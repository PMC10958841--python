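"""SMLM reconstruction and Normalized STORM Intensity (NSI).

Simulates heterochromatin-like localization events with 60% of events in a
periphery band (contour dilated 5x with a 5x5 kernel), reconstructs a
26-nm-per-pixel histogram image, and scores periphery vs interior NSI.
NSI > 1 means the region holds more signal per pixel than the nuclear
average.
"""

from nucleodyn.geometry import make_periphery_interior
from nucleodyn.spatial import compute_nsi, reconstruct_image
from nucleodyn.synthetic import gen_localizations, gen_nucleus_mask

mask = gen_nucleus_mask(256, 256, 26.0, (2_800.0, 2_600.0))
bands = make_periphery_interior(mask, iterations=5, kernel=5)

loc = gen_localizations(mask, n=100_000, periphery_fraction=0.6,
                        periphery_mask=bands.periphery, seed=3)
image = reconstruct_image(loc, bin_nm=26.0, frame_px=mask.raster.shape)

for name, region in (("periphery", bands.periphery),
                     ("interior", bands.interior)):
    res = compute_nsi(image, region, mask.raster, region=name)
    print(f"{name:>9}: NSI = {res.nsi:.3f}  "
          f"(area {res.area_mask_px} px, signal {res.sum_mask:.0f} events)")

print("\nWith 60% of events packed into the smaller periphery band, its "
      "per-pixel signal density exceeds the nuclear average (NSI > 1).")
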