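"""Dual-PWS chromatin dynamics: Sigma_t^2, fractional moving mass, and
ACF-decay diffusion, aggregated over peripheral ribbons.

Simulates a temporal interference cube in which each nuclear pixel follows
a stationary AR(1) (discretized Ornstein-Uhlenbeck) process with known
variance and correlation time, then recovers both and converts the
temporal variance into fractional moving mass with the physical
normalization prefactor.
"""

import numpy as np

from nucleodyn.geometry import make_ribbons
from nucleodyn.pws import (
    OpticalConstants,
    diffusion_map,
    fractional_moving_mass,
    regional_dynamics,
    temporal_variance,
)
from nucleodyn.synthetic import gen_nucleus_mask, gen_temporal_cube

mask = gen_nucleus_mask(64, 64, 130.0, (3_500.0, 3_200.0))
truth_var, truth_tau = 0.04, 0.5          # dimensionless variance, seconds
cube = gen_temporal_cube(mask, frames=4_000, dt_s=0.05,
                         variance=truth_var, tau_s=truth_tau, seed=4)

sigma_t2 = temporal_variance(cube)
print(f"mean Sigma_t^2 = {sigma_t2[mask.raster].mean():.4f} "
      f"(generator truth {truth_var})")

constants = OpticalConstants(gamma=0.08)   # Fresnel coefficient: user choice
mf, prefactor = fractional_moving_mass(sigma_t2, constants)
print(f"moving-mass prefactor C = {prefactor:.3e} g; "
      f"mean m_f = {mf[mask.raster].mean():.3e} g")

diff = diffusion_map(cube, mask=mask.raster, fit_lags=10)
print(f"median ACF decay rate = {np.nanmedian(diff.rate_s1[diff.valid]):.3f} "
      f"s^-1 (truth 1/tau = {1 / truth_tau:.1f})")

ribbons = make_ribbons(mask, width_nm=260.0, n_ribbons=6)
reg = regional_dynamics(sigma_t2, ribbons)
print("regional mean Sigma_t^2 (ribbon 1 = periphery ... 7 = center):")
print("  " + "  ".join(f"{v:.4f}" for v in reg.means))
print("\nDynamics are spatially uniform here by construction; on real "
      "nuclei these regional means resolve periphery-vs-center differences.")
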