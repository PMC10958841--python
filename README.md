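# nucleodyn

Quantitative analytics for nuclear chromatin organization: how the nuclear
lamina and its lamin-associated domains (LADs) shape genome folding, radial
positioning, and chromatin mobility. The library implements, as reusable and
tested components, the measurement pipeline used to ask whether losing
B-type lamins changes mesoscale genome folding, chromatin dynamics, and the
radial placement of chromosomes, heterochromatin, and individual gene loci.

It is aimed at chromatin and nuclear-organization researchers who have
per-assay primary outputs in hand — balanced Hi-C contact matrices, DamID
LAD tracks in BED, segmented nucleus masks and fluorescence rasters, SMLM
localization tables, PWS spectral/temporal cubes, and differential-expression
tables — and want the downstream statistics computed consistently.

## What it computes

**Contact scaling (`nucleodyn.hic`).** Contact probability between loci
separated by genomic distance *N* follows a power law *P* ∝ *N*⁻ˢ. The
module stratifies contacts by anchor class (both anchors in LADs, both
outside, or one of each), builds log-binned *P*(*N*) curves, and fits |s| by
ordinary least squares in log-log space over 10⁵–10⁶ bp. It also computes
per-chromosome LAD coverage and the exponential fit of |s| against
coverage, interchromosomal percent-change matrices, the A/B compartment
eigenvector (first eigenvector of the correlation matrix of
observed/expected contacts), and TAD-size summaries within/outside LADs
from externally supplied domain calls.

**Nuclear geometry (`nucleodyn.geometry`).** From a binary nucleus mask:
a normalized radial coordinate ρ (1 − boundary distance / max depth), ten
concentric rings of equal ρ with the 2k − 1 annulus-area weights, six
boundary-anchored 260-nm ribbons plus a center region, a dilated-contour
periphery band with its complementary interior (5 iterations of a 5×5
all-ones kernel by default), and the centroid with circular-equivalent
radius √(area/π).

**Spatial signal (`nucleodyn.spatial`).** Ring occupancy fractions f_k and
their area-normalized form g_k = f_k/(2k − 1); Normalized STORM Intensity
NSI = (Σ s_i/A_mask)/(Σ s_j/A_nuc); coefficient of variation σ/μ;
SMLM image reconstruction at 26 nm/px (count histogram or average shifted
histograms); focus-to-centroid distances normalized by the equivalent
radius, and matched pairwise distances between two loci.

**PWS dynamics (`nucleodyn.pws`).** Σ (per-pixel spectral standard
deviation of reference-normalized interference), a pluggable Σ→D packing
calibration, temporal variance Σ_t², the fractional moving mass

    m_f = Σ_t² · (πρ₀ / (2Γ²k³nᵢ)) · (NAᵢ/NA_c)² · (n₁/(n_m − n₁))²

with ρ₀ = 0.55 g·cm⁻³, k = 1.57×10⁵ cm⁻¹, nᵢ = 1.518, n₁ = 1.37,
n_m = 1.43, NAᵢ = 0.52, NA_c = 1.49 and a user-supplied Fresnel
coefficient Γ, plus ACF-decay diffusion maps and ribbon-regional averages
with paired percent changes.

**Expression divergence (`nucleodyn.expression`).** Strict DEG filtering
(adjusted P < 0.01, |log₂FC| > 1), gene-vs-LAD classification with
coverage/closest/relative-distance semantics, within/outside-LAD tallies,
and the Gini coefficient G = Σᵢⱼ|xᵢ − xⱼ|/(2n²x̄) of expression vectors.

**Synthetic data (`nucleodyn.synthetic`).** Generators with analytically
known ground truth for every stage: elliptical nuclei, radial intensity
profiles, foci and localization sets with controlled peripheral enrichment,
segment-classed power-law contact maps, AR(1) temporal cubes, spectral
cubes with exact per-pixel Σ, lognormal expression vectors (population
Gini = erf(σ/2)), and planted gene/LAD layouts.

## Worked example

`examples/01_contact_scaling.py` plants different decay exponents inside
and outside LADs and recovers them from the stratified curves:

```
    LAD: |s| = 0.858  (R^2 = 1.0000)
 nonLAD: |s| = 1.131  (R^2 = 0.9994)
  cross: |s| = 1.019  (R^2 = 0.9995)
    all: |s| = 0.933  (R^2 = 0.9993)
```

The LAD segments show the lower |s| (slower decay of contact probability
with distance — denser, heterochromatin-like packing), matching the planted
values 0.86 / 1.15. The other example scripts cover ring occupancy
(`02`), SMLM reconstruction + NSI (`03`), PWS dynamics (`04`), and
DEG/LAD/Gini analysis (`05`); each prints its numbers with a line on what
they mean.

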