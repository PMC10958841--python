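# Methods

This note records the models, conventions, parameter choices and known
limitations behind each module. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Contact-probability scaling

Mean contact frequency between loci separated by *N* bp is modeled as
*P*(*N*) ∝ *N*⁻ˢ. Curves are built on log-spaced genomic-distance bins
(8 per decade by default); each bin's value is the sum of counts over
qualifying bin pairs divided by the *number* of qualifying pairs, so
unobserved (zero-count) pairs deflate the mean rather than being silently
dropped. The abscissa of each bin is the pair-count-weighted geometric mean
of the diagonal separations it covers; with geometric *edge* centers an
exact power law refits with a visible bias (~1% at 8 bins/decade), with
weighted centers the residual bias is an order of magnitude smaller.
`distance_edges="diagonal"` disables aggregation entirely and is exact on
noiseless power laws. |s| is the negated slope of an ordinary
least-squares fit of log *P* on log *N* over 10⁵–10⁶ bp (at least three
populated bins required).

Anchor classes: a bin is a LAD bin when its bp overlap with the merged LAD
track is ≥ half the bin size (threshold configurable); a contact is "LAD"
when both anchors are LAD bins, "nonLAD" when neither is, "cross"
otherwise. "Both anchors in *any* LAD" is deliberate — contacts do not
need to share one LAD interval. The pair-count-weighted combination of the
three class curves reproduces the all-contacts curve exactly; this
partition identity is tested on random layouts.

The compartment eigenvector uses the standard observed/expected transform
(expected = per-separation mean over populated bins), the Pearson
correlation matrix of O/E columns, and the eigenvector of the
largest-magnitude eigenvalue. Because the expected vector depends on
|i − j|, the result is equivariant only under distance-preserving bin
permutations (tested with reversal); sign is fixed by a reference track
when given, else first-nonzero-positive. Matrices arrive already balanced
(KR or similar); no balancing is reimplemented. An optional total-sum
normalization guards interchromosomal comparisons; percent change per
chromosome pair is 100·(mean_treated − mean_control)/mean_control.

The |s|-versus-LAD-coverage relation is fitted as y = a·exp(−b·x),
log-linearized for the seed and refined by nonlinear least squares; a
two-parameter form is used (no additive offset).

## Nuclear geometry

All partitions operate on a filled, single-component binary mask. The
normalized radial coordinate is ρ = 1 − d_b/max(d_b) with d_b the
Euclidean distance transform; it is 0 at the deepest interior point and
→1 at the boundary, respects lobed shapes, and reduces to r/R on a disk
(verified to ~1 px). Rings are K equal-width bins of ρ (K = 10 default);
the annulus-area weight 2k − 1 (exact for equal-radius rings of a disk) is
attached for occupancy normalization, and measured pixel areas are also
reported so users may normalize by true areas instead. Ribbons bin the
physical boundary distance (d_b − 1 px, so boundary pixels sit at 0 nm)
into six 260-nm-wide bands plus a center remainder; the center must be
non-empty. The SMLM periphery band is the 8-connected boundary contour
dilated five times with a 5×5 all-ones kernel (Chebyshev growth of 2 px
per iteration, 11 px total inward extent), clipped to the mask; the
interior is the complement. The kernel and iteration count are exposed:
at 26 nm/px the literal recipe spans ~286 nm, considerably wider than the
oft-quoted "≈100 nm" gloss for such bands, so the defaults reproduce the
literal morphology and the parameters stay adjustable. Rings are defined
on the max-projection mask.

Physical coordinates place the center of pixel (r, c) at
((r + 0.5)·pixel, (c + 0.5)·pixel) nm; the synthetic generators, the
centroid, and the histogram reconstruction all share this convention (a
half-pixel mismatch here biases NSI recovery by several percent).

## Spatial signal statistics

Ring occupancy reports raw fractions f_k (Σf_k = 1), the area-normalized
g_k = f_k/(2k − 1), and a renormalized g for plotting; f is the primitive.
NSI is the region's mean pixel intensity divided by the whole-nucleus mean;
for any partition of the nucleus, Σ (A_region/A_nuc)·NSI_region = 1
exactly. CoV is the population σ/μ over in-mask pixels (sample variant by
`ddof=1`). Reconstruction defaults to a plain 2D count histogram at
26 nm/px; an average-shifted-histogram mode (m² shifted histograms, m = 2
default — the original shift count is not documented) is available, with
total intensity fixed to the event count in both modes. Focus distances are
divided by the circular-equivalent radius √(area/π); the area-based check
is implemented as d/√area (the dimensionally consistent reading of
"divide by the nuclear area"), with the literal d/area also carried.
Pairwise locus distances use greedy closest-pair matching (each focus used
once), chosen because the upstream acquisition analyzes co-planar focus
pairs without a stated assignment rule; an optimal-assignment mode
(`method="optimal"`) is available and the greedy total is tested against
the brute-force optimum at small n (classic factor-2 bound; typically
equal on well-separated sets).

## PWS statistics

Σ is the per-pixel population standard deviation over wavelength of
intensity divided by a reference spectrum (mean removed after
normalization — the order matters and is tested). The Σ→D calibration is
pluggable (identity, affine, or monotone table) because the physical
mapping is instrument- and model-specific; it is a configuration point,
not a guess. Σ_t² is the per-pixel population variance over frames.

The fractional moving mass multiplies Σ_t² by the physical prefactor
C = (πρ₀/(2Γ²k³nᵢ))·(NAᵢ/NA_c)²·(n₁/(n_m − n₁))² with defaults
ρ₀ = 0.55 g·cm⁻³, k = 1.57×10⁵ cm⁻¹, nᵢ = 1.518, n₁ = 1.37, n_m = 1.43,
NAᵢ = 0.52, NA_c = 1.49. Γ has no accepted default and must be supplied
(a helper computes a normal-incidence Fresnel intensity coefficient from
an RI pair); the package never invents a physical constant silently. The
prefactor is verified against an independent hand evaluation at three
constant sets to 1e−12 relative error.

Diffusion is the decay rate 1/τ of the per-pixel normalized autocovariance,
fitted as exp(−t/τ) by least squares on log-transformed positive ACF values
over the first 10 lags (through the origin, since ACF(0) = 1); pixels with
non-positive lag-1 ACF are flagged noise-dominated and excluded from
regional means. Conversion to absolute diffusion units is a user constant.
Regional aggregation averages valid pixels per ribbon; paired percent
change differences per-region means (per-cell means differenced, not pixels
pooled across cells).

## Expression statistics

DEG filtering uses strict inequalities exactly as printed: adjusted
P < 0.01 and |log₂FC| > 1. A gene is within-LAD on ≥ 1 bp overlap with the
merged track (the standard interval-tool default; threshold raisable), so
boundary-spanning genes count as within. Distance to the nearest LAD is the
bp gap (0 when overlapping, ∞ on LAD-free chromosomes); note the
`bedtools closest -d` convention reports gap + 1 for non-overlapping
features, which the oracle tests account for. The relative-distance
statistic places each gene midpoint between its flanking LAD midpoints,
min(d_left, d_right)/(d_left + d_right) ∈ [0, 0.5]; uniform placement
averages 0.25. Gini uses the population form via the sorted-rank identity
(equal to the double sum to 1e−12, tested against the O(n²) oracle);
whether expression is TPM/FPKM/counts and whether zeros are filtered is the
caller's choice and recorded in the result.

## Synthetic-data generators

Generators emulate the statistical structure each estimator assumes, not
the optics or polymer physics of the real assays: no PSF, no localization
error, no loops/TADs beyond segment-class power laws, no spatial
correlation between pixels in the dynamics cubes. Passing recovery tests
therefore demonstrates estimator correctness under the stated model, not
robustness to real-data artifacts.

Key conventions: radial placement densities are densities of ρ itself
(uniform-over-area = 2ρ — the area weighting is applied explicitly by
binning pixels on ρ and drawing bins by density mass, avoiding the classic
disk-sampling bias); contact maps draw Poisson counts about
scale·d⁻ˢ with the scale set analytically so the expected grand total hits
the requested depth (~5×10⁶ for acceptance runs, matching a deeply
sequenced single chromosome at 15-kb bins); temporal cubes use the exact
AR(1) discretization of an Ornstein–Uhlenbeck process (lag-1 coefficient
e^(−Δt/τ), stationary variance as requested); spectral cubes offer a
sinusoidal mode with an integer number of cycles so the per-pixel Σ is
exact, and lognormal expression has population Gini erf(σ/2). Every
stochastic generator has a noiseless or exact mode for sharp tests.
Randomness flows through named substreams of one global seed
(`SeedSequence([seed, crc32(name)])`), so adding a generator call never
perturbs earlier streams; identical seeds reproduce outputs bit-exactly.

Problem sizes in the tests (10⁴ frames for dynamics recovery, 10⁵ events
or genes for distributional checks, 1500-bin maps at ~5×10⁶ contacts for
exponent recovery) were chosen so each statistical check has comfortable
power at its stated tolerance while the whole suite runs in minutes on one
CPU.

## Known limitations

- Nucleus segmentation, single-molecule fitting, domain calling, and
  differential-expression fitting are out of scope; their outputs are
  inputs here.
- The ring/ribbon partitions are 2D (max-projection); no 3D partitioning.
- Greedy pair matching can exceed the optimal assignment total (bounded by
  2×); use `method="optimal"` when that matters.
- `.hic`/`.cool` binary formats are not parsed; contact matrices arrive as
  sparse coordinate text or dense toy tables.
- The trans percent-change uses raw (or total-sum-normalized) mean counts;
  whether the original analysis used balanced counts for trans pairs is
  not documented, so both paths are exposed.
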