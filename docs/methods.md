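# Methods

This note documents the models, conventions, and numerical choices behind
`wingbone`, and what the synthetic-data tests do and do not establish about
real histological material.

## Canal morphometry

**Measurement model.** Each primary vascular canal is reduced to a
second-moment-matched ellipse: the ellipse sharing the pixel region's
centroid and central second moments (axes 4√λ of the covariance
eigenvalues, so a filled ellipse is recovered exactly up to rasterization).
Regions smaller than 5 px are dropped with a logged count — below that size
the moment fit is unstable. Branched canals are split at skeleton junctions
(pixels of the morphological skeleton with ≥ 3 neighbors); every pixel of
the original region is assigned to the nearest branch, so the pixel union is
preserved.

**Classification.** A canal is classified from (aspect ratio, θ), θ being
the acute angle between its major axis and the local periosteal tangent,
folded into [0°, 90°]. The aspect test is applied first and is strict
(*a/b* < 3 ⇒ longitudinal); the circumferential [0°, 22.5°] and radial
[67.5°, 90°] bands are closed, making the ± notation inclusive, and oblique
is the open remainder. The partition is total: a dense-grid oracle test
checks every (aspect, θ) pair lands in exactly one class.

**Tangent reference.** The periosteal contour is extracted from the filled
mask, oriented counter-clockwise, and smoothed by a circular moving average
over a 50 µm window (≪ octant arc length; un-smoothed raster contours give
noisy tangents). The tangent at a canal is taken at the nearest contour
vertex. Cortical octants are 45° sectors about the section centroid centered
on the two anatomical axes — the simplest reproducible rule, since octant
boundaries are otherwise a free choice; the four diagonal octants are
discarded.

**Straightening.** An octant can be uncurved so the periosteal surface maps
to the top image row: the contour segment is resampled at uniform arc length
(step = 1 px), and the image is sampled by bilinear interpolation along
inward normals. The map preserves arc length along the surface; at depth *d*
below a surface of curvature radius *R* it stretches tangentially by
R/(R−d), which is what the validation harness measures by pushing known test
angles and circles through the map. Octants whose (window-averaged)
curvature radius is smaller than the requested depth are rejected — the map
would fold over. On gently curved octants (curvature radius ≥ 10× cortical
thickness) the distortion stays within the gates used for real material:
≤ 5° angle deviation and circle aspect ratios ≤ 1.17. Classification of
synthetic fields references tangents directly (the annulus tangent is
analytic), with straightening validated separately; on real imagery either
route gives the same θ by construction.

**Laminarity index.** LI is the proportion of circumferential canals among
primary canals (secondary-osteon canals are excluded upstream; identifying
them requires stained imagery, out of scope here). The default estimator is
the Wilson score center and interval at 95%,

  p̃ = (x + z²/2)/(n + z²),  half-width = z/(n + z²) · √(x(n−x)/n + z²/4),

with the "plus-four" simplification available as an option. With x = 0 the
index is reported as exactly 0 with no interval; with no primary canals at
all it is undefined (n/a) — both conventions occur in published specimen
tables without a stated rule, so the package exposes the n = 0 distinction
explicitly. Note p̃ is shrunk toward ½: an all-circumferential section has
p̃ < 1 at any finite n.

## Cross-sectional geometry

Each foreground pixel contributes its full area at its center (midpoint
rule); no sub-pixel boundary integration. CA counts cortical pixels; TA is
the area enclosed by the periosteal boundary (medullary cavity filled).
Principal moments come from the eigendecomposition of the central
second-moment tensor; J = I_max + I_min holds exactly by construction
(perpendicular-axis identity). The section-modulus moment arm defaults to
the **maximum** centroid-to-periosteal distance (the extreme-fiber arm of
standard section-modulus practice); a mean-radius option exists because
published workflows are ambiguous on this point. Raster values converge to
closed forms at better than 1% for discs, annuli and elliptical rings once
the outer diameter spans ≥ 1024 px, and the error falls with resolution.
A logged caution (never a value change) is emitted when I_max/I_min exceeds
1.5, where Z_p becomes a heuristic for a non-circular section.

## Growth and FMR

Inflection-point closed forms (mass m, asymptote A, rate constant K/day):

| model | inflection mass | max rate | RGR |
|---|---|---|---|
| logistic | A/2 | KA/4 | K/2 |
| Gompertz | A/e | KA/e | K |
| von Bertalanffy (mass form, cubed exponential) | 8A/27 | 4KA/9 | 3K/2 |

each verified against dense numerical differentiation of the model curve.
RGR is invariant to A in all three models — that is the point of the
standardization. Rates are kept in 1/day internally since compiled sources
mix units. Curve fitting (for the synthetic path; published compilations
arrive as parameters) is nonlinear least squares with data-driven starts;
noiseless series are recovered to better than 4 significant figures.
Mass-specific FMR is FMR/mass, and all log10 transforms are applied **after**
standardization.

## Phylogenetic scaling

**Covariance structures.** Brownian motion: V_ij = shared root-to-MRCA path
length, computed as (t_i + t_j − d_ij)/2 from tip depths and patristic
distances. Ornstein–Uhlenbeck (Martins–Hansen stationary form):
corr_ij = exp(−α·d_ij), diagonal 1. α = 0 degenerates to an all-ones matrix
(flagged); α → ∞ recovers OLS — the convergence rate is governed by α times
the *minimum* pairwise distance, so tests drive α·d_min ≥ 20. Non-ultrametric
trees get a warning rather than a refusal, since the stationary correlation
depends only on patristic distance. Polytomies are resolved into zero-length
branches (patristic distances unchanged); a covariance that then fails to
factor receives a logged ridge of 1e-10 × mean diagonal.

**Fitting.** Model-I GLS via Cholesky solves; REML by default (ML behind a
flag). The REML log-likelihood uses the standard restricted form and matches
R's `nlme::gls` to 6 decimals on the packaged specimen table (frozen
cross-check in the test suite). AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = 3
(slope, intercept, residual variance) for OLS/PGLS-BM/fixed-α OU and k = 4
when α is profiled; comparing REML fits by AICc is valid here because all
candidates share the same fixed-effects design. Confidence intervals are
t-based Wald intervals with n−2 df — the published tables do not state their
interval construction, and on Brownian simulations with a known slope the
95% interval covers at its nominal rate (93–97% over 500 replicates in the
acceptance battery). α handling follows the published tables' style: a
user-supplied α grid is the default mode, with REML profiling of α available
and recorded in the model label.

**Model choice.** (1) Blomberg's K on the response with a tip-permutation
test (999 permutations, explicit seed; gate p < 0.05 — threshold and
replicate count are package choices, the published procedure states only the
gate); no detectable signal selects OLS outright. (2) Residual "randomness"
is operationalized as a two-sided Wald–Wolfowitz runs test on residual signs
ordered by fitted value (the published procedure inspected plots visually);
exact conditional p up to n = 30, normal approximation beyond, indeterminate
below n = 5; the flag is advisory and configurable. (3) Lowest AICc among
survivors; if everything is eliminated, OLS is returned with a warning.
The full decision trace is logged.

## Synthetic data: what it emulates, and what it does not

Canal fields place non-touching elliptical canals in a circular annulus at
the emulated imaging resolution of 2.1 µm/px; angles are drawn relative to
the analytic periosteal tangent within each class's band (oblique from the
open interval (22.5°, 67.5°), longitudinal with aspect in [1, 3) and
arbitrary angle; non-longitudinal aspects in [3.5, 6]), so truth labels are
exact under the classifier's own convention. Default geometry (outer radius
900 µm, inner 500 µm, minor axes 10–14 µm) keeps 150–200 canals separable.
Real sections differ in every hard way: canals touch and branch irregularly,
secondary osteons intrude, the periosteal surface is rough, and cortices are
eccentric — so the ≥ 95% class-recovery result bounds raster/transform
error only, not segmentation or staining error. Profiles are ideal rings
with closed-form properties, not traced bone outlines. Growth noise is
additive i.i.d. Gaussian, not the heteroscedastic, serially correlated
error of longitudinal field data. Trees are pure-birth, rescaled to unit
depth so α and σ² are dimensionless and comparable across tests; the
simulator adds a final exponential holding time so terminal branches are
never zero-length.

## Known limitations

* Canal segmentation from raw micrographs and primary/secondary
  discrimination by image content are out of scope; canal records arrive
  pre-labeled.
* Specimen-level LI and Z_p values in the packaged table are fixtures from
  the published specimen table, not recomputable here (the underlying
  sections are not distributed at mask fidelity), and the published
  regression coefficients were evidently computed from unrounded source
  data: refitting the printed table reproduces the slopes closely (bats
  0.793 vs 0.788; birds 0.778 exactly) but the bats intercept only
  approximately (−2.517 vs −2.599).
* The FMR/RGR compilations and pruned supertrees are not redistributable;
  `data/supplementary/` is the documented drop-in slot (CSVs with columns
  species, x, y; Newick trees) used by the corresponding acceptance tests.
* Model II (reduced major axis) regression is deliberately absent, and
  Pagel's λ and other signal statistics are not implemented.
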