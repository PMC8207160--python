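# Methods

This note documents the statistical model behind the package, the default
parameter choices, what the synthetic-data generators do and do not emulate,
and the numerical decisions a maintainer should know about.

## Measurement model and Procrustes ANOVA

A specimen contributes two separate bilateral structures (left and right
hemimandibles), each photographed `m` times and digitized `d` times per
photograph. After reflecting one side and jointly superimposing all
configurations by generalized Procrustes analysis (GPA), the aligned
coordinate y of one configuration decomposes as

```
y = mean + individual + side + individual×side + image + digitizing
```

with *individual* random, *side* fixed (directional asymmetry, DA),
*individual×side* the fluctuating asymmetry (FA), and two nested error
strata: *image* (positioning/photography error, nested in specimen×side)
and *digitizing* (landmark-input error, nested in image).

Sums of squares are sequential (Type I) on this nested hierarchy, computed
by comparing least-squares fits of successive design matrices. For balanced
data this equals the classical group-mean decomposition exactly (the test
suite checks this to 1e-9 against a brute-force oracle); for unbalanced
data the degrees of freedom come from observed design-matrix ranks, so the
table is correct for whatever design it is given rather than forcing
nominal counts. For shape, SS are summed over all 2k coordinates and
structural df are multiplied by the shape-space dimension 2k − 4 (2-D data
after removing translation, scale, rotation); with k = 10 landmarks and 86
individuals this yields the familiar pattern side df = 16, individual and
interaction df = 85 × 16 = 1360. Size uses the same strata on scalar
centroid size without the multiplier.

F ratios are stratified: main effects are tested against the interaction,
the interaction against the image stratum, and the image stratum against
digitizing; p-values come from the F distribution (no permutation). FA is
declared present when the interaction has p < .05 and its F exceeds 10 ×
the F of the error stratum — the conventional guard against mistaking
measurement error for FA.

Method-of-moments variance components follow from the expected mean
squares: `E[MS_res] = s2_digit`, `E[MS_img] = s2_digit + d*s2_image`,
`E[MS_int] = E[MS_img] + (m*d/2)*s2_fa`, where `s2_fa` is the variance of
the *signed left − right* difference per coordinate. The factor 2 arises
because each side carries half of the asymmetry deviation. Although GPA
projects isotropic landmark noise into the (2k − 4)-dimensional shape
space, dividing SS by structural df × (2k − 4) makes the per-coordinate
mean squares unbiased, so injected variance components are recovered
essentially without attenuation (the suite checks 25 % at n = 200; observed
error is ~2 %).

## FA indices

**Shape.** The asymmetry vector of a specimen is the difference between its
replicate-averaged left and (reflected) right aligned configurations.
DA — the mean asymmetry over specimens — is removed, and each centered
deviation d_i is standardized by the sample covariance S of those
deviations: score_i = sqrt(d_i' S⁺ d_i). Shape space is rank-deficient, so
S⁺ is the eigendecomposition pseudo-inverse restricted to eigenvalues
above 1e-10 × the largest. The cutoff is a package decision; results are
insensitive to it over several orders of magnitude because the discarded
eigenvalues are numerically zero. Scores are invariant to a global rotation
of the aligned dataset (tested).

**Size.** signed index = mean over replicates of CS(left) − CS(right)
(positive when the left side is larger); the absolute value discards
direction. Centroid sizes are taken before GPA normalization, in input
units.

## Population genetics

Observed heterozygosity is the fraction of heterozygous loci per individual
and, per population, the mean over loci of the heterozygote proportion
among typed individuals (pairwise deletion of missing calls). F_is uses the
Weir & Cockerham (1984) within-population f: per allele,
`b = n/(n−1) [p(1−p) − (2n−1)/(4n) h]` and `c = h/2` with h the observed
heterozygote proportion carrying that allele; f = 1 − Σc/Σ(b+c) with sums
over alleles (per locus) or over loci and alleles (multilocus). A Nei-style
1 − Ho/He estimator is exposed for comparison. Degenerate edges behave as
expected: all homozygotes give f = 1, all heterozygotes f = −1, monomorphic
locus×population combinations are undefined and skipped.

The Hardy–Weinberg test is the exact conditional test: the p-value is the
total conditional probability (given allele counts) of genotype arrays no
more probable than the observed one. Arrays are fully enumerated when at
most 10⁶ exist; otherwise the null is sampled by shuffling the allele
vector and re-pairing (Monte-Carlo), with p = (1 + hits)/(reps + 1).
Probability comparisons happen on the log scale with a 1e-9 tolerance so
ties are counted consistently in both modes; the suite checks MC against
enumeration within 3 binomial SE.

Linkage disequilibrium between two loci uses the G log-likelihood-ratio
statistic of the two-locus genotype contingency table; the null is built by
permuting one locus's genotypes across individuals (within population), and
the p-value carries the +1 correction. For independent loci the p-value
distribution is approximately uniform (checked: mean ≈ 0.5).

## Landscape

Scale of effect from a home-range area HR: LD = √HR, MDD = 40·LD, candidate
radius band [0.30, 0.50] × MDD. MDD is computed from the *unrounded* LD —
the published distance table is only reproducible that way (e.g.
HR = 486.7 m² gives 40·√486.7 = 882.5 m, not 40·22.1 = 884 m). Values are
reported to one decimal.

Habitat amount within a buffer counts cells whose *center* lies within the
radius (the rule of common landscape-statistics tools; area-weighting of
partial cells is out of scope). Cells outside the raster are excluded from
numerator and denominator, with a warning when the raster covers < 99 % of
the circle. Coordinates are planar meters; no geodesy — appropriate for the
small buffers involved.

## Association battery

Group comparisons report both one-way ANOVA and Kruskal–Wallis (with tie
correction); which is "preferred" follows a Shapiro–Wilk gate on the pooled
within-group residuals at α = .05 — the choice of normality test is a
package decision. Relationships with continuous factors use Pearson r with
the two-sided t test. Factor relevance uses the likelihood-ratio test of a
bivariate normal linear model against the intercept-only null,
χ² = n·ln(RSS₀/RSS₁) ~ χ²(1); categorical factors are integer-coded, which
is exact for binary factors such as sex. All models are bivariate by
design (small samples), specimens are treated as independent across
populations (no mixed-effects correction), and per-test alphas are
Bonferroni: .05/5 = .01 at the individual level (habitat, sex, body size,
H_o, plus one reserved slot in the configured family), .05/4 = .0125 at the
population level (habitat, H_o, F_is, plus one reserved slot).

At n = 8 populations the normal-theory LRT is liberal: under the null,
r² ~ Beta(1/2, 3), so the exact rejection rate at α = .0125 is
P(r² > 1 − exp(−χ²crit/8)) ≈ 3.7 %, and simulations in the suite are
checked against this closed form rather than against the nominal α.

## Synthetic-data generators

**Landmarks.** Left side = mean shape + individual effect + a_i/2 + errors;
right side is the mirror of mean + individual effect − a_i/2 + errors,
with a_i ~ N(da, σ_fa² I) per coordinate, so the signed left−right
difference has mean da and variance σ_fa² — this makes the ANOVA
expectation algebra exact. All noise is isotropic Gaussian per coordinate.
Each image additionally receives a small placement nuisance (rotation
σ = 0.05 rad, translation σ = 5 % of scale), which GPA removes. Defaults
(units of the unit-centroid-size mean shape): σ_ind = 0.02, σ_digit =
0.002, σ_image = 0.0005, σ_fa = 0.005, scale = 20 mm, 2 images × 3
digitizings. Digitizing error dominates imaging error, consistent with
protocols in which re-photographing a rigid bone perturbs landmarks less
than re-clicking them; this keeps the error-stratum F near 1, as observed
in published tables of this design.

**Genotypes.** The second allele of a call copies the first with
probability F and is an independent draw otherwise, giving
P(A_iA_i) = p_i² + F·p_i(1−p_i), P(A_iA_j) = 2p_ip_j(1−F) and
E[Ho] = (1−F)(1−Σp²). Defaults: 7 loci × 5 equifrequent alleles, F = 0.05
per site — E[Ho] ≈ 0.76, inside the published 0.70–0.84 range.

**Rasters.** Gaussian-smoothed white noise thresholded at the empirical
quantile: the achieved habitat fraction matches the target to within one
cell, and patches are spatially autocorrelated like forest fragments.
Default grid 120 × 120 cells of 30 m (Landsat-like) with a smoothing length
of 2 cells (~60 m patch scale). The patch scale is deliberately small
relative to the 264 m buffer so that the buffer percentage is a
low-variance estimate of the site's nominal habitat proportion; with
coarse patches (≥150 m) the buffer percentage at a single site decouples
from the site parameter, which attenuates any habitat–FA association
regardless of its true strength.

**Study bundle.** Eight sites with habitat proportions 19–100 % and sample
sizes 8–15 mirror the reference system. The habitat→FA rule is
σ_fa(site) = 0.005 + effect × (1 − habitat proportion), with effect =
0.005 by default — developmental noise doubling from full forest to the
most deforested site, consistent with the ~3–4× FA-variance contrast
between the worst and typical sites in the published tables. The rule is a
configurable scenario, not an estimate: the true mapping between habitat
amount and developmental noise is unknown. Per-site substreams derive from
one integer seed via composite seeding, so sites are independent and the
bundle is bit-reproducible.

What the generators do **not** emulate: spatially explicit population
genetics (no migration/drift across the landscape), pedigrees, allometry,
age structure, classification error in the rasters, or non-Gaussian
landmark noise. Passing tests therefore demonstrate correctness of the
estimators and calibration of the tests under the stated model, not
robustness to those real-data complications.

## Numerical choices and limitations

* GPA: full Procrustes (unit centroid size), proper rotations only
  (det = +1) so reflection asymmetry cannot leak into the fit; tol = 1e-8
  on consensus RMS change, max 100 iterations; tangent-space projection is
  omitted (at mandible-scale shape variation the difference is below test
  tolerances). Configurations are stored in canonical key order, so results
  do not depend on input order.
* The first configuration initializes the consensus; the objective (summed
  squared distance to the consensus) is non-increasing across iterations
  (tested).
* Degenerate inputs fail loudly: all-coincident configurations, mixed
  landmark counts, duplicate replicate keys, single-sided datasets,
  monomorphic loci (flagged, p = 1), buffers that miss the raster.
* Problem sizes in the test suite and reproduction script (86-individual
  reference design, 200-individual recovery runs, 100–200 simulation seeds,
  199–10⁴ permutations/shuffles) are chosen to estimate each rate with
  binomial error well inside the asserted bands at desk scale.
* Individual-level inference ignores the population grouping; with strong
  between-population structure the individual-level LRTs are
  anti-conservative. The published analysis made the same choice, and the
  package reproduces it deliberately.
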