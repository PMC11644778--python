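# Methods

This note documents the statistical conventions, the generative model
behind the synthetic surveys, and the design decisions taken where the
conventions in the survey literature are genuinely open.

## Survey container

A survey is a sites × elements matrix of concentrations in mg/kg dry
weight with per-site metadata (WGS84 coordinates, elevation, moss
species). Values must be strictly positive and finite. Missing values
are rejected rather than imputed: the index chain (ratios, geometric
means) has no meaningful zero- or missing-value semantics, and silent
imputation would bias backgrounds downward. Surveys with gaps should be
filtered or imputed explicitly before analysis.

## Descriptive conventions

- standard deviation: sample (n−1 denominator); CV% = 100·sd/mean,
  rounded to integer percent only for presentation;
- MAD: raw median absolute deviation about the median, **not** scaled by
  the 1.4826 normal-consistency factor — survey tables label the column
  "median absolute deviation" with no consistency constant;
- quantiles: linear interpolation (the common statistical default);
  reproduction of published Q1/Q3/P90 values depends on this choice, so
  it is fixed and tested against a sort-and-interpolate oracle;
- skewness: adjusted Fisher–Pearson sample coefficient; degenerate
  (constant or near-constant) vectors report 0.

## Background estimation

Backgrounds are estimated from the data themselves because genuinely
uncontaminated reference sites are rarely identifiable a priori.

1. **Rank-sum ordering.** Each element ranks the sites ascending (ties
   averaged); per-site ranks are summed across elements. Summing ranks
   rather than concentrations makes the ordering scale-free, so elements
   spanning five orders of magnitude contribute equally. The ordering is
   monotone: raising every concentration of a site can only raise its
   rank sum, so strongly boosted hotspot sites cannot enter the subset.
2. **Subset.** The ⌈fraction·n⌉ lowest-rank-sum sites (default fraction
   0.10, so 10 of 95 sites; minimum subset size 3; cutoff ties break by
   site order, keeping selection deterministic). Selection is global —
   one shared subset for all elements — mirroring the idea that the
   subset represents "generally clean" locations.
3. **Outlier screen.** Per element, a two-sided single-outlier Grubbs
   test (G = max|x−mean|/sd against the classical t-based critical value)
   at α = 0.05, applied iteratively with re-testing after each removal.
   Removals are capped at one third of the subset, and the pool never
   shrinks below 3, preventing degeneracy on pathological inputs.
4. **Bootstrap upper limit.** The background is the percentile-bootstrap
   upper limit of the confidence interval for the subset mean (default:
   two-sided 95% CI, i.e. the 97.5th percentile of 2000 resampled means;
   a one-sided 95th-percentile variant is available by config). "Upper
   limit of the 95% CI" is read in the standard two-sided sense. The raw
   subset mean is reported alongside for transparency; whether a given
   published background used the mean or the upper limit is generally
   not stated, so both are exposed. Subset values are sorted before
   resampling and per-element seeds are spawned deterministically from
   the config seed, which makes the estimate invariant to row order.

A constant element short-circuits to the constant itself.

## Indices and classification scales

CF, PLI (geometric mean over the nine-element set Al, Cd, Cr, Cu, Fe,
Ni, Pb, V, Zn), PERI and ERI are defined in the README. Numerical
properties relied on by the tests: CF and PLI are homogeneous of degree
one in a site's concentrations; PLI lies between the smallest and
largest CF; ERI with unit TRFs reduces to the CF sum.

Class boundaries in the published scales are printed with strict
inequalities on both sides (e.g. "1 < CF < 2"), which leaves the
boundary points formally unassigned. All scales here use left-closed
intervals — [1, 2) "Suspected", [8, 27) "Severe", PERI [80, 160)
"significant" — except the ERI scale, whose published wording makes the
upper bounds at 300 and 600 explicitly inclusive: [0, 150) low,
[150, 300] moderate, (300, 600] considerable, (600, ∞) high. The PLI
scale maps floor(PLI), capped at 6, onto the seven labels from
"no pollution" to "extremely high" — the only reading that reconciles
the integer scoring description with the worked classifications in the
literature (3.21 → "moderate to severe", 2.22–2.97 → "moderate").
Boundary cases are measure-zero on real data; the convention is
documented and tested rather than load-bearing.

The toxic-response factor table follows Hakanson (Mn, Zn = 1; Cr, V = 2;
Cu, Pb, Ni = 5; Cd = 30; Hg = 40); only these nine elements enter
PERI/ERI. The printed TRF lists in parts of the survey literature
abbreviate chromium as "C"; the registry assigns that weight to Cr, the
standard Hakanson element (carbon is not a measured element).

## Multivariate screening

- **Spearman + Holm.** Pairwise Spearman rho on tie-averaged ranks;
  p-values from the t approximation for n ≥ 10 and from the exact
  permutation null below (the untied null of rho depends only on n, so
  it is enumerated once and shared across all pairs; tied small-n data
  falls back to the t approximation with a warning). The Holm family is
  the full set of element pairs (105 for 15 elements), matching
  matrix-wide significance masking; constant columns yield undefined
  correlations and are masked not-significant.
- **Mann–Whitney.** Two-sided; exact null for combined n < 50 without
  ties, otherwise the normal approximation with tie-corrected variance
  and continuity correction (the convention of R's `wilcox.test`).
- **PCA.** Columns standardized to unit variance (correlation PCA) —
  the defensible default for variables spanning 0.03 to ~7000 mg/kg; a
  log10 pre-transform is available by flag and is the right choice when
  the quantity of interest lives on the log scale (as in the planted
  variance-share recovery experiments). Per-sample contribution to a
  component is the sample's squared-score share of that component, the
  FactoMineR convention.

## Synthetic survey generator

Concentrations follow a log-normal latent-factor model:
C_ij = exp(μ_j + Σ_k L_jk f_ik + ε_ij) · boost_ij. This is the simplest
generative form reproducing the two features real surveys show: strongly
right-skewed positive marginals (mean > median for every element) and a
block correlation structure.

The default ("georgia-like") configuration emulates a 95-site,
15-element Caucasus-region national survey:

- exp(μ_j) sits at the survey's reference medians (Al 2131, Fe 1826,
  S 1252 mg/kg, … Hg 0.037 mg/kg);
- each element's total log-sd is derived from its reference CV% via
  σ = √ln(1+CV²) and split between three factors and residual noise.
  The geogenic block (Al, Co, Cr, Fe, V) places 82% of its log-variance
  on a shared factor, which puts within-block correlations at ≈ 0.82,
  the middle of the empirically observed 0.74–0.91 band; the
  anthropogenic block (Cd, Hg, Mn, Pb, Zn) shares 45% on a second
  factor; a small mixed-sign third factor carries local anomalies
  (Cu, Hg, Ni, S loading negatively against Ba, Cd, Mn, Sr);
- Pb and Mn keep a reduced bulk log-sd (0.45/0.50) with multiplicative
  hotspots carrying the rest of their spread — real surveys show tight
  MADs but ~74–94% CVs for these two, an outlier-driven pattern;
- four default hotspots emulate the observed extreme sites (an
  urban/industrial Pb–Cd–Zn site ×6, a ferroalloy-district Mn–Pb site
  ×6, a quarry Hg site ×2.5, and an erosion-driven geogenic site ×2.2);
- site coordinates are uniform in a Caucasus-like bounding box,
  elevations uniform on 2–2123 m, species drawn with the typical
  pleurocarpous-dominated proportions (70:14:6:5).

Two scenario configurations carry planted ground truth for recovery
experiments:

- **background recovery**: 15 of 95 sites are "clean" (factor scores
  damped to zero, so they sit at exp(μ) plus residual noise) and the
  rest take half-normal (non-negative) factor scores, making
  contamination a strictly upward shift; two hotspot sites boost all
  nine PLI elements ×10. The background estimate is compared per
  element against the clean sites' geometric mean, aggregated over 20
  seeds; the planted hotspots must occupy the top two PLI ranks and
  never enter the background subset. Note the estimator is *designed*
  to sit slightly above the clean level (it is an upper confidence
  limit); the observed aggregate recovery error is ×1.05–1.18.
- **PCA recovery**: all 15 elements share one log-sd, with
  42.5/12.5/7.5% of each element's log-variance on three factors with
  mutually near-orthogonal sign patterns. That makes the population
  eigenvalue shares of the log-scale correlation matrix exactly
  45/15/10% (noise absorbs the rest), recovered within ±7 points.

What the generator does **not** emulate: spatial autocorrelation (sites
are exchangeable; no deposition or wind physics), species-specific
uptake differences (species labels are decorative), measurement
uncertainty structure (no detection limits or heteroscedastic assay
noise), and between-element tail dependence beyond the Gaussian copula
implied by the factor model. Passing recovery tests therefore
demonstrates correctness of the *procedures* under the stated
statistical structure, not calibration against any real deposition
field.

## Problem sizes and numerical choices

Recovery experiments use 20 seeds at n = 95 sites, 2000 bootstrap
replicates (500 in the test suite, where the bootstrap Monte-Carlo error
is far below the tested tolerances), and exact small-n nulls only where
enumeration is cheap (n! ≤ 9! for Spearman, C(8,4) for the Mann–Whitney
oracle). The bootstrap upper limit agrees with the CLT closed form
mean + 1.96·sd/√n within 2% at n = 100, n_boot = 10⁴. All randomness
flows from single integer seeds through `numpy.random.default_rng`;
per-element bootstrap seeds are spawned with `SeedSequence`.

## Known limitations

- The background procedure assumes ≥ 10 sites and a complete matrix; it
  is a relative ("lowest decile") notion and will overestimate true
  backgrounds in a survey where even the cleanest sites are
  contaminated.
- Classification boundary conventions (left-closed; ERI inclusive at
  300/600) follow one defensible reading of scales whose printed
  inequalities are ambiguous at the boundary points.
- The exact Spearman permutation null ignores ties (it falls back to the
  t approximation when small samples are tied).
- GeoJSON export is point-only; interpolated pollution surfaces and
  cartography are out of scope.
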