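# Methods

## Scope and data model

The package covers the computational chain of a dicentric-assay
interlaboratory comparison: per-dose dicentric count spectra
(`AberrationDistribution`), linear-quadratic calibration curves with
coefficient covariance (`CalibrationCurve`), inverse dose estimates with
confidence intervals (`DoseEstimate`), dispersion statistics
(`DispersionResult`), and the proficiency report (`ILCReport`). All file
formats are plain text (CSV/JSON/YAML), locale-independent, and every
CLI run writes a manifest with the resolved configuration, its hash,
the seed and the package version.

## Calibration-curve fitting

Total dicentrics at each calibration dose are modelled as
`Xᵢ ~ Poisson(Nᵢ · (C + αDᵢ + βDᵢ²))`. The likelihood depends on the
data only through the per-dose totals `(Nᵢ, Xᵢ)`, so replicate
distributions at one dose are pooled before fitting. The identity-link
form is the convention for low-LET dicentric curves; fitting uses Fisher
scoring (IRLS) with projection of the coefficients onto the non-negative
orthant. Convergence is declared when the deviance change falls below
`10⁻¹⁰ · (deviance + 1)` (the +1 floor makes exact-fit data, whose
deviance is numerically zero, converge) within 100 iterations;
non-convergence raises an error carrying the last iterate. The
coefficient covariance is the inverse observed information
`Σᵢ Xᵢ gᵢgᵢᵀ / ŷᵢ²`, `g = (1, D, D²)`. At least three distinct dose
points are required; with fewer the model is unidentified and the fit
refuses to run. An optional quasi-Poisson switch (off by default)
inflates the covariance by `deviance/df` when that ratio exceeds 1, for
visibly overdispersed calibration data.

The test suite cross-checks the fit against an independent identity-link
Poisson GLM (statsmodels) and against a brute-force likelihood grid
search on a small instance, and verifies the intercept score equation
`Σ Nᵢŷᵢ = Σ Xᵢ` and the ~95% coverage of the Wald interval for α.

## Dose estimation

The point estimate inverts the fitted quadratic:
`D̂ = (−α + √(α² + 4β(X/N − C))) / 2β`, with `D̂ = 0` for yields at or
below background and the linear solution when `β = 0`. Two interval
methods are exposed and labelled on every estimate; neither is claimed
to replicate any specific laboratory's software:

* **yield_only** — exact (Garwood) Poisson limits on the yield at the
  requested level, inverted through the curve. Garwood limits
  (`χ²(α/2, 2X)/2N`, `χ²(1−α/2, 2(X+1))/2N`) are used rather than a
  normal approximation because triage-mode samples of ~200 cells carry
  low counts.
* **curve_plus_yield** (default) — the Merkle combination: Garwood
  limits at the 83% component level for the sampling error, and a
  simultaneous 83% confidence envelope for the curve,
  `ŷ(D) ± √(χ²₀.₈₃(3)) · √(gᵀΣg)`. The upper (lower) dose limit is the
  crossing of the lower (upper) curve envelope with the upper (lower)
  yield limit, root-found by bisection on `[0, 3 × max calibration
  dose]` to 10⁻⁶ Gy. The chi-square factor (df = number of fitted
  coefficients) rather than a plain normal quantile is deliberate: the
  83%/83% combination attains ≈ 95% dose coverage only when the curve
  envelope is a simultaneous region; with a pointwise z-envelope the
  combination under-covers whenever the calibration is informative
  (≈ 89–91% in our simulations, vs ≈ 94–95% with the chi-square
  factor at the default calibration design). When the curve covariance
  is all zeros the Merkle interval collapses, by construction, onto the
  yield-only interval at the 83% component level; comparing interval
  widths across methods is therefore meaningful at that matched
  component level.

Estimates beyond the curve's maximum calibration dose are permitted but
flagged `extrapolated`. Curves without covariance support only
`yield_only`; requesting the default method then raises a capability
error rather than silently degrading.

Coverage of the default method was measured at 2,000 replicates of a
200-cell sample at 3.41 Gy on a curve fitted once from a default-design
calibration: ≈ 94–95%, varying by ~±1 percentage point with the curve
realization, since the experiment is conditional on one fitted curve.

## Dose-definition conversion

Air kerma free in air and absorbed dose to blood differ by ≈ 5.7% for
the packaged ⁶⁰Co geometry. The conversion table stores anchor pairs
(2.56→2.71, 3.41→3.60, 4.54→4.80 Gy); between anchors the factor is
interpolated linearly in air kerma and held constant outside them. The
blood-to-kerma direction solves `k·f(k) = v` numerically so the round
trip reproduces inputs to 10⁻¹⁰ Gy. Conversions involving absorbed dose
to water are declined loudly — no physics for that pair is packaged.

## Dispersion statistics

`δ = s²/ȳ` uses the unbiased (N−1) variance of the per-cell counts,
matching the convention of the standard dosimetry software; δ is always
computed from the full spectrum, never reconstructed from (N, X). The
Papworth statistic `u = (δ−1)·√((N−1)/(2(1−1/X)))` requires `X ≥ 2`.
Both the one-sided overdispersion flag (`u > threshold`) and the
two-sided flag (`|u| > threshold`) are reported, with threshold 1.96 by
default. A caveat the package does not hide: under the Poisson null at
N = 200 and mean 0.6 the exact one-sided exceedance `P(u > 1.96)` is
≈ 0.033, not the nominal 0.025, because u is right-skewed
(skewness ≈ 0.36) at these sizes even though its mean and standard
deviation match the standard normal and the Kolmogorov–Smirnov distance
to it is < 0.05. Users applying a strict 2.5% one-sided error rate at
triage cell numbers should calibrate the threshold by simulation.

## Synthetic exercises

The generator emulates a blinded multi-laboratory comparison. Study
conditions (defaults): 14 laboratories; three blind samples at
2.56/3.41/4.54 Gy air kerma (2.71/3.60/4.80 Gy to blood); manual curves
with α ~ U[0.01, 0.069] Gy⁻¹, β ~ U[0.031, 0.097] Gy⁻², background
C ~ U[0.0005, 0.002] dic/cell (a typical range for healthy donors —
calibration backgrounds are rarely published); 200 cells per manual
blind sample and 3,500 per semi-automatic one (≈ 30% of labs
semi-automatic, ≈ 9/14 calibrated in air kerma, the rest in dose to
water); calibration design of 9 doses from 0 to 5 Gy with cells
decreasing 5,000 → 500, the usual "many cells at low dose, ~100
dicentrics at high dose" allocation.

Manual scoring draws Poisson per-cell counts. Semi-automatic scoring
draws gamma-mixed Poisson (negative-binomial) cells with
variance-to-mean ratio ~ U[1.05, 1.15]; any mixing law matching the
first two moments would reproduce the dispersion statistics, so the
gamma mixture is chosen for convenience. Each blind sample is generated
at the dose expressed on the laboratory's own calibration scale —
air-kerma labs see the kerma coordinate, water/blood labs the blood
coordinate — times an optional per-lab bias factor. This reproduces the
key field mechanism: laboratories calibrated in air kerma systematically
underestimate when judged against dose-to-blood references (by ≈ the
5.7% definition gap, i.e. 0.15–0.26 Gy at these doses).

Randomness: one seed per simulation; per-laboratory sub-streams are
spawned deterministically from it, so a lab's data is independent of lab
ordering. Identical seeds give byte-identical outputs.

What the generator does **not** emulate: metaphase image quality, culture
failure and slide-preparation problems, scorer-specific detection
efficiencies, the slight *under*dispersion real manual scoring shows at
high doses (cells carrying many dicentrics are less likely to be
scorable), dose-rate effects, and partial-body exposure. Passing tests
therefore demonstrate the correctness of the statistical chain under its
stated model, not the behaviour of any real laboratory.

## ILC evaluation

Reference selection supports three modes: air kerma, dose to blood, or
*matching* (air-kerma calibrations vs the kerma coordinate; dose-to-water
and dose-to-blood calibrations vs the blood coordinate — water is grouped
with blood since both sit a few percent above kerma for this geometry).
Z-scores use a pluggable σ rule, recorded in the report: `robust`
(default, 1.4826 × MAD of the participants' estimates, requiring ≥ 3
labs), `ci` (each lab's own interval width / 3.92), or `fixed:f`
(f × reference dose). The exact denominator used in past proficiency
exercises varies between networks, hence the choice is explicit
configuration, never a hidden constant. Thresholds: |z| > 1.96
questionable, |z| > 3 unsatisfactory (both configurable). A degenerate
spread (all estimates equal) makes the robust σ zero and the Z-score
raises an input error — a documented cascade rather than a silent NaN.

The systematic-bias rule is two-condition: all blind samples deviating
with one sign *and* at least two 95% CIs excluding the reference; labs
missing a sample are `not_classifiable`, distinct from `none`. Triage
categories place 1 Gy and 2 Gy in the middle class (closed interval);
the ±1 Gy band uses a closed comparison; ranking demands strict order
agreement (ties fail). Between-sample Pearson correlations of the lab
estimates are reported for every sample pair with ≥ 3 shared labs.

## Problem sizes and tolerances

Monte-Carlo checks in the acceptance layer use 500 calibration fits,
2,000 coverage replicates, 5,000 U-test replicates and 200 simulated
exercises — sizes at which each check resolves its target to a percent
or better while the whole suite runs in minutes on one CPU. Bisection
tolerances are 10⁻⁶ Gy for CI bounds and 10⁻¹² for conversion
round-trips; fit convergence is 10⁻¹⁰ relative deviance change.

## Known limitations

* Whole-body acute exposures only: no contaminated-Poisson/Dolphin
  partial-body estimation, no G-function protraction correction, no
  Bayesian dose estimation.
* The linear-quadratic form is fixed; no higher-order or linear-only
  (high-LET) variants.
* The kerma↔blood conversion is a lookup for one irradiation geometry,
  not a transport calculation; water conversions are unsupported.
* The Merkle component level (83%) is tuned to a 95% overall target;
  other overall levels fall back to using the requested level for both
  components rather than re-deriving an optimal split.
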