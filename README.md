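# dicentric

Cytogenetic biodosimetry toolkit for the dicentric chromosome assay:
linear-quadratic calibration-curve fitting, inverse dose estimation with
95% confidence intervals, dispersion statistics, and the evaluation of
blinded interlaboratory comparisons (ILCs).

## Who this is for

Biological dosimetry laboratories and network organisers who score
dicentric chromosomes in peripheral blood lymphocytes to estimate an
absorbed radiation dose, and who need a reproducible, scriptable chain
from raw count distributions to a proficiency report. The package also
ships a synthetic-data generator that emulates a multi-laboratory
exercise (heterogeneous calibration curves, manual vs semi-automatic
scoring, air-kerma vs dose-to-blood dose definitions), so every stage is
testable end to end without access to laboratory data.

## The model

The dicentric yield per cell after an acute, homogeneous low-LET
exposure follows the linear-quadratic dose-effect relation

    Y(D) = C + αD + βD²

with background frequency `C` (dic/cell), `α` (dic·cell⁻¹·Gy⁻¹) and `β`
(dic·cell⁻¹·Gy⁻²). Calibration data — total dicentrics `Xᵢ` in `Nᵢ`
cells at dose `Dᵢ` — are fitted by identity-link Poisson maximum
likelihood (IRLS, non-negative coefficients), with the inverse observed
Fisher information as the coefficient covariance.

A blind sample with `X` dicentrics in `N` cells is assigned the dose
`D̂` solving `Y(D̂) = X/N`. Confidence intervals come in two flavours:

* **curve_plus_yield** (default, Merkle-style): exact Garwood 83%
  Poisson limits on the observed yield are crossed with an 83%
  simultaneous confidence envelope of the fitted curve (chi-square,
  3 df); the combination targets ≈ 95% coverage on the dose.
* **yield_only**: inversion of the exact 95% Poisson yield limits,
  ignoring the curve's own error (the variant some dosimetry software
  reports).

Homogeneity of exposure is checked with the dispersion index
`δ = σ²/μ` and the Papworth U-test,
`u = (δ−1)·√((N−1)/(2(1−1/X)))`, with `|u| > 1.96` flagging a
significant departure from the Poisson expectation `δ = 1`.

ILC scoring compares each laboratory's estimates with reference doses
expressible as air kerma free in air or absorbed dose to blood (a
packaged conversion table maps 2.56/3.41/4.54 Gy air kerma to
2.71/3.60/4.80 Gy to blood): proficiency Z-scores
(`z = (D̂ − D_ref)/σ_p`, questionable beyond ±1.96), a two-condition
systematic-bias rule (all samples deviating one way *and* at least two
95% CIs excluding the reference), clinical triage categories
(< 1 Gy / 1–2 Gy / > 2 Gy), a ±1 Gy agreement band, dose ranking, and
between-sample correlation of the estimates.

## Worked example

```python
import numpy as np
import dicentric as dc

rng = np.random.default_rng(42)

# calibrate: simulate scoring at 9 doses on a known curve, then fit
truth = (0.0012, 0.04, 0.06)           # C, alpha, beta
doses = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
cells = (5000, 4000, 3000, 2500, 2000, 1500, 1000, 750, 500)
cal = [dc.simulate_distribution(truth, d, n, 1.0, rng)
       for d, n in zip(doses, cells)]
curve = dc.fit_lq_curve(cal)
print(f"C = {curve.background:.5f}, alpha = {curve.alpha:.4f}, "
      f"beta = {curve.beta:.4f}")

# a blind sample: 200 cells scored at a true dose of 3.41 Gy
sample = dc.simulate_distribution(truth, 3.41, 200, 1.0, rng)
est = dc.estimate_dose(curve, sample)
print(f"dose = {est.dose:.2f} Gy, 95% CI [{est.ci_low:.2f}, {est.ci_high:.2f}]")

res = dc.u_test(sample)
print(f"delta = {res.delta:.3f}, u = {res.u_statistic:.2f}")
print("blood dose:", round(dc.convert_dose(est.dose, "air_kerma",
                                           "dose_to_blood"), 2))
```

prints

```
C = 0.00169, alpha = 0.0398, beta = 0.0620
dose = 3.33 Gy, 95% CI [3.07, 3.61]
delta = 0.929, u = -0.71
blood dose: 3.51
```

The fitted coefficients recover the generating curve within sampling
error; the 200-cell blind sample (164 dicentrics) estimates 3.33 Gy with
a 95% interval that covers the true 3.41 Gy; the dispersion index near 1
is consistent with a homogeneous whole-body exposure; and the air-kerma
estimate converts to 3.51 Gy absorbed dose to blood.

A whole exercise runs in one call (or `dicentric full-run --seed 1
--out run/` from the shell):

```python
result = dc.run_ilc(dc.SimulationConfig(seed=1))
print(result.report.ci_coverage_fraction)
```

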