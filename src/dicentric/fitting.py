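"""Linear-quadratic dose-effect curve fitting by Poisson maximum likelihood.

The dicentric yield per cell is modelled as

    Y(D) = C + alpha * D + beta * D**2

with total dicentrics ``X_i ~ Poisson(N_i * Y(D_i))`` at each calibration
dose.  This is the identity-link Poisson generalised linear model that is
the convention for low-LET dicentric calibration curves.  The fit uses
Fisher scoring (iteratively reweighted least squares) with projection of
the coefficients onto the non-negative orthant, and reports the inverse
observed information as the coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import AberrationDistribution, DoseDefinition, ScoringMode, pool
from .errors import DesignError, FitConvergenceError, InputError

_YIELD_FLOOR = 1e-12


@dataclass(eq=False)
class CalibrationCurve:
    """Fitted (or externally supplied) linear-quadratic dose-effect curve.

    ``covariance`` is the 3x3 covariance of ``(C, alpha, beta)``; it may be
    ``None`` for curves published without uncertainties, in which case only
    confidence-interval methods that ignore the curve error are available.
    """

    background: float
    alpha: float
    beta: float
    covariance: np.ndarray | None = None
    dose_definition: DoseDefinition = DoseDefinition.AIR_KERMA
    scoring_mode: ScoringMode = ScoringMode.MANUAL
    max_calibration_dose: float = 5.0
    n_dose_points: int | None = None
    deviance: float | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if min(self.background, self.alpha, self.beta) < 0:
            raise InputError("curve coefficients must be non-negative")
        if self.max_calibration_dose <= 0:
            raise InputError("max_calibration_dose must be positive")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (3, 3):
                raise InputError("covariance must be 3x3 over (C, alpha, beta)")
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise InputError("covariance must be symmetric")
            if (np.diag(cov) < -1e-12).any():
                raise InputError("covariance diagonal must be non-negative")
            self.covariance = cov
        self.dose_definition = DoseDefinition(self.dose_definition)
        self.scoring_mode = ScoringMode(self.scoring_mode)

    def coefficients(self) -> np.ndarray:
        return np.array([self.background, self.alpha, self.beta])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CalibrationCurve):
            return NotImplemented
        same_cov = (
            (self.covariance is None and other.covariance is None)
            or (
                self.covariance is not None
                and other.covariance is not None
                and np.array_equal(self.covariance, other.covariance)
            )
        )
        return same_cov and (
            self.background,
            self.alpha,
            self.beta,
            self.dose_definition,
            self.scoring_mode,
            self.max_calibration_dose,
            self.n_dose_points,
            self.deviance,
            self.df,
        ) == (
            other.background,
            other.alpha,
            other.beta,
            other.dose_definition,
            other.scoring_mode,
            other.max_calibration_dose,
            other.n_dose_points,
            other.deviance,
            other.df,
        )


def curve_yield(curve: CalibrationCurve, dose) -> float | np.ndarray:
    """Predicted dicentric yield C + alpha*D + beta*D^2 at ``dose`` (Gy)."""
    dose = np.asarray(dose, dtype=float)
    if (dose < 0).any():
        raise InputError("dose must be non-negative")
    out = curve.background + curve.alpha * dose + curve.beta * dose**2
    return float(out) if out.ndim == 0 else out


def yield_variance(curve: CalibrationCurve, dose) -> float | np.ndarray:
    """Variance of the predicted yield, g' Sigma g with g = (1, D, D^2).

    Raises :class:`CapabilityError` when the curve has no covariance, which
    signals that only the yield-error-only dose CI is available.
    """
    from .errors import CapabilityError

    if curve.covariance is None:
        raise CapabilityError(
            "curve has no coefficient covariance; "
            "only the yield_only CI method is available"
        )
    dose = np.asarray(dose, dtype=float)
    if (dose < 0).any():
        raise InputError("dose must be non-negative")
    g = np.stack([np.ones_like(dose), dose, dose**2], axis=-1)
    out = np.einsum("...i,ij,...j->...", g, curve.covariance, g)
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def _deviance(n: np.ndarray, x: np.ndarray, mu: np.ndarray) -> float:
    fitted = n * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / fitted), 0.0)
    return float(2.0 * np.sum(term - (x - fitted)))


def fit_lq_curve(
    calibration_data: list[AberrationDistribution],
    *,
    dose_definition: DoseDefinition = DoseDefinition.AIR_KERMA,
    scoring_mode: ScoringMode = ScoringMode.MANUAL,
    quasi_poisson: bool = False,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CalibrationCurve:
    """Fit the linear-quadratic curve to per-dose count distributions.

    The Poisson likelihood depends on the data only through the per-dose
    totals ``(N_i, X_i)``, so replicate distributions at one dose are
    pooled before fitting.  At least three distinct dose points are needed
    to identify the three coefficients.

    With ``quasi_poisson=True`` the covariance is inflated by the factor
    ``deviance / df`` when that exceeds 1, a quasi-likelihood allowance
    for overdispersed calibration data (off by default).
    """
    totals = pool(calibration_data)
    if len(totals) < 3:
        raise DesignError(
            f"need >= 3 distinct dose points to fit 3 coefficients, "
            f"got {len(totals)}"
        )
    doses = np.array(list(totals))
    n = np.array([totals[d][0] for d in totals], dtype=float)
    x = np.array([totals[d][1] for d in totals], dtype=float)
    g = np.stack([np.ones_like(doses), doses, doses**2], axis=1)

    # start from a cell-weighted least-squares fit to the raw rates
    rates = x / n
    sw = np.sqrt(n)
    theta, *_ = np.linalg.lstsq(g * sw[:, None], rates * sw, rcond=None)
    theta = np.clip(theta, 0.0, None)

    dev = np.inf
    converged = False
    for _ in range(max_iter):
        mu = np.maximum(g @ theta, _YIELD_FLOOR)
        w = n / mu
        a = g.T @ (w[:, None] * g)
        b = g.T @ (x / mu)
        try:
            theta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
            raise DesignError(f"singular calibration design: {exc}") from exc
        theta = np.clip(theta, 0.0, None)
        mu = np.maximum(g @ theta, _YIELD_FLOOR)
        dev_new = _deviance(n, x, mu)
        # relative deviance change, with an absolute floor for exact fits
        if abs(dev_new - dev) <= tol * (abs(dev_new) + 1.0):
            dev = dev_new
            converged = True
            break
        dev = dev_new

    mu = np.maximum(g @ theta, _YIELD_FLOOR)
    # observed information for the identity-link Poisson likelihood
    info = g.T @ ((x / mu**2)[:, None] * g)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    cov = (cov + cov.T) / 2.0

    df = len(doses) - 3
    if quasi_poisson and df > 0:
        cov = cov * max(1.0, dev / df)

    curve = CalibrationCurve(
        background=float(theta[0]),
        alpha=float(theta[1]),
        beta=float(theta[2]),
        covariance=cov,
        dose_definition=dose_definition,
        scoring_mode=scoring_mode,
        max_calibration_dose=float(doses.max()),
        n_dose_points=len(doses),
        deviance=dev,
        df=df,
    )
    if not converged:
        raise FitConvergenceError(
            f"IRLS did not converge within {max_iter} iterations "
            f"(last deviance {dev:.6g})",
            last_curve=curve,
        )
    return curve
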