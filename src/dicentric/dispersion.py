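"""Dispersion index and the Papworth U-test.

For a homogeneous acute whole-body exposure the per-cell dicentric counts
are Poisson, so the dispersion index

    delta = sigma^2 / mu

is 1 in expectation.  Overdispersion (delta > 1) is the classical signal
of a heterogeneous or partial-body exposure; the U-test standardises the
departure of delta from 1 against its Poisson sampling distribution:

    u = (delta - 1) * sqrt((N - 1) / (2 * (1 - 1/X)))

with N scored cells and X total dicentrics.  Under the Poisson null, u is
approximately standard normal, so |u| > 1.96 flags a significant
departure at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .counts import AberrationDistribution
from .errors import InputError


class Direction(str, Enum):
    OVER = "over"
    UNDER = "under"
    NONE = "none"


def critical_value(alpha: float = 0.05) -> float:
    """Two-sided standard-normal critical value, 1.96 at the 5% level."""
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


@dataclass(frozen=True)
class DispersionResult:
    """Dispersion index with its U-test verdict for one scored sample."""

    delta: float
    u_statistic: float
    significant: bool  # two-sided: |u| > threshold
    significant_over: bool  # one-sided: u > threshold
    direction: Direction
    n_cells: int
    total_dicentrics: int
    threshold: float = 1.96


def dispersion_index(sample: AberrationDistribution) -> float:
    """Variance-to-mean ratio of the per-cell dicentric counts.

    The variance uses the unbiased N-1 denominator.  Undefined when no
    dicentric was scored (mean zero).
    """
    if sample.n_cells < 2:
        raise InputError("dispersion index needs at least 2 cells")
    if sample.total_dicentrics < 1:
        raise InputError("dispersion index is undefined for a zero mean (X = 0)")
    return sample.sample_variance() / sample.mean_yield


def u_test(
    sample: AberrationDistribution, threshold: float = 1.96
) -> DispersionResult:
    """Papworth U-test for departure of the dispersion index from 1."""
    n = sample.n_cells
    x = sample.total_dicentrics
    if n < 2:
        raise InputError("U-test needs at least 2 cells")
    if x < 2:
        raise InputError(
            f"U-test needs at least 2 dicentrics so that the factor "
            f"1 - 1/X is positive and finite; got X={x}"
        )
    delta = dispersion_index(sample)
    u = (delta - 1.0) * np.sqrt((n - 1) / (2.0 * (1.0 - 1.0 / x)))
    significant = bool(abs(u) > threshold)
    if significant:
        direction = Direction.OVER if u > 0 else Direction.UNDER
    else:
        direction = Direction.NONE
    return DispersionResult(
        delta=float(delta),
        u_statistic=float(u),
        significant=significant,
        significant_over=bool(u > threshold),
        direction=direction,
        n_cells=n,
        total_dicentrics=x,
        threshold=threshold,
    )


def mean_dispersion(results: list[DispersionResult]) -> float:
    """Unweighted mean of the dispersion indices across laboratories."""
    if not results:
        raise InputError("mean_dispersion needs a non-empty list")
    return float(np.mean([r.delta for r in results]))
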