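import numpy as np
import pytest

from dicentric import (
    AberrationDistribution,
    CalibrationCurve,
    fit_lq_curve,
    simulate_distribution,
)

TRUTH = (0.001, 0.03, 0.05)
CAL_DOSES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
CAL_CELLS = (5000, 4000, 3000, 2500, 2000, 1500, 1000, 750, 500)


@pytest.fixture
def rng():
    return np.random.default_rng(2023)


@pytest.fixture
def simple_curve():
    """Curve with easy hand-checkable coefficients and a known covariance."""
    return CalibrationCurve(
        background=0.001,
        alpha=0.02,
        beta=0.06,
        covariance=np.diag([1e-8, 1e-6, 1e-7]),
        max_calibration_dose=5.0,
    )


@pytest.fixture(scope="session")
def fitted_curve():
    """Curve fitted once from a simulated default-design calibration."""
    rng = np.random.default_rng(12345)
    cal = [
        simulate_distribution(TRUTH, d, n, 1.0, rng)
        for d, n in zip(CAL_DOSES, CAL_CELLS)
    ]
    return fit_lq_curve(cal)


def spectrum(counts: dict[int, int], **kw) -> AberrationDistribution:
    return AberrationDistribution(counts=counts, **kw)
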