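"""Synthetic interlaboratory-comparison data with the study's structure.

The generator emulates a blinded dicentric-assay exercise: a handful of
blood samples irradiated at known doses (expressed as air kerma free in
air, with the corresponding absorbed dose to blood a few percent higher)
are scored by laboratories whose dose-effect curves, scoring modes and
cell numbers are heterogeneous.  Manual scoring produces Poisson per-cell
counts; semi-automatic scoring is allowed to be overdispersed, modelled
as a gamma-mixed Poisson (negative binomial) cell whose variance-to-mean
ratio is the configured dispersion.

Each laboratory draws from its own deterministic RNG sub-stream, so one
lab's data is independent of lab ordering and of the other labs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .counts import AberrationDistribution, DoseDefinition, ScoringMode
from .errors import ConfigurationError, InputError

#: Blind doses of the packaged study conditions, air kerma free in air (Gy).
DEFAULT_BLIND_DOSES_AIR_KERMA = (2.56, 3.41, 4.54)
#: Matching absorbed dose to blood (Gy) from photon-transport calculations.
DEFAULT_BLIND_DOSES_TO_BLOOD = (2.71, 3.60, 4.80)

_DEFAULT_FACTORS = tuple(
    b / k for k, b in zip(DEFAULT_BLIND_DOSES_AIR_KERMA, DEFAULT_BLIND_DOSES_TO_BLOOD)
)

#: Default calibration design: 9 doses up to 5 Gy with cell numbers
#: decreasing from 5,000 at 0 Gy to 500 at the top dose, the usual
#: "many cells at low dose, ~100 dicentrics at high dose" allocation.
DEFAULT_CALIBRATION_DOSES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
DEFAULT_CALIBRATION_CELLS = (5000, 4000, 3000, 2500, 2000, 1500, 1000, 750, 500)


def _check_range(name: str, rng: tuple[float, float], lower_bound: float = 0.0) -> None:
    lo, hi = rng
    if not (lower_bound <= lo <= hi):
        raise ConfigurationError(
            f"{name} must satisfy {lower_bound} <= lower <= upper, got {rng}"
        )


@dataclass(frozen=True)
class LabProfile:
    """Ground-truth characteristics of one simulated laboratory."""

    lab_id: str
    alpha: float  # dicentrics / cell / Gy
    beta: float  # dicentrics / cell / Gy^2
    background: float  # dicentrics / cell
    dose_definition: DoseDefinition
    scoring_mode: ScoringMode
    cells_per_blind_sample: int
    calibration_doses: tuple[float, ...]
    cells_per_calibration_dose: tuple[int, ...]
    dispersion: float = 1.0
    bias_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.background) < 0:
            raise ConfigurationError("curve coefficients must be non-negative")
        doses = tuple(float(d) for d in self.calibration_doses)
        if any(d < 0 for d in doses) or any(
            b <= a for a, b in zip(doses, doses[1:])
        ):
            raise ConfigurationError(
                "calibration_doses must be strictly increasing and non-negative"
            )
        cells = self.cells_per_calibration_dose
        if isinstance(cells, (int, np.integer)):
            cells = (int(cells),) * len(doses)
        cells = tuple(int(c) for c in cells)
        if len(cells) != len(doses):
            raise ConfigurationError(
                "cells_per_calibration_dose must match calibration_doses in length"
            )
        if any(c < 1 for c in cells) or self.cells_per_blind_sample < 1:
            raise ConfigurationError("cell numbers must be positive")
        if self.dispersion < 1.0:
            raise ConfigurationError("dispersion must be >= 1 (1 = Poisson)")
        if self.bias_factor <= 0:
            raise ConfigurationError("bias_factor must be positive")
        object.__setattr__(self, "calibration_doses", doses)
        object.__setattr__(self, "cells_per_calibration_dose", cells)
        object.__setattr__(self, "dose_definition", DoseDefinition(self.dose_definition))
        object.__setattr__(self, "scoring_mode", ScoringMode(self.scoring_mode))

    @property
    def curve_params(self) -> tuple[float, float, float]:
        return (self.background, self.alpha, self.beta)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated interlaboratory comparison.

    The defaults reproduce the packaged exercise: 14 laboratories, three
    blind samples at 2.56/3.41/4.54 Gy air kerma (2.71/3.60/4.80 Gy to
    blood), manual curves with alpha in [0.01, 0.069] Gy^-1 and beta in
    [0.031, 0.097] Gy^-2, 200 cells per manual blind sample and thousands
    per semi-automatic one.
    """

    n_labs: int = 14
    blind_doses_air_kerma: tuple[float, ...] = DEFAULT_BLIND_DOSES_AIR_KERMA
    kerma_to_blood_factor: tuple[float, ...] = _DEFAULT_FACTORS
    alpha_range: tuple[float, float] = (0.01, 0.069)
    beta_range: tuple[float, float] = (0.031, 0.097)
    background_range: tuple[float, float] = (0.0005, 0.002)
    fraction_semi_automatic: float = 0.3
    fraction_air_kerma: float = 9 / 14
    semi_auto_dispersion_range: tuple[float, float] = (1.05, 1.15)
    manual_cells_per_blind: int = 200
    semi_auto_cells_per_blind: int = 3500
    calibration_doses: tuple[float, ...] = DEFAULT_CALIBRATION_DOSES
    calibration_cells: tuple[int, ...] = DEFAULT_CALIBRATION_CELLS
    bias_factors: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labs < 1:
            raise ConfigurationError("n_labs must be positive")
        if not self.blind_doses_air_kerma or any(
            d <= 0 for d in self.blind_doses_air_kerma
        ):
            raise ConfigurationError("blind_doses_air_kerma must be non-empty and > 0")
        factors = self.kerma_to_blood_factor
        if isinstance(factors, (int, float)):
            factors = (float(factors),) * len(self.blind_doses_air_kerma)
        factors = tuple(float(f) for f in factors)
        if len(factors) != len(self.blind_doses_air_kerma):
            raise ConfigurationError(
                "kerma_to_blood_factor must match blind_doses_air_kerma in length"
            )
        if any(f <= 0 for f in factors):
            raise ConfigurationError("kerma_to_blood_factor entries must be positive")
        _check_range("alpha_range", self.alpha_range)
        _check_range("beta_range", self.beta_range)
        _check_range("background_range", self.background_range)
        _check_range("semi_auto_dispersion_range", self.semi_auto_dispersion_range, 1.0)
        for name in ("fraction_semi_automatic", "fraction_air_kerma"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        object.__setattr__(
            self, "blind_doses_air_kerma", tuple(self.blind_doses_air_kerma)
        )
        object.__setattr__(self, "kerma_to_blood_factor", factors)
        object.__setattr__(self, "calibration_doses", tuple(self.calibration_doses))
        object.__setattr__(self, "calibration_cells", tuple(self.calibration_cells))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(len(self.blind_doses_air_kerma)))

    @property
    def blind_doses_to_blood(self) -> tuple[float, ...]:
        return tuple(
            k * f
            for k, f in zip(self.blind_doses_air_kerma, self.kerma_to_blood_factor)
        )


@dataclass(frozen=True)
class GroundTruth:
    """Unblinded payload of a simulated exercise."""

    samples: tuple[tuple[str, float, float], ...]  # (sample_id, kerma, blood)
    profiles: dict[str, LabProfile]

    def __post_init__(self) -> None:
        for _, kerma, blood in self.samples:
            if blood <= 0 or kerma <= 0:
                raise ConfigurationError("reference doses must be positive")


@dataclass(frozen=True)
class ILCDataset:
    """Blinded payload: per-lab calibration and blind-sample distributions."""

    calibration: dict[str, list[AberrationDistribution]]
    blind: dict[str, dict[str, AberrationDistribution]]
    ground_truth: GroundTruth


def sample_lab_profile(
    config: SimulationConfig,
    rng: np.random.Generator,
    lab_id: str = "L1",
) -> LabProfile:
    """Draw one laboratory profile from the configured ranges."""
    alpha = float(rng.uniform(*config.alpha_range))
    beta = float(rng.uniform(*config.beta_range))
    background = float(rng.uniform(*config.background_range))
    semi = bool(rng.random() < config.fraction_semi_automatic)
    mode = ScoringMode.SEMI_AUTOMATIC if semi else ScoringMode.MANUAL
    dispersion = (
        float(rng.uniform(*config.semi_auto_dispersion_range)) if semi else 1.0
    )
    definition = (
        DoseDefinition.AIR_KERMA
        if rng.random() < config.fraction_air_kerma
        else DoseDefinition.DOSE_TO_WATER
    )
    cells_blind = (
        config.semi_auto_cells_per_blind if semi else config.manual_cells_per_blind
    )
    return LabProfile(
        lab_id=lab_id,
        alpha=alpha,
        beta=beta,
        background=background,
        dose_definition=definition,
        scoring_mode=mode,
        cells_per_blind_sample=cells_blind,
        calibration_doses=config.calibration_doses,
        cells_per_calibration_dose=config.calibration_cells,
        dispersion=dispersion,
        bias_factor=config.bias_factors.get(lab_id, 1.0),
    )


def simulate_distribution(
    curve_params: tuple[float, float, float],
    dose: float,
    n_cells: int,
    dispersion: float = 1.0,
    rng: np.random.Generator | None = None,
) -> AberrationDistribution:
    """Draw a per-cell dicentric count spectrum at one dose.

    The cell mean is ``C + alpha*D + beta*D^2``.  ``dispersion = 1`` gives
    Poisson cells; ``dispersion > 1`` mixes the Poisson mean with a gamma
    variable so that the per-cell variance-to-mean ratio equals
    ``dispersion`` (negative-binomial cells).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_cells < 1:
        raise InputError(f"n_cells must be >= 1, got {n_cells}")
    if dose < 0:
        raise InputError(f"dose must be >= 0, got {dose}")
    if dispersion < 1.0:
        raise InputError(f"dispersion must be >= 1, got {dispersion}")
    c, alpha, beta = curve_params
    mean = c + alpha * dose + beta * dose**2
    if mean < 0:
        raise InputError("curve parameters give a negative mean yield")
    if mean == 0.0:
        cells = np.zeros(n_cells, dtype=np.int64)
    elif dispersion == 1.0:
        cells = rng.poisson(mean, size=n_cells)
    else:
        shape = mean / (dispersion - 1.0)
        lam = rng.gamma(shape=shape, scale=dispersion - 1.0, size=n_cells)
        cells = rng.poisson(lam)
    return AberrationDistribution.from_cells(cells, dose=dose)


def simulate_ilc(config: SimulationConfig) -> ILCDataset:
    """Simulate the full blinded exercise for every configured laboratory."""
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(config.n_labs)
    calibration: dict[str, list[AberrationDistribution]] = {}
    blind: dict[str, dict[str, AberrationDistribution]] = {}
    profiles: dict[str, LabProfile] = {}

    blood_doses = config.blind_doses_to_blood
    for i in range(config.n_labs):
        lab_id = f"L{i + 1}"
        rng = np.random.default_rng(children[i])
        profile = sample_lab_profile(config, rng, lab_id=lab_id)
        profiles[lab_id] = profile

        calibration[lab_id] = [
            simulate_distribution(
                profile.curve_params, d, c, profile.dispersion, rng
            )
            for d, c in zip(
                profile.calibration_doses, profile.cells_per_calibration_dose
            )
        ]

        lab_blind: dict[str, AberrationDistribution] = {}
        for sid, kerma, blood in zip(
            config.sample_ids, config.blind_doses_air_kerma, blood_doses
        ):
            # dose the sample "looks like" on the lab's own calibration scale
            scale_dose = (
                kerma
                if profile.dose_definition is DoseDefinition.AIR_KERMA
                else blood
            )
            effective = scale_dose * profile.bias_factor
            dist = simulate_distribution(
                profile.curve_params,
                effective,
                profile.cells_per_blind_sample,
                profile.dispersion,
                rng,
            )
            lab_blind[sid] = AberrationDistribution(
                counts=dist.counts, dose=None, sample_id=sid
            )
        blind[lab_id] = lab_blind

    truth = GroundTruth(
        samples=tuple(
            (sid, kerma, blood)
            for sid, kerma, blood in zip(
                config.sample_ids, config.blind_doses_air_kerma, blood_doses
            )
        ),
        profiles=profiles,
    )
    return ILCDataset(calibration=calibration, blind=blind, ground_truth=truth)
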