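"""Scoring an interlaboratory comparison.

Each laboratory submits a point dose estimate with a 95% confidence
interval per blind sample.  The evaluation compares every estimate with a
reference dose (selectable as air kerma, absorbed dose to blood, or the
definition matching the lab's own calibration), computes proficiency
Z-scores, classifies laboratory-level systematic bias, assigns clinical
triage categories, and checks the +/- 1 Gy band and the dose ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from itertools import combinations

import numpy as np
from scipy import stats

from .counts import DoseDefinition, ScoringMode
from .errors import InputError


class ReferenceMode(str, Enum):
    AIR_KERMA = "air_kerma"
    DOSE_TO_BLOOD = "dose_to_blood"
    MATCHING = "matching"


class BiasClass(str, Enum):
    SYSTEMATIC_OVER = "systematic_over"
    SYSTEMATIC_UNDER = "systematic_under"
    NONE = "none"
    NOT_CLASSIFIABLE = "not_classifiable"


class TriageCategory(str, Enum):
    LOW = "low"  # < 1 Gy
    MEDIUM = "medium"  # 1-2 Gy inclusive
    HIGH = "high"  # > 2 Gy


class ZFlag(str, Enum):
    OK = "ok"
    QUESTIONABLE = "questionable"  # |z| > 1.96
    UNSATISFACTORY = "unsatisfactory"  # |z| > 3


@dataclass(frozen=True)
class LabSubmission:
    """One laboratory's reported result for one blind sample."""

    lab_id: str
    sample_id: str
    scoring_mode: ScoringMode
    dose_estimate: float
    ci_low: float
    ci_high: float
    dose_definition: DoseDefinition
    n_cells: int
    n_dicentrics: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.dose_estimate <= self.ci_high:
            raise InputError(
                f"{self.lab_id}/{self.sample_id}: require "
                f"ci_low <= dose <= ci_high"
            )
        if self.n_cells < 1 or self.n_dicentrics < 0:
            raise InputError(
                f"{self.lab_id}/{self.sample_id}: invalid cell/dicentric counts"
            )
        object.__setattr__(self, "scoring_mode", ScoringMode(self.scoring_mode))
        object.__setattr__(
            self, "dose_definition", DoseDefinition(self.dose_definition)
        )


@dataclass(frozen=True)
class ReferenceDose:
    """Reference dose of one blind sample in both dosimetric definitions."""

    sample_id: str
    air_kerma: float
    dose_to_blood: float

    def __post_init__(self) -> None:
        if not self.dose_to_blood > self.air_kerma > 0:
            raise InputError(
                f"{self.sample_id}: require dose_to_blood > air_kerma > 0 "
                f"for this irradiation geometry"
            )


@dataclass(frozen=True)
class EvaluationConfig:
    reference_mode: ReferenceMode = ReferenceMode.MATCHING
    sigma_rule: str = "robust"  # robust | ci | fixed:<f>
    z_questionable: float = 1.96
    z_unsatisfactory: float = 3.0
    band: float = 1.0  # Gy

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_mode", ReferenceMode(self.reference_mode))
        rule = self.sigma_rule
        if rule not in ("robust", "ci") and not rule.startswith("fixed:"):
            raise InputError(f"unknown sigma rule {rule!r}")
        if self.band <= 0:
            raise InputError("band must be positive")


@dataclass(frozen=True)
class SampleRecord:
    """Per-(lab, sample) evaluation row."""

    lab_id: str
    sample_id: str
    scoring_mode: str
    dose_estimate: float
    ci_low: float
    ci_high: float
    reference: float
    deviation: float
    z_score: float
    z_flag: str
    ci_contains_reference: bool
    triage_category: str
    within_band: bool


@dataclass(frozen=True)
class LabSummary:
    lab_id: str
    bias_class: str
    ranking_correct: bool


@dataclass(frozen=True)
class PairCorrelation:
    sample_a: str
    sample_b: str
    r: float
    p_value: float


@dataclass(frozen=True)
class ILCReport:
    reference_mode: str
    sigma_rule: str
    records: tuple[SampleRecord, ...]
    lab_summaries: tuple[LabSummary, ...]
    correlations: tuple[PairCorrelation, ...]
    ci_coverage_fraction: dict[str, float]
    z_questionable: float = 1.96
    z_unsatisfactory: float = 3.0
    band: float = 1.0

    def to_dict(self) -> dict:
        return {
            "reference_mode": self.reference_mode,
            "sigma_rule": self.sigma_rule,
            "records": [asdict(r) for r in self.records],
            "lab_summaries": [asdict(s) for s in self.lab_summaries],
            "correlations": [asdict(c) for c in self.correlations],
            "ci_coverage_fraction": dict(self.ci_coverage_fraction),
            "z_questionable": self.z_questionable,
            "z_unsatisfactory": self.z_unsatisfactory,
            "band": self.band,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ILCReport":
        return cls(
            reference_mode=payload["reference_mode"],
            sigma_rule=payload["sigma_rule"],
            records=tuple(SampleRecord(**r) for r in payload["records"]),
            lab_summaries=tuple(LabSummary(**s) for s in payload["lab_summaries"]),
            correlations=tuple(
                PairCorrelation(**c) for c in payload["correlations"]
            ),
            ci_coverage_fraction=dict(payload["ci_coverage_fraction"]),
            z_questionable=payload["z_questionable"],
            z_unsatisfactory=payload["z_unsatisfactory"],
            band=payload["band"],
        )


# -- elementary metrics -------------------------------------------------------


def select_reference(
    ref: ReferenceDose,
    submission: LabSubmission,
    mode: ReferenceMode | str,
) -> float:
    """Reference coordinate the submission is judged against.

    In ``matching`` mode an air-kerma calibration is compared with the
    air-kerma reference, while dose-to-water and dose-to-blood
    calibrations are compared with the dose-to-blood reference.
    """
    mode = ReferenceMode(mode)
    if mode is ReferenceMode.AIR_KERMA:
        return ref.air_kerma
    if mode is ReferenceMode.DOSE_TO_BLOOD:
        return ref.dose_to_blood
    if submission.dose_definition is DoseDefinition.AIR_KERMA:
        return ref.air_kerma
    return ref.dose_to_blood


def z_score(estimate: float, reference: float, sigma_p: float) -> float:
    """Proficiency Z-score (estimate - reference) / sigma_p."""
    if sigma_p <= 0:
        raise InputError(f"sigma_p must be positive, got {sigma_p}")
    return (estimate - reference) / sigma_p


def flag_z(z: float, questionable: float = 1.96, unsatisfactory: float = 3.0) -> ZFlag:
    if abs(z) > unsatisfactory:
        return ZFlag.UNSATISFACTORY
    if abs(z) > questionable:
        return ZFlag.QUESTIONABLE
    return ZFlag.OK


def proficiency_sigma(
    submissions: list[LabSubmission],
    rule: str = "robust",
    reference: float | None = None,
) -> np.ndarray:
    """Per-submission proficiency sigma for one blind sample.

    ``robust``: 1.4826 x median absolute deviation of the participants'
    estimates (one shared value, needs >= 3 submissions).  ``ci``: each
    lab's (ci_high - ci_low) / (2 * 1.96).  ``fixed:<f>``: f times the
    reference dose.
    """
    if not submissions:
        raise InputError("no submissions for this sample")
    estimates = np.array([s.dose_estimate for s in submissions])
    if rule == "robust":
        if len(submissions) < 3:
            raise InputError(
                f"robust sigma rule needs >= 3 submissions, got {len(submissions)}"
            )
        mad = np.median(np.abs(estimates - np.median(estimates)))
        return np.full(len(submissions), 1.4826 * mad)
    if rule == "ci":
        return np.array([(s.ci_high - s.ci_low) / (2 * 1.96) for s in submissions])
    if rule.startswith("fixed:"):
        frac = float(rule.split(":", 1)[1])
        if frac <= 0:
            raise InputError(f"fixed sigma fraction must be positive, got {frac}")
        if reference is None:
            raise InputError("fixed sigma rule needs the reference dose")
        return np.full(len(submissions), frac * reference)
    raise InputError(f"unknown sigma rule {rule!r}")


def triage_category(dose: float) -> TriageCategory:
    """Clinical triage category: < 1 Gy low, 1-2 Gy medium, > 2 Gy high."""
    if dose < 0:
        raise InputError(f"dose must be non-negative, got {dose}")
    if dose < 1.0:
        return TriageCategory.LOW
    if dose <= 2.0:
        return TriageCategory.MEDIUM
    return TriageCategory.HIGH


def within_band(estimate: float, reference: float, band: float = 1.0) -> bool:
    """Whether the estimate lies within +/- ``band`` Gy of the reference."""
    if band <= 0:
        raise InputError(f"band must be positive, got {band}")
    return abs(estimate - reference) <= band


def ranking_correct(
    estimates: dict[str, float], references: dict[str, float]
) -> bool:
    """Whether the lab's estimates strictly rank the samples as the references do."""
    if set(estimates) != set(references):
        raise InputError("estimates and references cover different sample sets")
    order = sorted(references, key=references.get)
    values = [estimates[s] for s in order]
    return all(a < b for a, b in zip(values, values[1:]))


def classify_bias(
    submissions: list[LabSubmission],
    references: dict[str, ReferenceDose],
    mode: ReferenceMode | str = ReferenceMode.MATCHING,
) -> BiasClass:
    """Two-condition systematic-bias rule for one laboratory.

    A lab systematically over-(under-)estimates when (1) every blind
    sample is over-(under-)estimated and (2) at least two of its 95%
    confidence intervals exclude the reference dose.
    """
    covered = {s.sample_id for s in submissions}
    if covered != set(references):
        return BiasClass.NOT_CLASSIFIABLE
    deviations, excludes = [], 0
    for sub in submissions:
        ref = select_reference(references[sub.sample_id], sub, mode)
        deviations.append(sub.dose_estimate - ref)
        if not (sub.ci_low <= ref <= sub.ci_high):
            excludes += 1
    if excludes >= 2:
        if all(d > 0 for d in deviations):
            return BiasClass.SYSTEMATIC_OVER
        if all(d < 0 for d in deviations):
            return BiasClass.SYSTEMATIC_UNDER
    return BiasClass.NONE


def estimate_correlation(
    estimates_a: dict[str, float], estimates_b: dict[str, float]
) -> tuple[float, float]:
    """Pearson correlation of two samples' dose estimates across labs."""
    labs = sorted(set(estimates_a) & set(estimates_b))
    if len(labs) < 3:
        raise InputError(
            f"correlation needs >= 3 labs present in both samples, got {len(labs)}"
        )
    a = np.array([estimates_a[l] for l in labs])
    b = np.array([estimates_b[l] for l in labs])
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# -- full evaluation ----------------------------------------------------------


def evaluate_ilc(
    submissions: list[LabSubmission],
    references: list[ReferenceDose],
    config: EvaluationConfig = EvaluationConfig(),
) -> ILCReport:
    """Compute the full proficiency report for one exercise."""
    if not submissions:
        raise InputError("need at least one submission")
    refs = {r.sample_id: r for r in references}
    by_sample: dict[str, list[LabSubmission]] = {}
    by_lab: dict[str, list[LabSubmission]] = {}
    for sub in submissions:
        if sub.sample_id not in refs:
            raise InputError(f"submission for unknown sample {sub.sample_id!r}")
        by_sample.setdefault(sub.sample_id, []).append(sub)
        by_lab.setdefault(sub.lab_id, []).append(sub)

    records: list[SampleRecord] = []
    coverage: dict[str, float] = {}
    for sid in sorted(by_sample, key=lambda s: refs[s].air_kerma):
        subs = sorted(by_sample[sid], key=lambda s: s.lab_id)
        ref_values = np.array(
            [select_reference(refs[sid], s, config.reference_mode) for s in subs]
        )
        sigmas = proficiency_sigma(
            subs, config.sigma_rule, reference=float(np.median(ref_values))
        )
        contains = 0
        for sub, ref_value, sigma in zip(subs, ref_values, sigmas):
            z = z_score(sub.dose_estimate, float(ref_value), float(sigma))
            inside = bool(sub.ci_low <= ref_value <= sub.ci_high)
            contains += inside
            records.append(
                SampleRecord(
                    lab_id=sub.lab_id,
                    sample_id=sid,
                    scoring_mode=sub.scoring_mode.value,
                    dose_estimate=sub.dose_estimate,
                    ci_low=sub.ci_low,
                    ci_high=sub.ci_high,
                    reference=float(ref_value),
                    deviation=float(sub.dose_estimate - ref_value),
                    z_score=float(z),
                    z_flag=flag_z(
                        z, config.z_questionable, config.z_unsatisfactory
                    ).value,
                    ci_contains_reference=inside,
                    triage_category=triage_category(sub.dose_estimate).value,
                    within_band=bool(
                        within_band(sub.dose_estimate, float(ref_value), config.band)
                    ),
                )
            )
        coverage[sid] = contains / len(subs)

    summaries: list[LabSummary] = []
    for lab_id in sorted(by_lab):
        subs = by_lab[lab_id]
        bias = classify_bias(subs, refs, config.reference_mode)
        if {s.sample_id for s in subs} == set(refs):
            est = {s.sample_id: s.dose_estimate for s in subs}
            ref_coord = {
                s.sample_id: select_reference(
                    refs[s.sample_id], s, config.reference_mode
                )
                for s in subs
            }
            ranked = ranking_correct(est, ref_coord)
        else:
            ranked = False
        summaries.append(
            LabSummary(lab_id=lab_id, bias_class=bias.value, ranking_correct=ranked)
        )

    correlations: list[PairCorrelation] = []
    sample_order = sorted(by_sample, key=lambda s: refs[s].air_kerma)
    for sa, sb in combinations(sample_order, 2):
        ea = {s.lab_id: s.dose_estimate for s in by_sample[sa]}
        eb = {s.lab_id: s.dose_estimate for s in by_sample[sb]}
        try:
            r, p = estimate_correlation(ea, eb)
        except InputError:
            continue
        correlations.append(PairCorrelation(sample_a=sa, sample_b=sb, r=r, p_value=p))

    return ILCReport(
        reference_mode=ReferenceMode(config.reference_mode).value,
        sigma_rule=config.sigma_rule,
        records=tuple(records),
        lab_summaries=tuple(summaries),
        correlations=tuple(correlations),
        ci_coverage_fraction=coverage,
        z_questionable=config.z_questionable,
        z_unsatisfactory=config.z_unsatisfactory,
        band=config.band,
    )
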