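import numpy as np
import pytest

from dicentric import (
    BiasClass,
    DoseDefinition,
    EvaluationConfig,
    InputError,
    LabSubmission,
    ReferenceDose,
    ReferenceMode,
    ScoringMode,
    TriageCategory,
    classify_bias,
    estimate_correlation,
    evaluate_ilc,
    proficiency_sigma,
    ranking_correct,
    select_reference,
    triage_category,
    within_band,
    z_score,
)

REFS = [
    ReferenceDose("S1", 2.56, 2.71),
    ReferenceDose("S2", 3.41, 3.60),
    ReferenceDose("S3", 4.54, 4.80),
]


def sub(lab, sample, dose, lo, hi, definition=DoseDefinition.AIR_KERMA):
    return LabSubmission(
        lab_id=lab,
        sample_id=sample,
        scoring_mode=ScoringMode.MANUAL,
        dose_estimate=dose,
        ci_low=lo,
        ci_high=hi,
        dose_definition=definition,
        n_cells=200,
        n_dicentrics=100,
    )


class TestSelectReference:
    def test_air_kerma_mode(self):
        s = sub("L1", "S1", 2.6, 2.2, 3.0)
        assert select_reference(REFS[0], s, ReferenceMode.AIR_KERMA) == 2.56

    def test_matching_mode_groups_water_with_blood(self):
        s = sub("L1", "S1", 2.6, 2.2, 3.0, DoseDefinition.DOSE_TO_WATER)
        assert select_reference(REFS[0], s, ReferenceMode.MATCHING) == 2.71
        s2 = sub("L1", "S1", 2.6, 2.2, 3.0, DoseDefinition.AIR_KERMA)
        assert select_reference(REFS[0], s2, ReferenceMode.MATCHING) == 2.56

    def test_blood_mode_is_lab_independent(self):
        for definition in DoseDefinition:
            s = sub("L1", "S1", 2.6, 2.2, 3.0, definition)
            assert select_reference(REFS[0], s, ReferenceMode.DOSE_TO_BLOOD) == 2.71


class TestZScore:
    def test_zero_at_reference(self):
        assert z_score(2.56, 2.56, 0.2) == 0.0

    def test_hand_arithmetic(self):
        assert z_score(3.0, 2.56, 0.22) == pytest.approx(2.0)

    def test_antisymmetry(self):
        assert z_score(3.0, 2.5, 0.1) == -z_score(2.0, 2.5, 0.1)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InputError):
            z_score(3.0, 2.5, 0.0)


class TestProficiencySigma:
    def test_robust_mad_rule(self):
        subs = [sub("L1", "S1", 2.0, 1, 3), sub("L2", "S1", 2.5, 1, 3),
                sub("L3", "S1", 3.0, 1, 3)]
        sigma = proficiency_sigma(subs, "robust")
        assert sigma == pytest.approx([0.7413] * 3, abs=1e-4)

    def test_robust_needs_three_labs(self):
        with pytest.raises(InputError):
            proficiency_sigma([sub("L1", "S1", 2.0, 1, 3)], "robust")

    def test_degenerate_spread_cascades_to_z_error(self):
        subs = [sub(f"L{i}", "S1", 2.5, 1, 3) for i in range(4)]
        sigma = proficiency_sigma(subs, "robust")
        assert sigma[0] == 0.0
        with pytest.raises(InputError):
            z_score(2.5, 2.56, float(sigma[0]))

    def test_ci_rule_is_per_lab(self):
        subs = [sub("L1", "S1", 2.5, 2.0, 3.0), sub("L2", "S1", 2.5, 1.5, 3.5)]
        sigma = proficiency_sigma(subs, "ci")
        assert sigma == pytest.approx([1.0 / 3.92, 2.0 / 3.92])

    def test_fixed_rule(self):
        subs = [sub("L1", "S1", 2.5, 2.0, 3.0)]
        sigma = proficiency_sigma(subs, "fixed:0.1", reference=3.41)
        assert sigma[0] == pytest.approx(0.341)


class TestClassifyBias:
    def refs(self):
        return {r.sample_id: r for r in REFS}

    def test_systematic_over(self):
        subs = [
            sub("L6", "S1", 3.1, 2.8, 3.4),
            sub("L6", "S2", 4.0, 3.7, 4.3),
            sub("L6", "S3", 5.0, 4.3, 5.7),  # CI includes 4.54
        ]
        assert classify_bias(subs, self.refs(), ReferenceMode.AIR_KERMA) \
            is BiasClass.SYSTEMATIC_OVER

    def test_wide_intervals_mean_no_bias(self):
        subs = [
            sub("L1", "S1", 3.0, 2.0, 4.0),
            sub("L1", "S2", 3.9, 3.0, 5.0),
            sub("L1", "S3", 5.0, 4.0, 6.0),
        ]
        assert classify_bias(subs, self.refs(), ReferenceMode.AIR_KERMA) \
            is BiasClass.NONE

    def test_mixed_signs_mean_no_bias(self):
        subs = [
            sub("L1", "S1", 3.1, 2.9, 3.3),  # over, CI excludes
            sub("L1", "S2", 3.0, 2.8, 3.2),  # under, CI excludes
            sub("L1", "S3", 5.0, 4.8, 5.2),  # over, CI excludes
        ]
        assert classify_bias(subs, self.refs(), ReferenceMode.AIR_KERMA) \
            is BiasClass.NONE

    def test_systematic_under(self):
        subs = [
            sub("L9", "S1", 2.0, 1.8, 2.2),
            sub("L9", "S2", 2.9, 2.6, 3.2),
            sub("L9", "S3", 4.0, 3.4, 4.7),
        ]
        assert classify_bias(subs, self.refs(), ReferenceMode.AIR_KERMA) \
            is BiasClass.SYSTEMATIC_UNDER

    def test_missing_sample_not_classifiable(self):
        subs = [sub("L5", "S1", 3.0, 2.5, 3.5)]
        assert classify_bias(subs, self.refs(), ReferenceMode.AIR_KERMA) \
            is BiasClass.NOT_CLASSIFIABLE


class TestCategoricalChecks:
    @pytest.mark.parametrize(
        "dose,category",
        [
            (0.0, TriageCategory.LOW),
            (0.99, TriageCategory.LOW),
            (1.0, TriageCategory.MEDIUM),
            (2.0, TriageCategory.MEDIUM),
            (2.9, TriageCategory.HIGH),
        ],
    )
    def test_triage_boundaries(self, dose, category):
        assert triage_category(dose) is category

    def test_triage_rejects_negative(self):
        with pytest.raises(InputError):
            triage_category(-0.1)

    def test_band_membership(self):
        assert within_band(3.3, 3.41)
        assert not within_band(4.42, 3.41, band=1.0)
        assert within_band(3.41, 3.41, band=1e-9)

    def test_ranking(self):
        refs = {"S1": 2.56, "S2": 3.41, "S3": 4.54}
        assert ranking_correct({"S1": 2.7, "S2": 3.5, "S3": 4.6}, refs)
        assert not ranking_correct({"S1": 3.5, "S2": 2.7, "S3": 4.6}, refs)
        assert not ranking_correct({"S1": 2.7, "S2": 2.7, "S3": 4.6}, refs)
        with pytest.raises(InputError):
            ranking_correct({"S1": 2.7}, refs)


class TestCorrelation:
    def test_perfect_linearity(self):
        a = {"L1": 1.0, "L2": 2.0, "L3": 3.0}
        r, p = estimate_correlation(a, {k: 2 * v for k, v in a.items()})
        assert r == pytest.approx(1.0)
        r2, _ = estimate_correlation(a, {"L1": 3.0, "L2": 2.0, "L3": 1.0})
        assert r2 == pytest.approx(-1.0)

    def test_needs_three_shared_labs(self):
        with pytest.raises(InputError):
            estimate_correlation({"L1": 1.0, "L2": 2.0}, {"L1": 1.0, "L2": 2.0})


class TestEvaluateILC:
    def good_submissions(self):
        subs = []
        for lab in ("L1", "L2", "L3", "L4"):
            wobble = {"L1": 0.0, "L2": 0.05, "L3": -0.05, "L4": 0.1}[lab]
            for ref in REFS:
                dose = ref.air_kerma + wobble * ref.air_kerma
                subs.append(sub(lab, ref.sample_id, dose, dose - 0.6, dose + 0.6))
        return subs

    def test_unbiased_fixture_all_green(self):
        report = evaluate_ilc(
            self.good_submissions(),
            REFS,
            EvaluationConfig(reference_mode=ReferenceMode.AIR_KERMA),
        )
        assert all(f == 1.0 for f in report.ci_coverage_fraction.values())
        assert all(s.bias_class == "none" for s in report.lab_summaries)
        assert all(s.ranking_correct for s in report.lab_summaries)
        assert all(r.triage_category == "high" for r in report.records)
        assert len(report.records) == 12
        assert len(report.correlations) == 3

    def test_report_invariant_ci_contains(self):
        report = evaluate_ilc(
            self.good_submissions(),
            REFS,
            EvaluationConfig(reference_mode=ReferenceMode.AIR_KERMA),
        )
        for rec in report.records:
            assert rec.ci_contains_reference == (
                rec.ci_low <= rec.reference <= rec.ci_high
            )

    def test_lab_relabeling_invariance(self):
        subs = self.good_submissions()
        config = EvaluationConfig(reference_mode=ReferenceMode.AIR_KERMA)
        base = evaluate_ilc(subs, REFS, config)
        relabeled = [
            LabSubmission(
                lab_id="X" + s.lab_id,
                sample_id=s.sample_id,
                scoring_mode=s.scoring_mode,
                dose_estimate=s.dose_estimate,
                ci_low=s.ci_low,
                ci_high=s.ci_high,
                dose_definition=s.dose_definition,
                n_cells=s.n_cells,
                n_dicentrics=s.n_dicentrics,
            )
            for s in reversed(subs)
        ]
        other = evaluate_ilc(relabeled, REFS, config)
        assert base.ci_coverage_fraction == other.ci_coverage_fraction
        assert sorted(r.z_score for r in base.records) == pytest.approx(
            sorted(r.z_score for r in other.records)
        )

    def test_bias_reflection_antisymmetry(self):
        refs = {r.sample_id: r for r in REFS}
        over = [
            sub("L1", "S1", 3.1, 2.9, 3.3),
            sub("L1", "S2", 4.0, 3.8, 4.2),
            sub("L1", "S3", 5.2, 5.0, 5.4),
        ]
        reflected = [
            sub(
                "L1",
                s.sample_id,
                2 * refs[s.sample_id].air_kerma - s.dose_estimate,
                2 * refs[s.sample_id].air_kerma - s.ci_high,
                2 * refs[s.sample_id].air_kerma - s.ci_low,
            )
            for s in over
        ]
        assert classify_bias(over, refs, ReferenceMode.AIR_KERMA) \
            is BiasClass.SYSTEMATIC_OVER
        assert classify_bias(reflected, refs, ReferenceMode.AIR_KERMA) \
            is BiasClass.SYSTEMATIC_UNDER

    def test_empty_submissions_rejected(self):
        with pytest.raises(InputError):
            evaluate_ilc([], REFS)
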