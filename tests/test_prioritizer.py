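import itertools

import pytest

from recessix.case_studies import cascade_worked_example
from recessix.consequence_annotator import HIGH, Consequence
from recessix.prioritizer import (
    PREDICATE_ORDER,
    AnnotatedVariant,
    ControlCohort,
    ExpressionProfile,
    FrequencyAnnotations,
    PrioritizationConfig,
    apply_cohort_filter,
    apply_frequency_filter,
    apply_recessive_model,
    compute_tissue_specificity,
    evaluate_predicates,
    run_cascade,
)
from recessix.variant_model import VariantRecord

from conftest import make_call


def _variant(pos=100, afs=None, genotypes=None, specific=True, ratio=50.0,
             so="stop_gained", tier=HIGH):
    return AnnotatedVariant(
        variant=VariantRecord("chr1", pos, "A", "G", 100.0),
        gene_id=f"G{pos}",
        consequence=Consequence(so, tier, "c.1A>G"),
        frequencies=afs or FrequencyAnnotations(),
        genotypes=genotypes or {"P1": make_call("P1", "hom_alt")},
        specificity_ratio=ratio,
        is_tissue_specific=specific,
    )


class TestFrequencyFilter:
    def test_rare_reported_af_retained(self):
        assert apply_frequency_filter(
            _variant(afs=FrequencyAnnotations(af_gnomad=5.02e-3))
        )

    def test_two_percent_gnomad_filtered(self):
        assert not apply_frequency_filter(
            _variant(afs=FrequencyAnnotations(af_gnomad=0.02))
        )

    def test_per_database_caps(self):
        assert not apply_frequency_filter(
            _variant(afs=FrequencyAnnotations(af_1000g=0.04))
        )
        assert apply_frequency_filter(
            _variant(afs=FrequencyAnnotations(af_1000g=0.025, af_esp=0.045))
        )

    def test_novel_variant_retained(self):
        v = _variant(afs=FrequencyAnnotations())
        assert v.frequencies.is_novel
        assert apply_frequency_filter(v)

    def test_negative_af_rejected(self):
        with pytest.raises(ValueError):
            FrequencyAnnotations(af_gnomad=-0.1)


class TestCohortFilter:
    def test_absent_from_controls_retained(self):
        cohort = ControlCohort(n_controls=445, counts={})
        assert apply_cohort_filter(_variant(), cohort)

    def test_single_het_carrier_filtered(self):
        v = _variant()
        cohort = ControlCohort(n_controls=445, counts={v.key: (1, 0)})
        assert not apply_cohort_filter(v, cohort)

    def test_carrier_override(self):
        v = _variant()
        cohort = ControlCohort(n_controls=445, counts={v.key: (1, 0)})
        cfg = PrioritizationConfig(max_control_carriers=2)
        assert apply_cohort_filter(v, cohort, cfg)

    def test_empty_cohort_warns_and_retains(self):
        cohort = ControlCohort(n_controls=0, counts={})
        with pytest.warns(UserWarning, match="empty"):
            assert apply_cohort_filter(_variant(), cohort)


class TestRecessiveModel:
    def test_homozygous_rare_passes(self):
        v = _variant(afs=FrequencyAnnotations(af_gnomad=5.02e-3))
        assert apply_recessive_model(v, "P1")

    def test_heterozygous_fails(self):
        v = _variant(genotypes={"P1": make_call("P1", "het")},
                     afs=FrequencyAnnotations(af_gnomad=1e-4))
        assert not apply_recessive_model(v, "P1")

    def test_af_above_one_percent_fails(self):
        v = _variant(afs=FrequencyAnnotations(af_gnomad=0.012))
        assert not apply_recessive_model(v, "P1")

    def test_unknown_proband_raises(self):
        with pytest.raises(KeyError):
            apply_recessive_model(_variant(), "NOBODY")


class TestTissueSpecificity:
    def test_ratio_and_call(self):
        profile = ExpressionProfile("G", {"testis": 50.0, "brain": 0.5, "liver": 0.2})
        ratio, specific = compute_tissue_specificity(profile)
        assert ratio == pytest.approx(100.0)
        assert specific

    def test_uniform_expression_not_specific(self):
        profile = ExpressionProfile("G", {t: 7.0 for t in ("testis", "brain", "liver")})
        ratio, specific = compute_tissue_specificity(profile)
        assert ratio == pytest.approx(1.0)
        assert not specific

    def test_silent_gene(self):
        profile = ExpressionProfile("G", {t: 0.0 for t in ("testis", "brain")})
        ratio, specific = compute_tissue_specificity(profile)
        assert ratio == 0.0 and not specific

    def test_exclusive_target_expression_is_infinite(self):
        profile = ExpressionProfile("G", {"testis": 4.0, "brain": 0.0})
        ratio, specific = compute_tissue_specificity(profile)
        assert ratio == float("inf") and specific

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            compute_tissue_specificity(ExpressionProfile("G", {}))


class TestCascade:
    def test_worked_example_yields_exactly_two_candidates(self):
        """The two published candidate records survive; every distractor is
        excluded at its designed predicate."""
        ex = cascade_worked_example()
        survivors = []
        for proband in ex.probands:
            result = run_cascade(ex.variants, proband, ex.control_cohort)
            survivors.extend(result.candidate_keys())
            for excl in result.exclusions:
                if excl.key in ex.distractor_design:
                    assert excl.failed_predicate == ex.distractor_design[excl.key]
        assert len(survivors) == 2
        assert set(survivors) == set(ex.expected_candidate_keys.values())

    def test_audit_completeness(self):
        ex = cascade_worked_example()
        for proband in ex.probands:
            result = run_cascade(ex.variants, proband, ex.control_cohort)
            assert len(result.candidates) + len(result.exclusions) == len(ex.variants)

    def test_candidate_set_is_predicate_order_invariant(self):
        """The survivor set equals the brute-force conjunction of all
        predicates, independent of evaluation order."""
        ex = cascade_worked_example()
        for proband in ex.probands:
            result = run_cascade(ex.variants, proband, ex.control_cohort)
            for order in itertools.permutations(PREDICATE_ORDER, 3):
                brute = {
                    v.key
                    for v in ex.variants
                    if all(
                        evaluate_predicates(
                            v, proband, ex.control_cohort, PrioritizationConfig()
                        ).values()
                    )
                }
                assert set(result.candidate_keys()) == brute

    def test_tightening_thresholds_never_grows_candidates(self):
        ex = cascade_worked_example()
        loose = PrioritizationConfig()
        tighter_cfgs = [
            PrioritizationConfig(recessive_max_af=1e-4),
            PrioritizationConfig(min_specificity_ratio=1000.0),
            PrioritizationConfig(max_af_gnomad=1e-4),
        ]
        for proband in ex.probands:
            base = set(
                run_cascade(ex.variants, proband, ex.control_cohort, loose)
                .candidate_keys()
            )
            for cfg in tighter_cfgs:
                tight = set(
                    run_cascade(ex.variants, proband, ex.control_cohort, cfg)
                    .candidate_keys()
                )
                assert tight <= base

    def test_disabled_thresholds_return_all_high_impact_homozygotes(self):
        ex = cascade_worked_example()
        cfg = PrioritizationConfig(
            max_af_gnomad=1.0, max_af_1000g=1.0, max_af_esp=1.0,
            recessive_max_af=1.0, require_absent_in_controls=False,
            min_specificity_ratio=1e-9, min_target_tpm=0.0,
        )
        for proband in ex.probands:
            # with thresholds disabled, specificity flags are moot only if set;
            # force them on to isolate the impact + zygosity predicates
            variants = [
                AnnotatedVariant(
                    variant=v.variant, gene_id=v.gene_id, consequence=v.consequence,
                    frequencies=v.frequencies, genotypes=v.genotypes,
                    specificity_ratio=v.specificity_ratio, is_tissue_specific=True,
                )
                for v in ex.variants
            ]
            result = run_cascade(variants, proband, ex.control_cohort, cfg)
            expected = {
                v.key
                for v in variants
                if v.consequence.impact_tier == HIGH
                and v.genotypes[proband].zygosity == "hom_alt"
            }
            assert set(result.candidate_keys()) == expected

    def test_empty_input_yields_empty_list(self):
        result = run_cascade([], "P1", ControlCohort(5, {}))
        assert result.candidates == [] and result.exclusions == []

    def test_ranking_prefers_higher_specificity_then_lower_af(self):
        shared = dict(genotypes={"P1": make_call("P1", "hom_alt")})
        a = _variant(pos=10, ratio=100.0,
                     afs=FrequencyAnnotations(af_gnomad=5e-3), **shared)
        b = _variant(pos=20, ratio=10.0,
                     afs=FrequencyAnnotations(af_gnomad=1e-4), **shared)
        c = _variant(pos=30, ratio=10.0,
                     afs=FrequencyAnnotations(af_gnomad=5e-5), **shared)
        result = run_cascade([b, c, a], "P1", ControlCohort(10, {}))
        assert [v.variant.pos for v in result.candidates] == [10, 30, 20]
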