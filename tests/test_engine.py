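"""Report generation shape, aggregation, assurance filtering and amendment
application."""

import random

import pytest

from bdqual.engine import (
    AmendmentMode,
    AmendmentPolicy,
    ProfileError,
    ReportMismatchError,
    UnresolvedSpecificationError,
    apply_amendments,
    default_registry,
    filter_fit_for_use,
    generate_report,
)
from bdqual.io_formats import report_to_document
from bdqual.mechanisms import aggregate_record_outcomes
from bdqual.model import (
    AmendmentStatus,
    Comparator,
    ContextualizedCriterion,
    ContextualizedDimension,
    ContextualizedEnhancement,
    DataResource,
    EnhancementType,
    MeasureResult,
    MeasureStatus,
    Profile,
    ResourceType,
    ValidationOutcome,
)
from bdqual.synthetic import DefectRates, generate_dataset

from conftest import WORKED_RECORD, build_standard_profile
from generators import random_profile


def _count_shapes(profile, n):
    record_dims = sum(1 for d in profile.measurement_policy
                      if d.resource_type is ResourceType.SINGLE_RECORD)
    dataset_dims = len(profile.measurement_policy) - record_dims
    record_crits = sum(
        1 for c in profile.validation_policy
        if profile.dimension(c.dimension_ref).resource_type
        is ResourceType.SINGLE_RECORD)
    dataset_crits = len(profile.validation_policy) - record_crits
    return (record_dims * n + dataset_dims,
            record_crits * n + dataset_crits,
            len(profile.enhancement_policy) * n)


class TestGenerateReport:
    def test_counts_follow_the_profile_to_report_mapping(self, registry):
        profile = build_standard_profile(
            record_completeness=False, dataset_completeness=True,
            taxon_completeness=True, taxon_fill=True)
        # 2 dataset dims, 1 dataset criterion, 1 enhancement, 10 records
        dataset, _ = generate_dataset(10, DefectRates(), seed=1)
        report = generate_report(profile, dataset, registry)
        assert len(report.measures) == 2
        assert len(report.validations) == 1
        assert len(report.amendments) == 10

    def test_empty_enhancement_policy_yields_no_amendments(self, registry):
        dataset, _ = generate_dataset(5, DefectRates(), seed=1)
        report = generate_report(build_standard_profile(), dataset, registry)
        assert report.amendments == []

    def test_worked_example_single_record_report(self, registry):
        profile = Profile(
            use_case=build_standard_profile().use_case,
            valuable_ies=build_standard_profile().valuable_ies,
            measurement_policy=(ContextualizedDimension(
                id="coord-consistency", dimension="CONSISTENCY",
                ie_ref="coordinates",
                resource_type=ResourceType.SINGLE_RECORD,
                specification_ref="spec:coordinate-consistency"),),
        )
        resource = DataResource(resource_type=ResourceType.SINGLE_RECORD,
                                record=dict(WORKED_RECORD),
                                resource_id="mcz-record")
        report = generate_report(profile, resource, registry)
        assert len(report.measures) == 1
        assertion = report.measures[0]
        assert assertion.result.qualitative == "NOT_CONSISTENT"
        assert assertion.element_ref == "coord-consistency"
        assert assertion.specification_ref == "spec:coordinate-consistency"
        assert assertion.mechanism_ref == "mech:coordinate-consistency"
        assert assertion.resource_ref.dataset_id == "mcz-record"

    def test_malformed_profile_fails_before_evaluation(self, registry):
        base = build_standard_profile()
        bad = Profile(
            use_case=base.use_case, valuable_ies=base.valuable_ies,
            measurement_policy=base.measurement_policy,
            validation_policy=(ContextualizedCriterion(
                id="c", dimension_ref="ghost", comparator=Comparator.EQ,
                threshold=1.0),))
        dataset, _ = generate_dataset(3, DefectRates(), seed=1)
        with pytest.raises(ProfileError):
            generate_report(bad, dataset, registry)

    def test_unresolved_specification_named_before_evaluation(self, registry):
        base = build_standard_profile()
        bad = Profile(
            use_case=base.use_case, valuable_ies=base.valuable_ies,
            measurement_policy=(ContextualizedDimension(
                id="d", dimension="COMPLETENESS", ie_ref="coordinates",
                resource_type=ResourceType.DATASET,
                specification_ref="spec:does-not-exist"),))
        dataset, _ = generate_dataset(3, DefectRates(), seed=1)
        with pytest.raises(UnresolvedSpecificationError) as err:
            generate_report(bad, dataset, registry)
        assert "spec:does-not-exist" in str(err.value)

    @pytest.mark.parametrize("seed", range(20))
    def test_report_shape_law_on_random_profiles(self, reference, seed):
        """Assertion counts follow the mapping rules exactly: one measure per
        record per record-level dimension, one per dataset-level dimension,
        likewise for criteria, and one amendment per enhancement per record."""
        rng = random.Random(seed)
        registry = default_registry(reference)
        profile = random_profile(rng)
        n = rng.randint(1, 60)
        rates = DefectRates(p_missing_coord=rng.random() * 0.4,
                            p_missing_taxon_ranks=rng.random() * 0.4)
        dataset, _ = generate_dataset(n, rates, seed=seed)
        report = generate_report(profile, dataset, registry)
        m, v, a = _count_shapes(profile, n)
        assert len(report.measures) == m
        assert len(report.validations) == v
        assert len(report.amendments) == a

    def test_dataset_proportions_equal_record_level_recount(self, registry):
        """Aggregation oracle: every dataset proportion equals a brute-force
        recount of the per-record outcomes of the same mechanism."""
        profile = build_standard_profile(
            dataset_conformity=True, dataset_consistency=True,
            taxon_completeness=True)
        rates = DefectRates(p_missing_coord=0.25, p_nonnumeric_coord=0.15,
                            p_out_of_range=0.1, p_wrong_country=0.1,
                            p_missing_taxon_ranks=0.3)
        dataset, _ = generate_dataset(120, rates, seed=11)
        report = generate_report(profile, dataset, registry)
        for assertion in report.measures:
            if assertion.result.quantitative is None:
                continue
            dim = profile.dimension(assertion.element_ref)
            entry = registry.resolve(dim.specification_ref)
            ie = profile.information_element(dim.ie_ref)
            outcomes = [
                entry.record_fn(rec, ie, registry.reference_data,
                                entry.specification.formal_params)
                for _, rec in dataset.iter_rows()
            ]
            recount = sum(
                1 for o in outcomes
                if o.status is MeasureStatus.COMPLETED
                and o.qualitative == entry.positive_value
            )
            assert assertion.result.quantitative == recount / dataset.n_records

    def test_determinism_excluding_timestamp(self, registry):
        profile = build_standard_profile(dataset_conformity=True,
                                         record_criterion=True)
        dataset, _ = generate_dataset(40, DefectRates(p_missing_coord=0.3),
                                      seed=5)
        doc1 = report_to_document(
            generate_report(profile, dataset, registry, generated_at="T"))
        doc2 = report_to_document(
            generate_report(profile, dataset, registry, generated_at="T"))
        assert doc1 == doc2


class TestAggregateRecordOutcomes:
    def _q(self, value):
        return MeasureResult(status=MeasureStatus.COMPLETED, qualitative=value)

    def test_two_of_three_positive(self):
        result = aggregate_record_outcomes(
            [self._q("COMPLETE"), self._q("COMPLETE"), self._q("NOT_COMPLETE")],
            "COMPLETE")
        assert result.quantitative == pytest.approx(2 / 3)

    def test_all_positive_is_one(self):
        result = aggregate_record_outcomes([self._q("COMPLETE")] * 4, "COMPLETE")
        assert result.quantitative == 1.0

    def test_empty_input_is_prerequisite_failure(self):
        assert aggregate_record_outcomes([], "COMPLETE").status \
            is MeasureStatus.PREREQUISITES_NOT_MET

    def test_unassessable_records_count_as_not_positive(self):
        outcomes = [self._q("COMPLETE"),
                    MeasureResult(status=MeasureStatus.PREREQUISITES_NOT_MET)]
        assert aggregate_record_outcomes(outcomes, "COMPLETE").quantitative == 0.5

    @pytest.mark.parametrize("seed", range(3))
    def test_random_vectors_match_brute_force_recount(self, seed):
        rng = random.Random(seed)
        for _ in range(100):
            values = [rng.choice(["A", "B", "C"]) for _ in range(rng.randint(1, 30))]
            outcomes = [self._q(v) for v in values]
            expected = values.count("A") / len(values)
            assert aggregate_record_outcomes(outcomes, "A").quantitative == expected


class TestFilterFitForUse:
    def _run(self, n, rates, seed, registry):
        profile = build_standard_profile(record_criterion=True)
        dataset, truth = generate_dataset(n, rates, seed=seed)
        report = generate_report(profile, dataset, registry)
        return profile, dataset, truth, report

    def test_incomplete_records_excluded_and_logged(self, registry):
        profile, dataset, truth, report = self._run(
            50, DefectRates(p_missing_coord=0.3), 13, registry)
        subset, log = filter_fit_for_use(dataset, profile, report)
        assert subset.n_records == truth.coord_complete_count
        assert len(log) == 50 - truth.coord_complete_count
        for entry in log:
            assert "record-must-be-complete" in entry.failed_criteria

    def test_partitions_the_dataset(self, registry):
        profile, dataset, _, report = self._run(
            60, DefectRates(p_missing_coord=0.4), 17, registry)
        subset, log = filter_fit_for_use(dataset, profile, report)
        retained = set(subset.row_ids)
        excluded = {e.row_id for e in log}
        assert retained | excluded == set(dataset.row_ids)
        assert retained & excluded == set()

    def test_all_compliant_is_identity(self, registry):
        profile, dataset, _, report = self._run(20, DefectRates(), 19, registry)
        subset, log = filter_fit_for_use(dataset, profile, report)
        assert log == []
        assert subset.records == dataset.records
        assert subset.row_ids == dataset.row_ids

    def test_retained_records_are_compliant_on_all_record_criteria(self, registry):
        profile, dataset, _, report = self._run(
            80, DefectRates(p_missing_coord=0.3, p_nonnumeric_coord=0.2),
            23, registry)
        subset, _ = filter_fit_for_use(dataset, profile, report)
        re_report = generate_report(profile, subset, registry)
        for assertion in re_report.validations:
            if assertion.resource_ref.row_id is not None:
                assert assertion.result.outcome is ValidationOutcome.COMPLIANT

    @pytest.mark.parametrize("seed", [29, 31, 37])
    def test_idempotent_on_synthetic_datasets(self, registry, seed):
        profile, dataset, _, report = self._run(
            50, DefectRates(p_missing_coord=0.35), seed, registry)
        subset, _ = filter_fit_for_use(dataset, profile, report)
        report2 = generate_report(profile, subset, registry)
        subset2, log2 = filter_fit_for_use(subset, profile, report2)
        assert log2 == []
        assert subset2.records == subset.records

    def test_mismatched_report_rejected(self, registry):
        profile, dataset, _, report = self._run(5, DefectRates(), 1, registry)
        other, _ = generate_dataset(5, DefectRates(), seed=2,
                                    resource_id="other")
        with pytest.raises(ReportMismatchError):
            filter_fit_for_use(other, profile, report)


class TestApplyAmendments:
    def test_accept_all_taxon_fill_never_decreases_completeness(self, registry):
        profile = build_standard_profile(taxon_completeness=True,
                                         taxon_fill=True)
        dataset, _ = generate_dataset(
            60, DefectRates(p_missing_taxon_ranks=0.4), seed=41)
        report = generate_report(profile, dataset, registry)
        before = [a.result.quantitative for a in report.measures
                  if a.element_ref == "taxon-completeness-dataset"][0]
        outcome = apply_amendments(
            dataset, report, AmendmentPolicy(mode=AmendmentMode.ACCEPT_ALL))
        assert dataset.records != outcome.dataset.records  # copy, not alias
        after_report = generate_report(profile, outcome.dataset, registry)
        after = [a.result.quantitative for a in after_report.measures
                 if a.element_ref == "taxon-completeness-dataset"][0]
        assert after >= before
        assert len({c.row_id for c in outcome.changelog}) \
            == sum(1 for a in report.amendments
                   if a.result.status is AmendmentStatus.PROPOSED)

    def test_original_dataset_untouched(self, registry):
        profile = build_standard_profile(taxon_completeness=True,
                                         taxon_fill=True)
        dataset, _ = generate_dataset(
            10, DefectRates(p_missing_taxon_ranks=1.0), seed=43)
        snapshot = [dict(r) for r in dataset.records]
        report = generate_report(profile, dataset, registry)
        apply_amendments(dataset, report,
                         AmendmentPolicy(mode=AmendmentMode.ACCEPT_ALL))
        assert dataset.records == snapshot

    def test_empty_accept_set_changes_nothing(self, registry):
        profile = build_standard_profile(taxon_completeness=True,
                                         taxon_fill=True)
        dataset, _ = generate_dataset(
            10, DefectRates(p_missing_taxon_ranks=1.0), seed=47)
        report = generate_report(profile, dataset, registry)
        outcome = apply_amendments(
            dataset, report,
            AmendmentPolicy(mode=AmendmentMode.ACCEPT_TYPES,
                            accept_types=frozenset()))
        assert outcome.dataset.records == dataset.records
        assert outcome.changelog == []
        assert len(outcome.pending) > 0

    def test_conflicting_proposals_for_same_field_dropped_and_logged(self, registry):
        base = build_standard_profile(taxon_completeness=True)
        profile = Profile(
            use_case=base.use_case, valuable_ies=base.valuable_ies,
            measurement_policy=base.measurement_policy,
            enhancement_policy=(
                ContextualizedEnhancement(
                    id="country-fix", enhancement_type=EnhancementType.CORRECTION,
                    target_dimension_refs=("coord-completeness-dataset",),
                    specification_ref="spec:country-from-coordinates"),
                ContextualizedEnhancement(
                    id="country-fix-2",
                    enhancement_type=EnhancementType.RECOMMENDATION,
                    target_dimension_refs=("coord-completeness-dataset",),
                    specification_ref="spec:country-from-coordinates"),
            ))
        dataset = DataResource(
            resource_type=ResourceType.DATASET,
            records=[{"decimalLatitude": "5.0", "decimalLongitude": "5.0",
                      "country": "", "kingdom": "Animalia",
                      "phylum": "Arthropoda", "class": "Insecta",
                      "order": "Hymenoptera", "family": "Apidae",
                      "genus": "Apis", "species": "Apis mellifera"}],
            resource_id="tiny")
        report = generate_report(profile, dataset, registry)
        # rewrite the second enhancement's proposal to a different value to
        # force a genuine conflict
        from bdqual.model import AmendmentResult, Assertion
        forced = []
        for a in report.amendments:
            if a.element_ref == "country-fix-2":
                a = Assertion(
                    assertion_type=a.assertion_type, element_ref=a.element_ref,
                    specification_ref=a.specification_ref,
                    mechanism_ref=a.mechanism_ref, resource_ref=a.resource_ref,
                    result=AmendmentResult(
                        status=AmendmentStatus.PROPOSED,
                        proposed_changes={"country": "Lemuria"},
                        enhancement_type=EnhancementType.RECOMMENDATION))
            forced.append(a)
        report.amendments = forced
        outcome = apply_amendments(
            dataset, report, AmendmentPolicy(mode=AmendmentMode.ACCEPT_ALL))
        assert outcome.changelog == []
        assert len(outcome.conflicts) == 1
        assert outcome.conflicts[0].field == "country"
        assert outcome.dataset.records[0]["country"] == ""

    def test_prevention_suggestions_are_never_applied(self, registry):
        base = build_standard_profile(taxon_completeness=True)
        profile = Profile(
            use_case=base.use_case, valuable_ies=base.valuable_ies,
            measurement_policy=base.measurement_policy,
            enhancement_policy=(ContextualizedEnhancement(
                id="name-hints", enhancement_type=EnhancementType.PREVENTION,
                target_dimension_refs=("coord-completeness-dataset",),
                specification_ref="spec:name-suggestions"),))
        dataset, _ = generate_dataset(
            10, DefectRates(p_misspelled_name=1.0), seed=53)
        report = generate_report(profile, dataset, registry)
        assert all(a.result.status is not AmendmentStatus.PROPOSED
                   for a in report.amendments)
        outcome = apply_amendments(
            dataset, report, AmendmentPolicy(mode=AmendmentMode.ACCEPT_ALL))
        assert outcome.changelog == []
        assert outcome.dataset.records == dataset.records
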