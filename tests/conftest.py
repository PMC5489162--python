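import pytest

from bdqual.engine import default_registry
from bdqual.model import (
    Comparator,
    ContextualizedCriterion,
    ContextualizedDimension,
    ContextualizedEnhancement,
    EnhancementType,
    IEKind,
    InformationElement,
    Profile,
    ResourceType,
    UseCase,
)
from bdqual.synthetic import generate_reference_fixtures

COORD_TERMS = ("decimalLatitude", "decimalLongitude",
               "coordinateUncertaintyInMeters", "geodeticDatum")
TAXON_TERMS = ("kingdom", "phylum", "class", "order", "family", "genus",
               "species")

#: The point-radius record from the framework's worked assertion example.
WORKED_RECORD = {
    "decimalLatitude": "-35.3848",
    "decimalLongitude": "13.8352",
    "coordinateUncertaintyInMeters": "100",
    "geodeticDatum": "SIRGAS2000",
    "country": "Brazil",
}


@pytest.fixture(scope="session")
def reference():
    return generate_reference_fixtures(0)


@pytest.fixture()
def registry(reference):
    return default_registry(reference)


@pytest.fixture()
def coordinates_ie():
    return InformationElement(
        id="coordinates", label="coordinates", kind=IEKind.COMPOSED,
        terms=COORD_TERMS,
    )


@pytest.fixture()
def taxon_ie():
    return InformationElement(
        id="taxon", label="taxon hierarchy", kind=IEKind.COMPOSED,
        terms=TAXON_TERMS,
    )


def build_standard_profile(
    *,
    record_completeness: bool = True,
    dataset_completeness: bool = True,
    dataset_conformity: bool = False,
    dataset_consistency: bool = False,
    taxon_completeness: bool = False,
    completeness_criterion: bool = True,
    record_criterion: bool = False,
    taxon_fill: bool = False,
) -> Profile:
    """The coordinate-quality profile used across the suite: composed
    coordinates element, completeness/conformity/consistency dimensions, the
    'completeness must equal 100%' criterion, and taxon backfill."""
    ies = [InformationElement(id="coordinates", label="coordinates",
                              kind=IEKind.COMPOSED, terms=COORD_TERMS)]
    dims, crits, enhs = [], [], []
    if record_completeness:
        dims.append(ContextualizedDimension(
            id="coord-completeness-record", dimension="COMPLETENESS",
            ie_ref="coordinates", resource_type=ResourceType.SINGLE_RECORD,
            specification_ref="spec:completeness"))
    if dataset_completeness:
        dims.append(ContextualizedDimension(
            id="coord-completeness-dataset", dimension="COMPLETENESS",
            ie_ref="coordinates", resource_type=ResourceType.DATASET,
            specification_ref="spec:completeness"))
    if dataset_conformity:
        dims.append(ContextualizedDimension(
            id="coord-conformity-dataset", dimension="CONFORMITY",
            ie_ref="coordinates", resource_type=ResourceType.DATASET,
            specification_ref="spec:coordinate-conformity"))
    if dataset_consistency:
        dims.append(ContextualizedDimension(
            id="coord-consistency-dataset", dimension="CONSISTENCY",
            ie_ref="coordinates", resource_type=ResourceType.DATASET,
            specification_ref="spec:coordinate-consistency"))
    if taxon_completeness:
        ies.append(InformationElement(id="taxon", label="taxon hierarchy",
                                      kind=IEKind.COMPOSED, terms=TAXON_TERMS))
        dims.append(ContextualizedDimension(
            id="taxon-completeness-dataset", dimension="COMPLETENESS",
            ie_ref="taxon", resource_type=ResourceType.DATASET,
            specification_ref="spec:completeness"))
    if completeness_criterion and dataset_completeness:
        crits.append(ContextualizedCriterion(
            id="completeness-must-be-total",
            statement="coordinate completeness of a dataset must be equal to 100%",
            dimension_ref="coord-completeness-dataset",
            comparator=Comparator.EQ, threshold=1.0))
    if record_criterion and record_completeness:
        crits.append(ContextualizedCriterion(
            id="record-must-be-complete",
            dimension_ref="coord-completeness-record",
            comparator=Comparator.EQ, threshold="COMPLETE"))
    if taxon_fill and taxon_completeness:
        enhs.append(ContextualizedEnhancement(
            id="taxon-backfill",
            statement="Fill in taxon hierarchy based on the most specific name.",
            enhancement_type=EnhancementType.CORRECTION,
            target_dimension_refs=("taxon-completeness-dataset",),
            specification_ref="spec:fill-taxon-hierarchy"))
    return Profile(
        use_case=UseCase(
            id="uc-bee-sdm",
            label="Distribution model for Tetragonisca angustula",
            description=("Species distribution modelling of a stingless bee "
                         "needs complete, conformant, country-consistent "
                         "point-radius coordinates."),
        ),
        valuable_ies=tuple(ies),
        measurement_policy=tuple(dims),
        validation_policy=tuple(crits),
        enhancement_policy=tuple(enhs),
    )


@pytest.fixture()
def standard_profile():
    return build_standard_profile()
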