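"""Profile evaluation engine.

Applies a data-quality profile to a data resource through a registry of
mechanism implementations and produces the DQ status report: one measure
per contextualized dimension (per record for record-level dimensions, one
roll-up for dataset-level ones), one validation per criterion, and one
amendment assertion per enhancement per applicable record — explicitly
recording NOT_PROPOSED / PREREQUISITES_NOT_MET rather than omitting them.

Two management modes sit on top of the report: quality assurance
(``filter_fit_for_use`` retains only records compliant with every
record-level criterion) and quality control (``apply_amendments`` applies
accepted proposals to a copy of the data, never in place).
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

from . import __version__
from .mechanisms import (
    CONFORMANT,
    CONSISTENT,
    COMPLETE,
    ReferenceData,
    aggregate_record_outcomes,
    amend_coordinates_from_locality,
    amend_country_from_coordinates,
    amend_fill_taxon_hierarchy,
    check_is_number,
    check_latitude_range,
    check_longitude_range,
    check_valid_characters,
    is_missing,
    measure_completeness_record,
    measure_coordinate_conformity_record,
    measure_coordinate_consistency_record,
    suggest_name_amendment,
    validate_against_criterion,
)
from .model import (
    AmendmentResult,
    AmendmentStatus,
    Assertion,
    Coverage,
    DataResource,
    EnhancementType,
    InformationElement,
    MeasureResult,
    MeasureStatus,
    Mechanism,
    Profile,
    Report,
    ResourceRef,
    ResourceType,
    Specification,
    ValidationOutcome,
    ValidationResult,
    build_assertion,
    validate_profile,
)

# Validation assertions are produced by one generic comparator mechanism.
VALIDATION_SPEC_ID = "spec:criterion-comparator"
DERIVED_SUMMARY_SPEC_ID = "spec:derived-compliance-proportion"


class ProfileError(ValueError):
    """The profile failed structural validation."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "malformed profile: " + "; ".join(str(v) for v in self.violations)
        )


class UnresolvedSpecificationError(LookupError):
    """A profile references specifications with no registered implementation."""

    def __init__(self, spec_ids):
        self.spec_ids = sorted(spec_ids)
        super().__init__(
            "unresolved specification(s): " + ", ".join(self.spec_ids)
        )


class ReportMismatchError(ValueError):
    """Report and dataset disagree (unknown row ids, wrong resource)."""


MeasureFn = Callable[[Mapping[str, str], InformationElement, ReferenceData, Mapping], MeasureResult]
AmendFn = Callable[[Mapping[str, str], ReferenceData, Mapping], AmendmentResult]


@dataclass(frozen=True)
class RegisteredMechanism:
    """One registry entry: metadata plus the executable implementation."""

    mechanism: Mechanism
    specification: Specification
    kind: str  # "measure" | "amendment"
    record_fn: Callable
    positive_value: Optional[str] = None  # qualitative value counted in roll-ups


@dataclass
class MechanismRegistry:
    """In-process catalogue mapping specification ids to implementations."""

    reference_data: ReferenceData
    entries: dict[str, RegisteredMechanism] = field(default_factory=dict)

    def register(self, entry: RegisteredMechanism) -> None:
        for spec_id in entry.mechanism.implements:
            if spec_id in self.entries and self.entries[spec_id] is not entry:
                raise ValueError(f"specification {spec_id!r} already registered")
        self.entries[entry.specification.id] = entry

    def resolve(self, spec_id: str) -> RegisteredMechanism:
        try:
            return self.entries[spec_id]
        except KeyError:
            raise UnresolvedSpecificationError([spec_id]) from None

    def specification_ids(self) -> set[str]:
        return set(self.entries)

    def unresolved(self, profile: Profile) -> set[str]:
        wanted = {d.specification_ref for d in profile.measurement_policy}
        wanted |= {e.specification_ref for e in profile.enhancement_policy}
        return wanted - self.specification_ids()

    def check_acyclic_uses(self) -> None:
        """The mechanism delegation graph must be a DAG."""
        graph = {
            e.mechanism.id: set(e.mechanism.uses) for e in self.entries.values()
        }
        state: dict[str, int] = {}

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if state.get(node) == 2:
                return
            if state.get(node) == 1:
                raise ValueError(
                    "cyclic mechanism delegation: " + " -> ".join(stack + (node,))
                )
            state[node] = 1
            for dep in graph.get(node, ()):
                visit(dep, stack + (node,))
            state[node] = 2

        for node in graph:
            visit(node, ())


def _spec(spec_id: str, text: str, **params) -> Specification:
    return Specification(id=spec_id, human_text=text, formal_params=params)


def default_registry(reference: ReferenceData) -> MechanismRegistry:
    """Registry pre-loaded with the built-in mechanism catalogue.

    The four coordinate-value sub-checks are registered as SPECIFIC
    mechanisms; the coordinate-conformity mechanism is BROAD and delegates
    to them.  Measurement specifications are record-level; dataset-level
    dimensions referencing them are rolled up by the engine.
    """
    registry = MechanismRegistry(reference_data=reference)

    def _measure(spec_id, text, fn, positive, mech_id, label,
                 coverage=Coverage.SPECIFIC, uses=(), implements=None):
        spec = _spec(spec_id, text)
        mech = Mechanism(
            id=mech_id,
            label=label,
            coverage=coverage,
            implements=tuple(implements or (spec_id,)),
            uses=tuple(uses),
        )
        registry.register(
            RegisteredMechanism(
                mechanism=mech,
                specification=spec,
                kind="measure",
                record_fn=fn,
                positive_value=positive,
            )
        )

    def _amend(spec_id, text, fn, mech_id, label):
        spec = _spec(spec_id, text)
        mech = Mechanism(
            id=mech_id, label=label, coverage=Coverage.SPECIFIC,
            implements=(spec_id,),
        )
        registry.register(
            RegisteredMechanism(
                mechanism=mech, specification=spec, kind="amendment", record_fn=fn
            )
        )

    _measure(
        "spec:completeness",
        "A value is present for every term of the information element "
        "(blank, NULL, NA and N/A count as absent).",
        lambda record, ie, ref, params: measure_completeness_record(record, ie),
        COMPLETE,
        "mech:completeness", "Presence check over an information element",
    )

    def _value_check(check, which):
        def fn(record, ie, ref, params):
            lat_term = params.get("lat_term", "decimalLatitude")
            lon_term = params.get("lon_term", "decimalLongitude")
            lat, lon = record.get(lat_term), record.get(lon_term)
            if is_missing(lat) or is_missing(lon):
                return MeasureResult(
                    status=MeasureStatus.PREREQUISITES_NOT_MET,
                    detail="missing coordinate term(s)",
                )
            if which == "lat":
                ok = check(lat)
            elif which == "lon":
                ok = check(lon)
            else:
                ok = check(lat) and check(lon)
            return MeasureResult(
                status=MeasureStatus.COMPLETED,
                qualitative=CONFORMANT if ok else "NOT_CONFORMANT",
            )
        return fn

    _measure("spec:value-is-number",
             "Each provided coordinate value is a plain decimal number.",
             _value_check(check_is_number, "both"), CONFORMANT,
             "mech:value-is-number", "Numeric value check")
    _measure("spec:value-valid-characters",
             "Each provided coordinate value contains only an optional sign, "
             "digits and at most one decimal point.",
             _value_check(check_valid_characters, "both"), CONFORMANT,
             "mech:value-valid-characters", "Character-set check")
    _measure("spec:latitude-range",
             "Latitude is between -90 and 90, inclusive.",
             _value_check(check_latitude_range, "lat"), CONFORMANT,
             "mech:latitude-range", "Latitude range check")
    _measure("spec:longitude-range",
             "Longitude is between -180 and 180, inclusive.",
             _value_check(check_longitude_range, "lon"), CONFORMANT,
             "mech:longitude-range", "Longitude range check")

    _measure(
        "spec:coordinate-conformity",
        "Latitude and longitude are numbers, contain no invalid characters "
        "and lie in the correct ranges ([-90, 90] and [-180, 180], inclusive).",
        lambda record, ie, ref, params: measure_coordinate_conformity_record(
            record,
            lat_term=params.get("lat_term", "decimalLatitude"),
            lon_term=params.get("lon_term", "decimalLongitude"),
        ),
        CONFORMANT,
        "mech:coordinate-conformity", "Coordinate conformity (composite)",
        coverage=Coverage.BROAD,
        uses=("mech:value-is-number", "mech:value-valid-characters",
              "mech:latitude-range", "mech:longitude-range"),
        implements=("spec:coordinate-conformity", "spec:coordinate-conformity/strict"),
    )

    _measure(
        "spec:coordinate-consistency",
        "The circle around the coordinate, with radius equal to the "
        "coordinate uncertainty in meters, intersects the area within the "
        "boundary of the named country (planar approximation; tangency "
        "counts as consistent).",
        lambda record, ie, ref, params: measure_coordinate_consistency_record(
            record, ref,
            lat_term=params.get("lat_term", "decimalLatitude"),
            lon_term=params.get("lon_term", "decimalLongitude"),
            uncertainty_term=params.get(
                "uncertainty_term", "coordinateUncertaintyInMeters"),
            country_term=params.get("country_term", "country"),
        ),
        CONSISTENT,
        "mech:coordinate-consistency", "Point-radius country consistency",
    )

    _amend(
        "spec:fill-taxon-hierarchy",
        "Fill blank higher taxon ranks from the lineage of the most specific "
        "name resolvable in the reference taxonomy; never overwrite filled "
        "fields.",
        lambda record, ref, params: amend_fill_taxon_hierarchy(record, ref),
        "mech:fill-taxon-hierarchy", "Taxon hierarchy backfill",
    )
    _amend(
        "spec:country-from-coordinates",
        "Recommend a country name when the coordinate falls inside exactly "
        "one country boundary.",
        lambda record, ref, params: amend_country_from_coordinates(
            record, ref,
            country_term=params.get("country_term", "country"),
        ),
        "mech:country-from-coordinates", "Country from coordinates",
    )
    _amend(
        "spec:coordinates-from-locality",
        "Recommend coordinates by exact gazetteer lookup of the normalized "
        "locality string.",
        lambda record, ref, params: amend_coordinates_from_locality(record, ref),
        "mech:coordinates-from-locality", "Coordinates from locality",
    )
    _amend(
        "spec:name-suggestions",
        "Suggest similar accepted scientific names within a bounded edit "
        "distance; advisory only, never proposes a change.",
        lambda record, ref, params: suggest_name_amendment(
            record, ref,
            max_distance=int(params.get("max_distance", 2)),
            limit=int(params.get("limit", 5)),
        ),
        "mech:name-suggestions", "Accepted-name suggestion (prevention)",
    )

    registry.check_acyclic_uses()
    return registry


class AmendmentMode(str, enum.Enum):
    ACCEPT_ALL = "ACCEPT_ALL"
    ACCEPT_TYPES = "ACCEPT_TYPES"
    INTERACTIVE_LIST = "INTERACTIVE_LIST"


@dataclass(frozen=True)
class AmendmentPolicy:
    """Curator decision rule for which proposed amendments get applied.

    PREVENTION-type enhancements are never applied regardless of mode; they
    only carry suggestions.
    """

    mode: AmendmentMode = AmendmentMode.INTERACTIVE_LIST
    accept_types: frozenset[EnhancementType] = frozenset()
    audit: bool = True

    def accepts(self, enhancement_type: Optional[EnhancementType]) -> bool:
        if enhancement_type is EnhancementType.PREVENTION or enhancement_type is None:
            return False
        if self.mode is AmendmentMode.ACCEPT_ALL:
            return True
        if self.mode is AmendmentMode.ACCEPT_TYPES:
            return enhancement_type in self.accept_types
        return False


def _resource_ref(resource: DataResource, row_id: Optional[int],
                  record: Optional[Mapping[str, str]]) -> ResourceRef:
    occ = None
    if record is not None and not is_missing(record.get("occurrenceID")):
        occ = record["occurrenceID"].strip()
    return ResourceRef(dataset_id=resource.resource_id, row_id=row_id,
                       occurrence_id=occ)


def generate_report(
    profile: Profile,
    resource: DataResource,
    registry: MechanismRegistry,
    *,
    generated_at: Optional[str] = None,
) -> Report:
    """Evaluate *profile* over *resource* and assemble the DQ status report.

    Fails before any evaluation if the profile is structurally invalid or
    any referenced specification is unregistered.  Assertion order is
    measurement-policy order, then row order, for reproducible diffs.
    """
    violations = validate_profile(profile)
    if violations:
        raise ProfileError(violations)
    missing = registry.unresolved(profile)
    if missing:
        raise UnresolvedSpecificationError(missing)

    is_dataset = resource.resource_type is ResourceType.DATASET
    rows = list(resource.iter_rows())

    measures: list[Assertion] = []
    # dimension id -> list of (row_id, MeasureResult) for record-level dims,
    # or the single dataset-level MeasureResult.
    record_outcomes: dict[str, list[tuple[Optional[int], MeasureResult]]] = {}
    dataset_outcomes: dict[str, MeasureResult] = {}

    for dim in profile.measurement_policy:
        entry = registry.resolve(dim.specification_ref)
        if entry.kind != "measure":
            raise UnresolvedSpecificationError([dim.specification_ref])
        ie = profile.information_element(dim.ie_ref)
        params = entry.specification.formal_params
        per_record = [
            (rid, entry.record_fn(rec, ie, registry.reference_data, params))
            for rid, rec in rows
        ]
        if dim.resource_type is ResourceType.SINGLE_RECORD:
            record_outcomes[dim.id] = per_record
            for (rid, rec), (_, result) in zip(rows, per_record):
                measures.append(
                    build_assertion(
                        dim, entry.specification.id, entry.mechanism.id,
                        _resource_ref(resource, rid, rec), result,
                    )
                )
        else:
            if not is_dataset:
                # a dataset dimension over a single record rolls up n=1
                rolled = aggregate_record_outcomes(
                    [m for _, m in per_record], entry.positive_value or ""
                )
            elif not rows:
                rolled = MeasureResult(
                    status=MeasureStatus.PREREQUISITES_NOT_MET,
                    detail="empty dataset",
                )
            else:
                rolled = aggregate_record_outcomes(
                    [m for _, m in per_record], entry.positive_value or ""
                )
            dataset_outcomes[dim.id] = rolled
            record_outcomes.setdefault(dim.id, per_record)
            measures.append(
                build_assertion(
                    dim, entry.specification.id, entry.mechanism.id,
                    _resource_ref(resource, None, None), rolled,
                )
            )

    validations: list[Assertion] = []
    derived: list[Assertion] = []
    for crit in profile.validation_policy:
        dim = profile.dimension(crit.dimension_ref)
        entry = registry.resolve(dim.specification_ref)
        if dim.resource_type is ResourceType.DATASET:
            result = validate_against_criterion(dataset_outcomes[dim.id], crit)
            validations.append(
                build_assertion(
                    crit, VALIDATION_SPEC_ID, entry.mechanism.id,
                    _resource_ref(resource, None, None), result,
                )
            )
        else:
            per_record = record_outcomes[dim.id]
            results = []
            for (rid, rec), (_, m) in zip(rows, per_record):
                vres = validate_against_criterion(m, crit)
                results.append(vres)
                validations.append(
                    build_assertion(
                        crit, VALIDATION_SPEC_ID, entry.mechanism.id,
                        _resource_ref(resource, rid, rec), vres,
                    )
                )
            if is_dataset and results:
                # convenience roll-up, outside the core profile->report mapping
                k = sum(
                    1 for r in results
                    if r.outcome is ValidationOutcome.COMPLIANT
                )
                derived.append(
                    build_assertion(
                        crit, DERIVED_SUMMARY_SPEC_ID, entry.mechanism.id,
                        _resource_ref(resource, None, None),
                        ValidationResult(
                            status=MeasureStatus.COMPLETED,
                            outcome=(
                                ValidationOutcome.COMPLIANT
                                if k == len(results)
                                else ValidationOutcome.NOT_COMPLIANT
                            ),
                            detail=f"derived: {k}/{len(results)} records compliant",
                        ),
                    )
                )

    amendments: list[Assertion] = []
    for enh in profile.enhancement_policy:
        entry = registry.resolve(enh.specification_ref)
        if entry.kind != "amendment":
            raise UnresolvedSpecificationError([enh.specification_ref])
        params = entry.specification.formal_params
        for rid, rec in rows:
            result = entry.record_fn(rec, registry.reference_data, params)
            stamped = AmendmentResult(
                status=result.status,
                proposed_changes=result.proposed_changes,
                rationale=result.rationale,
                replaces_existing=result.replaces_existing,
                enhancement_type=enh.enhancement_type,
            )
            amendments.append(
                build_assertion(
                    enh, entry.specification.id, entry.mechanism.id,
                    _resource_ref(resource, rid, rec), stamped,
                )
            )

    return Report(
        profile_ref=profile.id,
        resource_ref=resource.resource_id,
        measures=measures,
        validations=validations,
        amendments=amendments,
        derived_summaries=derived,
        generated_at=generated_at
        or datetime.datetime.now(datetime.timezone.utc).isoformat(),
        engine_version=__version__,
    )


@dataclass(frozen=True)
class ExclusionLogEntry:
    row_id: int
    failed_criteria: tuple[str, ...]


def filter_fit_for_use(
    dataset: DataResource, profile: Profile, report: Report
) -> tuple[DataResource, list[ExclusionLogEntry]]:
    """Quality assurance: retain exactly the records whose record-level
    validations are all COMPLIANT.

    Records with any NOT_COMPLIANT or unassessable (PREREQUISITES_NOT_MET)
    validation are excluded and logged with the failing criterion ids.
    Dataset-level criteria never remove individual records.  Row ids are
    preserved in the retained subset, so filtering is idempotent.
    """
    if dataset.resource_type is not ResourceType.DATASET:
        raise ValueError("filter_fit_for_use requires a DATASET resource")
    if report.resource_ref != dataset.resource_id:
        raise ReportMismatchError(
            f"report targets {report.resource_ref!r}, dataset is "
            f"{dataset.resource_id!r}"
        )
    known_rows = set(dataset.row_ids or [])
    failures: dict[int, list[str]] = {}
    for assertion in report.validations:
        rid = assertion.resource_ref.row_id
        if rid is None:
            continue  # dataset-level criterion
        if rid not in known_rows:
            raise ReportMismatchError(f"report references unknown row id {rid}")
        result = assertion.result
        bad = (
            result.status is MeasureStatus.PREREQUISITES_NOT_MET
            or result.outcome is ValidationOutcome.NOT_COMPLIANT
        )
        if bad:
            failures.setdefault(rid, []).append(assertion.element_ref)
    retained = [rid for rid in (dataset.row_ids or []) if rid not in failures]
    log = [
        ExclusionLogEntry(row_id=rid, failed_criteria=tuple(fails))
        for rid, fails in sorted(failures.items())
    ]
    return dataset.subset(retained), log


@dataclass(frozen=True)
class ChangeLogEntry:
    row_id: int
    field: str
    old: str
    new: str
    enhancement_id: str


@dataclass(frozen=True)
class AmendmentConflict:
    row_id: int
    field: str
    enhancement_ids: tuple[str, ...]
    values: tuple[str, ...]


@dataclass
class AmendmentOutcome:
    dataset: DataResource
    changelog: list[ChangeLogEntry]
    conflicts: list[AmendmentConflict]
    pending: list[Assertion]  # proposals not accepted under the policy


def apply_amendments(
    dataset: DataResource, report: Report, policy: AmendmentPolicy
) -> AmendmentOutcome:
    """Quality control: apply accepted proposals to a copy of the data.

    The original dataset is never modified.  Proposals are all computed
    against the original values (no chaining); conflicting proposals for the
    same (row, field) from different enhancements are both dropped and
    logged as conflicts.
    """
    if dataset.resource_type is not ResourceType.DATASET:
        raise ValueError("apply_amendments requires a DATASET resource")
    if report.resource_ref != dataset.resource_id:
        raise ReportMismatchError(
            f"report targets {report.resource_ref!r}, dataset is "
            f"{dataset.resource_id!r}"
        )
    known_rows = set(dataset.row_ids or [])

    # (row, field) -> list of (enhancement id, new value)
    staged: dict[tuple[int, str], list[tuple[str, str]]] = {}
    pending: list[Assertion] = []
    for assertion in report.amendments:
        result = assertion.result
        if result.status is not AmendmentStatus.PROPOSED:
            continue
        rid = assertion.resource_ref.row_id
        if rid is None or rid not in known_rows:
            raise ReportMismatchError(
                f"amendment references unknown row id {rid!r}"
            )
        if not policy.accepts(result.enhancement_type):
            pending.append(assertion)
            continue
        for fld, new_value in result.proposed_changes.items():
            staged.setdefault((rid, fld), []).append(
                (assertion.element_ref, new_value)
            )

    records = {rid: dict(rec) for rid, rec in dataset.iter_rows()}
    changelog: list[ChangeLogEntry] = []
    conflicts: list[AmendmentConflict] = []
    for (rid, fld), proposals in sorted(staged.items()):
        values = {v for _, v in proposals}
        if len(values) > 1:
            conflicts.append(
                AmendmentConflict(
                    row_id=rid,
                    field=fld,
                    enhancement_ids=tuple(e for e, _ in proposals),
                    values=tuple(v for _, v in proposals),
                )
            )
            continue
        enhancement_id, new_value = proposals[0]
        old = records[rid].get(fld, "")
        records[rid][fld] = new_value
        changelog.append(
            ChangeLogEntry(
                row_id=rid, field=fld, old=old, new=new_value,
                enhancement_id=enhancement_id,
            )
        )

    amended = DataResource(
        resource_type=ResourceType.DATASET,
        records=[records[rid] for rid in (dataset.row_ids or [])],
        row_ids=list(dataset.row_ids or []),
        resource_id=dataset.resource_id,
        source_uri=dataset.source_uri,
    )
    return AmendmentOutcome(
        dataset=amended, changelog=changelog, conflicts=conflicts,
        pending=pending,
    )
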