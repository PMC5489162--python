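"""Domain types for fitness-for-use data-quality profiles and assertions.

The vocabulary follows the TDWG/GBIF biodiversity data-quality framework:
a *Use Case* scopes what quality means, *Information Elements* name the
record fields that matter, contextualized *Dimensions* are measured,
*Criteria* validate the measures, and *Enhancements* describe how data
could be improved.  Running mechanisms over a *Data Resource* (a single
occurrence record or a dataset) yields five-component *Assertions* —
measures, validations and proposed amendments — collected in a *Report*.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union


class _Missing:
    """Sentinel for an absent or blank record value."""

    _instance: Optional["_Missing"] = None

    def __new__(cls) -> "_Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

#: Sentinel strings that count as "no value" after trimming, case-insensitive.
MISSING_SENTINELS = frozenset({"", "null", "na", "n/a"})


def is_missing(value: object) -> bool:
    """True if *value* is absent or normalizes to empty.

    A value is missing when it is None / the MISSING sentinel, or when its
    text, after stripping whitespace, is empty or one of the conventional
    null markers (``NULL``, ``NA``, ``N/A``, case-insensitive) that dominate
    real occurrence exports.
    """
    if value is None or value is MISSING:
        return True
    if isinstance(value, str):
        return value.strip().lower() in MISSING_SENTINELS
    return False


class ResourceType(str, enum.Enum):
    SINGLE_RECORD = "SINGLE_RECORD"
    DATASET = "DATASET"


class IEKind(str, enum.Enum):
    SINGLE = "SINGLE"
    COMPOSED = "COMPOSED"


class Comparator(str, enum.Enum):
    EQ = "EQ"
    GE = "GE"
    LE = "LE"
    GT = "GT"
    LT = "LT"


class EnhancementType(str, enum.Enum):
    PREVENTION = "PREVENTION"
    CORRECTION = "CORRECTION"
    RECOMMENDATION = "RECOMMENDATION"


class Coverage(str, enum.Enum):
    BROAD = "BROAD"
    SPECIFIC = "SPECIFIC"


class MeasureStatus(str, enum.Enum):
    COMPLETED = "COMPLETED"
    PREREQUISITES_NOT_MET = "PREREQUISITES_NOT_MET"


class ValidationOutcome(str, enum.Enum):
    COMPLIANT = "COMPLIANT"
    NOT_COMPLIANT = "NOT_COMPLIANT"


class AmendmentStatus(str, enum.Enum):
    PROPOSED = "PROPOSED"
    NOT_PROPOSED = "NOT_PROPOSED"
    PREREQUISITES_NOT_MET = "PREREQUISITES_NOT_MET"


class AssertionType(str, enum.Enum):
    MEASURE = "MEASURE"
    VALIDATION = "VALIDATION"
    AMENDMENT = "AMENDMENT"


# Well-known dimension names; the enum-like namespace is open — any string
# names a dimension (the framework treats the catalogue as extensible).
DIMENSION_COMPLETENESS = "COMPLETENESS"
DIMENSION_CONFORMITY = "CONFORMITY"
DIMENSION_CONSISTENCY = "CONSISTENCY"


class IncompleteAssertionError(ValueError):
    """An assertion was built with a null/missing component."""


class SubtypeMismatchError(TypeError):
    """Element subtype and result subtype do not match."""


@dataclass(frozen=True)
class UseCase:
    """The data-use story whose purpose defines what quality means."""

    id: str
    label: str = ""
    description: str = ""
    stakeholder_notes: Optional[str] = None


@dataclass(frozen=True)
class InformationElement:
    """A named single field or composed set of fields meaningful to a use case.

    The classic composed example is "coordinates": decimalLatitude,
    decimalLongitude, coordinateUncertaintyInMeters and geodeticDatum taken
    together as one point-radius georeference.
    """

    id: str
    label: str
    kind: IEKind
    terms: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))


@dataclass(frozen=True)
class ContextualizedDimension:
    """A quality dimension bound to an information element and resource type."""

    id: str
    dimension: str
    ie_ref: str
    resource_type: ResourceType
    specification_ref: str


@dataclass(frozen=True)
class ContextualizedCriterion:
    """A pass/fail rule over a dimension's measure.

    For DATASET dimensions ``threshold`` is a proportion in [0, 1] compared
    with ``comparator``; for SINGLE_RECORD dimensions it is the required
    qualitative value (comparator must be EQ).
    """

    id: str
    dimension_ref: str
    comparator: Comparator
    threshold: Union[float, str]
    statement: str = ""


@dataclass(frozen=True)
class ContextualizedEnhancement:
    """A described improvement activity targeting one or more dimensions."""

    id: str
    enhancement_type: EnhancementType
    target_dimension_refs: tuple[str, ...]
    specification_ref: str
    statement: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "target_dimension_refs", tuple(self.target_dimension_refs)
        )


@dataclass(frozen=True)
class Specification:
    """A formal or informal description of a measurement/validation/enhancement
    method; the human-readable text is mandatory, formal parameters optional."""

    id: str
    human_text: str
    formal_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.human_text:
            raise ValueError(f"specification {self.id!r}: human_text is mandatory")
        object.__setattr__(self, "formal_params", dict(self.formal_params))


@dataclass(frozen=True)
class Mechanism:
    """An artifact that executes one (SPECIFIC) or several (BROAD) specifications."""

    id: str
    label: str
    coverage: Coverage
    implements: tuple[str, ...]
    uses: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "implements", tuple(self.implements))
        object.__setattr__(self, "uses", tuple(self.uses))
        n = len(self.implements)
        if self.coverage is Coverage.SPECIFIC and n != 1:
            raise ValueError(
                f"mechanism {self.id!r}: SPECIFIC coverage implies exactly one "
                f"specification, got {n}"
            )
        if self.coverage is Coverage.BROAD and n < 2:
            raise ValueError(
                f"mechanism {self.id!r}: BROAD coverage implies >=2 specifications"
            )


@dataclass
class DataResource:
    """A single occurrence record or an ordered multi-record dataset.

    Field values are kept verbatim as text; any type coercion happens only
    inside mechanisms.  Row ids are stable and positional by default.
    """

    resource_type: ResourceType
    record: Optional[Mapping[str, str]] = None
    records: Optional[list[dict[str, str]]] = None
    row_ids: Optional[list[int]] = None
    resource_id: str = "resource"
    source_uri: Optional[str] = None

    def __post_init__(self) -> None:
        if self.resource_type is ResourceType.SINGLE_RECORD:
            if self.record is None or self.records is not None:
                raise ValueError("SINGLE_RECORD resource must populate exactly `record`")
        else:
            if self.records is None or self.record is not None:
                raise ValueError("DATASET resource must populate exactly `records`")
            if self.row_ids is None:
                self.row_ids = list(range(len(self.records)))
            elif len(self.row_ids) != len(self.records):
                raise ValueError("row_ids length must match records length")

    @property
    def n_records(self) -> int:
        if self.resource_type is ResourceType.SINGLE_RECORD:
            return 1
        return len(self.records or [])

    def iter_rows(self):
        """Yield (row_id, record) pairs in dataset order."""
        if self.resource_type is ResourceType.SINGLE_RECORD:
            yield None, dict(self.record or {})
        else:
            for rid, rec in zip(self.row_ids or [], self.records or []):
                yield rid, rec

    def subset(self, keep_row_ids: Sequence[int]) -> "DataResource":
        """New DATASET resource restricted to *keep_row_ids*, preserving order
        and the original row ids."""
        if self.resource_type is not ResourceType.DATASET:
            raise ValueError("subset() only applies to DATASET resources")
        keep = set(keep_row_ids)
        recs, rids = [], []
        for rid, rec in self.iter_rows():
            if rid in keep:
                recs.append(dict(rec))
                rids.append(rid)
        return DataResource(
            resource_type=ResourceType.DATASET,
            records=recs,
            row_ids=rids,
            resource_id=self.resource_id,
            source_uri=self.source_uri,
        )


@dataclass(frozen=True)
class ResourceRef:
    """Pointer from an assertion to its target: a dataset, or one row of it.

    ``occurrence_id`` echoes the record's occurrenceID when present, purely
    for traceability; row identity is positional.
    """

    dataset_id: str
    row_id: Optional[int] = None
    occurrence_id: Optional[str] = None

    def __str__(self) -> str:
        if self.row_id is None:
            return self.dataset_id
        return f"{self.dataset_id}#{self.row_id}"


@dataclass(frozen=True)
class MeasureResult:
    """Outcome of measuring a dimension: qualitative for single records
    (e.g. COMPLETE / NOT_COMPLETE), quantitative in [0, 1] for datasets."""

    status: MeasureStatus
    qualitative: Optional[str] = None
    quantitative: Optional[float] = None
    detail: str = ""

    def __post_init__(self) -> None:
        has_q = self.qualitative is not None
        has_n = self.quantitative is not None
        if self.status is MeasureStatus.COMPLETED:
            if has_q == has_n:
                raise ValueError(
                    "COMPLETED measure must set exactly one of qualitative/quantitative"
                )
        elif has_q or has_n:
            raise ValueError("PREREQUISITES_NOT_MET measure carries no value")
        if has_n and not 0.0 <= float(self.quantitative) <= 1.0:
            raise ValueError(f"quantitative measure {self.quantitative} outside [0, 1]")


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of judging a measure against a criterion."""

    status: MeasureStatus
    outcome: Optional[ValidationOutcome] = None
    detail: str = ""

    def __post_init__(self) -> None:
        if (self.status is MeasureStatus.COMPLETED) != (self.outcome is not None):
            raise ValueError("validation COMPLETED iff outcome present")


@dataclass(frozen=True)
class AmendmentResult:
    """A proposed (never applied in place) change to a record.

    ``replaces_existing`` lists proposed fields whose current value is
    non-blank — i.e. recommendation-style replacements rather than fills.
    ``enhancement_type`` is stamped by the engine so downstream policy
    decisions need no profile lookup.
    """

    status: AmendmentStatus
    proposed_changes: Mapping[str, str] = field(default_factory=dict)
    rationale: str = ""
    replaces_existing: tuple[str, ...] = ()
    enhancement_type: Optional[EnhancementType] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "proposed_changes", dict(self.proposed_changes))
        object.__setattr__(self, "replaces_existing", tuple(self.replaces_existing))
        if (self.status is AmendmentStatus.PROPOSED) != bool(self.proposed_changes):
            raise ValueError("proposed_changes non-empty iff status is PROPOSED")


ResultT = Union[MeasureResult, ValidationResult, AmendmentResult]
ElementT = Union[ContextualizedDimension, ContextualizedCriterion, ContextualizedEnhancement]


@dataclass(frozen=True)
class Assertion:
    """The five-component data-quality assertion: element in context,
    specification, mechanism, data resource, and result."""

    assertion_type: AssertionType
    element_ref: str
    specification_ref: str
    mechanism_ref: str
    resource_ref: ResourceRef
    result: ResultT


_ELEMENT_RESULT_PAIRS = {
    ContextualizedDimension: (MeasureResult, AssertionType.MEASURE),
    ContextualizedCriterion: (ValidationResult, AssertionType.VALIDATION),
    ContextualizedEnhancement: (AmendmentResult, AssertionType.AMENDMENT),
}


def build_assertion(
    element: ElementT,
    specification_ref: str,
    mechanism_ref: str,
    resource_ref: ResourceRef,
    result: ResultT,
) -> Assertion:
    """Assemble an immutable five-component assertion.

    Raises IncompleteAssertionError if any component is null/empty and
    SubtypeMismatchError if the result subtype does not match the element
    subtype (dimension -> measure, criterion -> validation, enhancement ->
    amendment).
    """
    components = {
        "element": element,
        "specification_ref": specification_ref,
        "mechanism_ref": mechanism_ref,
        "resource_ref": resource_ref,
        "result": result,
    }
    for name, value in components.items():
        if value is None or value == "":
            raise IncompleteAssertionError(f"incomplete assertion: {name} is missing")
    pair = _ELEMENT_RESULT_PAIRS.get(type(element))
    if pair is None:
        raise SubtypeMismatchError(f"{type(element).__name__} is not an assertable element")
    expected_result, assertion_type = pair
    if not isinstance(result, expected_result):
        raise SubtypeMismatchError(
            f"{type(element).__name__} requires {expected_result.__name__}, "
            f"got {type(result).__name__}"
        )
    return Assertion(
        assertion_type=assertion_type,
        element_ref=element.id,
        specification_ref=specification_ref,
        mechanism_ref=mechanism_ref,
        resource_ref=resource_ref,
        result=result,
    )


@dataclass(frozen=True)
class Profile:
    """A declarative data-quality wish-list: use case, valuable information
    elements, and the measurement / validation / enhancement policies."""

    use_case: UseCase
    valuable_ies: tuple[InformationElement, ...]
    measurement_policy: tuple[ContextualizedDimension, ...]
    validation_policy: tuple[ContextualizedCriterion, ...] = ()
    enhancement_policy: tuple[ContextualizedEnhancement, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "valuable_ies", tuple(self.valuable_ies))
        object.__setattr__(self, "measurement_policy", tuple(self.measurement_policy))
        object.__setattr__(self, "validation_policy", tuple(self.validation_policy))
        object.__setattr__(self, "enhancement_policy", tuple(self.enhancement_policy))

    @property
    def id(self) -> str:
        return self.use_case.id

    def dimension(self, dim_id: str) -> Optional[ContextualizedDimension]:
        for d in self.measurement_policy:
            if d.id == dim_id:
                return d
        return None

    def information_element(self, ie_id: str) -> Optional[InformationElement]:
        for ie in self.valuable_ies:
            if ie.id == ie_id:
                return ie
        return None

    def enhancement(self, enh_id: str) -> Optional[ContextualizedEnhancement]:
        for e in self.enhancement_policy:
            if e.id == enh_id:
                return e
        return None


@dataclass
class Report:
    """The DQ status of one data resource under one profile: a measure per
    dimension, a validation per criterion, an amendment per enhancement per
    applicable record.  ``derived_summaries`` carries convenience dataset
    roll-ups of record-level validations; they are not part of the core
    profile-to-report mapping."""

    profile_ref: str
    resource_ref: str
    measures: list[Assertion]
    validations: list[Assertion]
    amendments: list[Assertion]
    generated_at: str
    engine_version: str
    derived_summaries: list[Assertion] = field(default_factory=list)


@dataclass(frozen=True)
class ProfileViolation:
    """One structural rule broken by a profile document."""

    section: str
    item_id: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.section}] {self.item_id}: {self.message} ({self.rule})"


_SEMVER_RE = re.compile(r"^\d+\.\d+(\.\d+)?$")


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


def validate_profile(
    profile: Profile,
    known_specifications: Optional[set[str]] = None,
) -> list[ProfileViolation]:
    """Check every structural invariant of a profile.

    Returns an empty list iff the profile is well formed.  Violations are
    data, not exceptions: each names the offending section, id and rule.
    When *known_specifications* is given, dimension and enhancement
    specification references are resolved against it as well.
    """
    out: list[ProfileViolation] = []

    def add(section: str, item_id: str, rule: str, message: str) -> None:
        out.append(ProfileViolation(section, item_id, rule, message))

    if not profile.use_case.id:
        add("use_case", "", "use-case-id-empty", "use case id must be non-empty")

    if not profile.valuable_ies:
        add("information_elements", "", "no-valuable-ies",
            "profile declares no valuable information elements")

    ie_ids = [ie.id for ie in profile.valuable_ies]
    for section, ids in (
        ("information_elements", ie_ids),
        ("measurement_policy", [d.id for d in profile.measurement_policy]),
        ("validation_policy", [c.id for c in profile.validation_policy]),
        ("enhancement_policy", [e.id for e in profile.enhancement_policy]),
    ):
        for dup in _duplicates(ids):
            add(section, dup, "duplicate-id", f"id {dup!r} declared more than once")

    for ie in profile.valuable_ies:
        if not ie.terms:
            add("information_elements", ie.id, "ie-empty-terms",
                "information element declares no terms")
            continue
        if ie.kind is IEKind.SINGLE and len(ie.terms) != 1:
            add("information_elements", ie.id, "ie-kind-term-count",
                f"SINGLE element must have exactly one term, has {len(ie.terms)}")
        if ie.kind is IEKind.COMPOSED and len(ie.terms) < 2:
            add("information_elements", ie.id, "ie-kind-term-count",
                "COMPOSED element must have at least two terms")
        for dup in _duplicates(list(ie.terms)):
            add("information_elements", ie.id, "ie-duplicate-terms",
                f"term {dup!r} repeated within the element")

    ie_id_set = set(ie_ids)
    dim_ids = {d.id for d in profile.measurement_policy}

    for dim in profile.measurement_policy:
        if dim.ie_ref not in ie_id_set:
            add("measurement_policy", dim.id, "dimension-unknown-ie",
                f"dimension references undeclared information element {dim.ie_ref!r}")
        if known_specifications is not None and dim.specification_ref not in known_specifications:
            add("measurement_policy", dim.id, "unknown-specification",
                f"dimension references unregistered specification {dim.specification_ref!r}")

    for crit in profile.validation_policy:
        dim = profile.dimension(crit.dimension_ref)
        if dim is None:
            add("validation_policy", crit.id, "criterion-unknown-dimension",
                f"criterion references undeclared dimension {crit.dimension_ref!r}")
            continue
        if dim.resource_type is ResourceType.DATASET:
            if not isinstance(crit.threshold, (int, float)) or isinstance(crit.threshold, bool):
                add("validation_policy", crit.id, "threshold-type",
                    "dataset-level criterion requires a numeric threshold")
            elif not 0.0 <= float(crit.threshold) <= 1.0:
                add("validation_policy", crit.id, "threshold-range",
                    f"threshold {crit.threshold} outside the proportion scale [0, 1]")
        else:
            if not isinstance(crit.threshold, str):
                add("validation_policy", crit.id, "threshold-type",
                    "record-level criterion requires a qualitative required value")
            if crit.comparator is not Comparator.EQ:
                add("validation_policy", crit.id, "qualitative-comparator",
                    "record-level criteria support only the EQ comparator")

    for enh in profile.enhancement_policy:
        if not enh.target_dimension_refs:
            add("enhancement_policy", enh.id, "enhancement-no-targets",
                "enhancement targets no dimension")
        for ref in enh.target_dimension_refs:
            if ref not in dim_ids:
                add("enhancement_policy", enh.id, "enhancement-unknown-dimension",
                    f"enhancement targets undeclared dimension {ref!r}")
        if known_specifications is not None and enh.specification_ref not in known_specifications:
            add("enhancement_policy", enh.id, "unknown-specification",
                f"enhancement references unregistered specification {enh.specification_ref!r}")

    out.sort(key=lambda v: (v.section, v.item_id, v.rule, v.message))
    return out


def resolve_information_element(
    record: Mapping[str, str], ie: InformationElement
) -> list[tuple[str, object]]:
    """Resolve an information element against one record.

    Returns one ``(term, value)`` pair per declared term, in declared order;
    the value is the MISSING sentinel when the term is absent from the
    record or its text normalizes to empty.
    """
    out: list[tuple[str, object]] = []
    for term in ie.terms:
        value = record.get(term)
        out.append((term, MISSING if is_missing(value) else value))
    return out
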