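"""Readers and writers for occurrence data, profiles, reference data and reports.

All readers reject malformed input with location-bearing messages instead
of silently coercing.  Occurrence values are kept verbatim as text; profile
thresholds written as percentages ("100%") are normalized to proportions.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Optional, Union

import yaml
from shapely.errors import GEOSException
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from .mechanisms import RANK_ORDER, ReferenceData, TaxonNode, normalize_locality
from .model import (
    AmendmentResult,
    AmendmentStatus,
    Assertion,
    AssertionType,
    Comparator,
    ContextualizedCriterion,
    ContextualizedDimension,
    ContextualizedEnhancement,
    DataResource,
    EnhancementType,
    IEKind,
    InformationElement,
    MeasureResult,
    MeasureStatus,
    Profile,
    Report,
    ResourceRef,
    ResourceType,
    UseCase,
    ValidationOutcome,
    ValidationResult,
)

FORMAT_VERSION = "1.0"
_SUPPORTED_MAJOR = 1

PathLike = Union[str, Path]


class DataFormatError(ValueError):
    """Malformed input file; the message carries a location."""


class ProfileSchemaError(DataFormatError):
    """Profile document violates the published schema."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("profile schema violations: " + "; ".join(self.problems))


# ---------------------------------------------------------------------------
# Occurrence data

def read_occurrences(
    path: PathLike,
    delimiter: Optional[str] = None,
    resource_id: Optional[str] = None,
) -> DataResource:
    """Read a Darwin Core occurrence CSV/TSV into a DATASET resource.

    The delimiter is auto-detected between comma and tab from the header
    line unless forced.  Row ids are 0-based and positional.  Duplicate
    header names and ragged rows are hard errors.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise DataFormatError(f"{path}: missing header row")
    if delimiter is None:
        header_line = lines[0]
        delimiter = "\t" if header_line.count("\t") > header_line.count(",") else ","
    reader = csv.reader(text.splitlines(), delimiter=delimiter)
    rows = list(reader)
    header = rows[0]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise DataFormatError(
            f"{path}: duplicate header name(s): {', '.join(dups)}"
        )
    records: list[dict[str, str]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise DataFormatError(
                f"{path}: row {i} has {len(row)} fields, header has {len(header)}"
            )
        records.append(dict(zip(header, row)))
    return DataResource(
        resource_type=ResourceType.DATASET,
        records=records,
        resource_id=resource_id or path.stem,
        source_uri=str(path),
    )


def write_occurrences(resource: DataResource, path: PathLike,
                      delimiter: str = ",") -> None:
    """Write a DATASET resource back to CSV/TSV with a stable header union."""
    path = Path(path)
    header: list[str] = []
    for _, rec in resource.iter_rows():
        for key in rec:
            if key not in header:
                header.append(key)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(header)
        for _, rec in resource.iter_rows():
            writer.writerow([rec.get(h, "") for h in header])


# ---------------------------------------------------------------------------
# Profiles

_PERCENT_RE = re.compile(r"^\s*([0-9]+(\.[0-9]+)?)\s*%\s*$")


def _parse_threshold(value: object, dataset_level: bool, path: str,
                     problems: list[str]):
    if dataset_level:
        if isinstance(value, str):
            m = _PERCENT_RE.match(value)
            if m:
                return float(m.group(1)) / 100.0
            try:
                return float(value)
            except ValueError:
                problems.append(f"{path}: threshold {value!r} is not a number or percentage")
                return 0.0
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return float(value)
        problems.append(f"{path}: threshold must be numeric for dataset dimensions")
        return 0.0
    if not isinstance(value, str):
        problems.append(f"{path}: record-level threshold must be a qualitative value")
        return str(value)
    return value


def _check_keys(obj: dict, path: str, required: set[str], optional: set[str],
                problems: list[str]) -> bool:
    if not isinstance(obj, dict):
        problems.append(f"{path}: expected a mapping")
        return False
    for key in sorted(set(obj) - required - optional):
        problems.append(f"{path}.{key}: unknown key")
    ok = True
    for key in sorted(required - set(obj)):
        problems.append(f"{path}.{key}: required key missing")
        ok = False
    return ok


def _enum(cls, value, path, problems):
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in cls)
        problems.append(f"{path}: {value!r} not one of {allowed}")
        return None


def profile_from_document(doc: dict) -> Profile:
    """Build a Profile from a parsed YAML/JSON document, enforcing the
    schema: unknown keys are rejected with their paths; a newer major
    format_version is refused."""
    problems: list[str] = []
    if not isinstance(doc, dict):
        raise ProfileSchemaError(["$: document must be a mapping"])
    _check_keys(
        doc, "$",
        required={"format_version", "use_case", "information_elements",
                  "measurement_policy"},
        optional={"validation_policy", "enhancement_policy"},
        problems=problems,
    )
    version = str(doc.get("format_version", FORMAT_VERSION))
    m = re.match(r"^(\d+)\.(\d+)(\.\d+)?$", version)
    if not m:
        problems.append(f"$.format_version: {version!r} is not MAJOR.MINOR")
    elif int(m.group(1)) > _SUPPORTED_MAJOR:
        problems.append(
            f"$.format_version: major version {m.group(1)} is newer than "
            f"supported {_SUPPORTED_MAJOR}"
        )
    if problems:
        raise ProfileSchemaError(problems)

    uc_doc = doc["use_case"]
    _check_keys(uc_doc, "$.use_case", {"id"},
                {"label", "description", "stakeholder_notes"}, problems)
    use_case = UseCase(
        id=str(uc_doc.get("id", "")),
        label=str(uc_doc.get("label", "")),
        description=str(uc_doc.get("description", "")),
        stakeholder_notes=uc_doc.get("stakeholder_notes"),
    ) if isinstance(uc_doc, dict) else UseCase(id="")

    ies = []
    for i, item in enumerate(doc.get("information_elements") or []):
        p = f"$.information_elements[{i}]"
        if not _check_keys(item, p, {"id", "kind", "terms"},
                           {"label", "description"}, problems):
            continue
        kind = _enum(IEKind, item["kind"], f"{p}.kind", problems)
        terms = item["terms"]
        if not isinstance(terms, list) or not all(isinstance(t, str) for t in terms):
            problems.append(f"{p}.terms: expected a list of term names")
            terms = []
        if kind is None:
            continue
        ies.append(InformationElement(
            id=str(item["id"]), label=str(item.get("label", item["id"])),
            kind=kind, terms=tuple(terms),
            description=str(item.get("description", "")),
        ))

    dims = []
    dim_types: dict[str, ResourceType] = {}
    for i, item in enumerate(doc.get("measurement_policy") or []):
        p = f"$.measurement_policy[{i}]"
        if not _check_keys(item, p,
                           {"id", "dimension", "information_element",
                            "resource_type", "specification"},
                           set(), problems):
            continue
        rt = _enum(ResourceType, item["resource_type"], f"{p}.resource_type",
                   problems)
        if rt is None:
            continue
        dim = ContextualizedDimension(
            id=str(item["id"]), dimension=str(item["dimension"]),
            ie_ref=str(item["information_element"]), resource_type=rt,
            specification_ref=str(item["specification"]),
        )
        dims.append(dim)
        dim_types[dim.id] = rt

    crits = []
    for i, item in enumerate(doc.get("validation_policy") or []):
        p = f"$.validation_policy[{i}]"
        if not _check_keys(item, p, {"id", "dimension", "comparator", "threshold"},
                           {"statement"}, problems):
            continue
        comparator = _enum(Comparator, item["comparator"], f"{p}.comparator",
                           problems)
        if comparator is None:
            continue
        dataset_level = dim_types.get(
            str(item["dimension"])) is ResourceType.DATASET
        threshold = _parse_threshold(item["threshold"], dataset_level,
                                     f"{p}.threshold", problems)
        crits.append(ContextualizedCriterion(
            id=str(item["id"]), dimension_ref=str(item["dimension"]),
            comparator=comparator, threshold=threshold,
            statement=str(item.get("statement", "")),
        ))

    enhs = []
    for i, item in enumerate(doc.get("enhancement_policy") or []):
        p = f"$.enhancement_policy[{i}]"
        if not _check_keys(item, p,
                           {"id", "type", "target_dimensions", "specification"},
                           {"statement"}, problems):
            continue
        etype = _enum(EnhancementType, item["type"], f"{p}.type", problems)
        targets = item["target_dimensions"]
        if not isinstance(targets, list):
            problems.append(f"{p}.target_dimensions: expected a list")
            targets = []
        if etype is None:
            continue
        enhs.append(ContextualizedEnhancement(
            id=str(item["id"]), enhancement_type=etype,
            target_dimension_refs=tuple(str(t) for t in targets),
            specification_ref=str(item["specification"]),
            statement=str(item.get("statement", "")),
        ))

    if problems:
        raise ProfileSchemaError(problems)
    return Profile(
        use_case=use_case, valuable_ies=tuple(ies),
        measurement_policy=tuple(dims), validation_policy=tuple(crits),
        enhancement_policy=tuple(enhs),
    )


def profile_to_document(profile: Profile) -> dict:
    """Inverse of profile_from_document (write -> read round-trips)."""
    doc: dict = {
        "format_version": FORMAT_VERSION,
        "use_case": {
            "id": profile.use_case.id,
            "label": profile.use_case.label,
            "description": profile.use_case.description,
        },
        "information_elements": [
            {
                "id": ie.id, "label": ie.label, "kind": ie.kind.value,
                "terms": list(ie.terms), "description": ie.description,
            }
            for ie in profile.valuable_ies
        ],
        "measurement_policy": [
            {
                "id": d.id, "dimension": d.dimension,
                "information_element": d.ie_ref,
                "resource_type": d.resource_type.value,
                "specification": d.specification_ref,
            }
            for d in profile.measurement_policy
        ],
        "validation_policy": [
            {
                "id": c.id, "dimension": c.dimension_ref,
                "comparator": c.comparator.value, "threshold": c.threshold,
                "statement": c.statement,
            }
            for c in profile.validation_policy
        ],
        "enhancement_policy": [
            {
                "id": e.id, "type": e.enhancement_type.value,
                "target_dimensions": list(e.target_dimension_refs),
                "specification": e.specification_ref,
                "statement": e.statement,
            }
            for e in profile.enhancement_policy
        ],
    }
    if profile.use_case.stakeholder_notes is not None:
        doc["use_case"]["stakeholder_notes"] = profile.use_case.stakeholder_notes
    return doc


def read_profile(path: PathLike) -> Profile:
    """Read a profile from YAML (.yaml/.yml) or JSON (.json) by extension."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise DataFormatError(f"{path}: invalid JSON: {exc}") from exc
    elif path.suffix.lower() in {".yaml", ".yml"}:
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise DataFormatError(f"{path}: invalid YAML: {exc}") from exc
    else:
        raise DataFormatError(
            f"{path}: unknown profile extension {path.suffix!r} "
            "(expected .yaml, .yml or .json)"
        )
    return profile_from_document(doc)


def write_profile(profile: Profile, path: PathLike) -> None:
    path = Path(path)
    doc = profile_to_document(profile)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False),
                        encoding="utf-8")


# ---------------------------------------------------------------------------
# Reports

def _resource_ref_to_doc(ref: ResourceRef) -> dict:
    doc: dict = {"dataset_id": ref.dataset_id}
    if ref.row_id is not None:
        doc["row_id"] = ref.row_id
    if ref.occurrence_id is not None:
        doc["occurrence_id"] = ref.occurrence_id
    return doc


def _result_to_doc(result) -> dict:
    if isinstance(result, MeasureResult):
        doc = {"status": result.status.value, "detail": result.detail}
        if result.qualitative is not None:
            doc["qualitative"] = result.qualitative
        if result.quantitative is not None:
            doc["quantitative"] = result.quantitative
        return doc
    if isinstance(result, ValidationResult):
        doc = {"status": result.status.value, "detail": result.detail}
        if result.outcome is not None:
            doc["outcome"] = result.outcome.value
        return doc
    doc = {
        "status": result.status.value,
        "proposed_changes": dict(result.proposed_changes),
        "rationale": result.rationale,
    }
    if result.replaces_existing:
        doc["replaces_existing"] = list(result.replaces_existing)
    if result.enhancement_type is not None:
        doc["enhancement_type"] = result.enhancement_type.value
    return doc


def _assertion_to_doc(assertion: Assertion) -> dict:
    return {
        "assertion_type": assertion.assertion_type.value,
        "element": assertion.element_ref,
        "specification": assertion.specification_ref,
        "mechanism": assertion.mechanism_ref,
        "resource": _resource_ref_to_doc(assertion.resource_ref),
        "result": _result_to_doc(assertion.result),
    }


def report_to_document(report: Report) -> dict:
    return {
        "profile": report.profile_ref,
        "resource": report.resource_ref,
        "generated_at": report.generated_at,
        "engine_version": report.engine_version,
        "measures": [_assertion_to_doc(a) for a in report.measures],
        "validations": [_assertion_to_doc(a) for a in report.validations],
        "amendments": [_assertion_to_doc(a) for a in report.amendments],
        "derived_summaries": [
            _assertion_to_doc(a) for a in report.derived_summaries
        ],
    }


def _result_from_doc(assertion_type: AssertionType, doc: dict):
    status = MeasureStatus(doc["status"]) if assertion_type in (
        AssertionType.MEASURE, AssertionType.VALIDATION
    ) else AmendmentStatus(doc["status"])
    if assertion_type is AssertionType.MEASURE:
        return MeasureResult(
            status=status,
            qualitative=doc.get("qualitative"),
            quantitative=doc.get("quantitative"),
            detail=doc.get("detail", ""),
        )
    if assertion_type is AssertionType.VALIDATION:
        outcome = doc.get("outcome")
        return ValidationResult(
            status=status,
            outcome=ValidationOutcome(outcome) if outcome else None,
            detail=doc.get("detail", ""),
        )
    etype = doc.get("enhancement_type")
    return AmendmentResult(
        status=status,
        proposed_changes=doc.get("proposed_changes", {}),
        rationale=doc.get("rationale", ""),
        replaces_existing=tuple(doc.get("replaces_existing", ())),
        enhancement_type=EnhancementType(etype) if etype else None,
    )


def _assertion_from_doc(doc: dict) -> Assertion:
    assertion_type = AssertionType(doc["assertion_type"])
    res = doc["resource"]
    return Assertion(
        assertion_type=assertion_type,
        element_ref=doc["element"],
        specification_ref=doc["specification"],
        mechanism_ref=doc["mechanism"],
        resource_ref=ResourceRef(
            dataset_id=res["dataset_id"],
            row_id=res.get("row_id"),
            occurrence_id=res.get("occurrence_id"),
        ),
        result=_result_from_doc(assertion_type, doc["result"]),
    )


def report_from_document(doc: dict) -> Report:
    return Report(
        profile_ref=doc["profile"],
        resource_ref=doc["resource"],
        generated_at=doc["generated_at"],
        engine_version=doc["engine_version"],
        measures=[_assertion_from_doc(a) for a in doc.get("measures", [])],
        validations=[_assertion_from_doc(a) for a in doc.get("validations", [])],
        amendments=[_assertion_from_doc(a) for a in doc.get("amendments", [])],
        derived_summaries=[
            _assertion_from_doc(a) for a in doc.get("derived_summaries", [])
        ],
    )


_CSV_COLUMNS = ("assertion_type", "element_id", "specification_id",
                "mechanism_id", "resource_ref", "status", "result", "detail")


def _result_summary(result) -> tuple[str, str, str]:
    """(status, result, detail) for the flat CSV form."""
    if isinstance(result, MeasureResult):
        value = result.qualitative if result.qualitative is not None else (
            "" if result.quantitative is None else repr(result.quantitative)
        )
        return result.status.value, value, result.detail
    if isinstance(result, ValidationResult):
        return (result.status.value,
                result.outcome.value if result.outcome else "", result.detail)
    return (result.status.value,
            json.dumps(dict(result.proposed_changes), sort_keys=True)
            if result.proposed_changes else "",
            result.rationale)


def write_report(report: Report, path: PathLike, format: str = "JSON") -> None:
    """Write a report as loss-free nested JSON or flat one-row-per-assertion CSV."""
    path = Path(path)
    fmt = format.upper()
    if fmt == "JSON":
        path.write_text(
            json.dumps(report_to_document(report), indent=2, sort_keys=True)
            + "\n",
            encoding="utf-8",
        )
    elif fmt == "CSV":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(_CSV_COLUMNS)
            for assertion in (report.measures + report.validations
                              + report.amendments):
                status, value, detail = _result_summary(assertion.result)
                writer.writerow([
                    assertion.assertion_type.value,
                    assertion.element_ref,
                    assertion.specification_ref,
                    assertion.mechanism_ref,
                    str(assertion.resource_ref),
                    status, value, detail,
                ])
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: PathLike) -> Report:
    """Read back a JSON report (the loss-free form)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"{path}: invalid JSON: {exc}") from exc
    return report_from_document(doc)


# ---------------------------------------------------------------------------
# Reference data

def _load_boundaries(path: PathLike, reference: ReferenceData) -> None:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"{path}: invalid GeoJSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise DataFormatError(f"{path}: expected a GeoJSON FeatureCollection")
    for i, feature in enumerate(doc.get("features", [])):
        name = (feature.get("properties") or {}).get("name")
        if not name:
            raise DataFormatError(
                f"{path}: feature [{i}] lacks a 'name' property"
            )
        geom_doc = feature.get("geometry")
        if not geom_doc or geom_doc.get("type") not in {"Polygon", "MultiPolygon"}:
            raise DataFormatError(
                f"{path}: feature {name!r} must be a Polygon or MultiPolygon"
            )
        for ring in _iter_rings(geom_doc):
            distinct = {tuple(pt) for pt in ring}
            if len(distinct) < 3:
                raise DataFormatError(
                    f"{path}: feature {name!r} has a ring with fewer than 3 "
                    "distinct vertices"
                )
            if tuple(ring[0]) != tuple(ring[-1]):
                raise DataFormatError(
                    f"{path}: feature {name!r} has an unclosed ring"
                )
        try:
            geometry: BaseGeometry = shape(geom_doc)
        except (GEOSException, ValueError) as exc:
            raise DataFormatError(
                f"{path}: feature {name!r} has malformed geometry: {exc}"
            ) from exc
        try:
            reference.add_country(name, geometry)
        except ValueError as exc:
            raise DataFormatError(f"{path}: {exc}") from exc


def _iter_rings(geom_doc: dict):
    if geom_doc["type"] == "Polygon":
        yield from geom_doc["coordinates"]
    else:
        for poly in geom_doc["coordinates"]:
            yield from poly


def _load_taxonomy(path: PathLike, reference: ReferenceData) -> None:
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != {
            "name", "rank", "parent"
        }:
            raise DataFormatError(
                f"{path}: taxonomy CSV must have exactly the columns "
                "name,rank,parent"
            )
        for i, row in enumerate(reader, start=2):
            name = (row["name"] or "").strip()
            rank = (row["rank"] or "").strip().lower()
            parent = (row["parent"] or "").strip() or None
            if not name:
                raise DataFormatError(f"{path}: row {i}: empty name")
            if rank not in RANK_ORDER:
                raise DataFormatError(
                    f"{path}: row {i}: rank {rank!r} not in "
                    f"{'/'.join(RANK_ORDER)}"
                )
            reference.taxonomy.setdefault(name, []).append(
                TaxonNode(name=name, rank=rank, parent=parent)
            )
    _check_taxonomy_forest(path, reference)


def _check_taxonomy_forest(path: Path, reference: ReferenceData) -> None:
    """Parent links must form a forest: no cycles, including self-parents."""
    for nodes in reference.taxonomy.values():
        for node in nodes:
            seen = {node.name}
            current = node
            while current.parent is not None:
                if current.parent in seen:
                    raise DataFormatError(
                        f"{path}: taxonomy cycle involving {current.parent!r}"
                    )
                seen.add(current.parent)
                parents = reference.taxonomy.get(current.parent, [])
                if not parents:
                    break
                current = parents[0]


def _load_gazetteer(path: PathLike, reference: ReferenceData) -> None:
    path = Path(path)
    required = {"locality", "decimalLatitude", "decimalLongitude",
                "coordinateUncertaintyInMeters"}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != required:
            raise DataFormatError(
                f"{path}: gazetteer CSV must have exactly the columns "
                + ",".join(sorted(required))
            )
        for i, row in enumerate(reader, start=2):
            try:
                entry = (
                    float(row["decimalLatitude"]),
                    float(row["decimalLongitude"]),
                    float(row["coordinateUncertaintyInMeters"]),
                )
            except (TypeError, ValueError) as exc:
                raise DataFormatError(
                    f"{path}: row {i}: non-numeric coordinate field"
                ) from exc
            reference.gazetteer[normalize_locality(row["locality"])] = entry


def load_reference_data(
    boundaries_path: Optional[PathLike] = None,
    taxonomy_path: Optional[PathLike] = None,
    gazetteer_path: Optional[PathLike] = None,
    names_path: Optional[PathLike] = None,
) -> ReferenceData:
    """Assemble ReferenceData from the optional file set: country boundaries
    (GeoJSON FeatureCollection with a 'name' property per feature), taxonomy
    CSV (name,rank,parent), gazetteer CSV, and one-name-per-line text."""
    reference = ReferenceData()
    if boundaries_path is not None:
        _load_boundaries(boundaries_path, reference)
    if taxonomy_path is not None:
        _load_taxonomy(taxonomy_path, reference)
    if gazetteer_path is not None:
        _load_gazetteer(gazetteer_path, reference)
    if names_path is not None:
        text = Path(names_path).read_text(encoding="utf-8")
        reference.accepted_names = [
            line.strip() for line in text.splitlines() if line.strip()
        ]
    return reference
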