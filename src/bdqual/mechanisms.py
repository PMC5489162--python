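"""Built-in catalogue of measurement, validation and amendment mechanisms.

Covers the canonical occurrence-record checks: coordinate completeness
(record and dataset), coordinate conformity (number / character / range
sub-checks composed into one broad mechanism), point-radius vs. country
boundary consistency, taxon-hierarchy backfill, country recommendation from
coordinates, gazetteer-based coordinate recommendation, and fuzzy
scientific-name suggestion.

Geometry is planar: a degree of latitude is 111,320 m and a degree of
longitude 111,320·cos(latitude) m at the record's latitude.  No geodesic
model and no datum transformation — geodeticDatum participates only in
completeness of the composed coordinates element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import edlib
from shapely import affinity
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .model import (
    AmendmentResult,
    AmendmentStatus,
    Comparator,
    ContextualizedCriterion,
    DataResource,
    InformationElement,
    MeasureResult,
    MeasureStatus,
    ResourceType,
    ValidationOutcome,
    ValidationResult,
    is_missing,
)

METERS_PER_DEGREE = 111_320.0

#: Darwin Core taxon-rank terms from most general to most specific.
RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(RANK_ORDER)}

# Qualitative measure vocabularies.
COMPLETE, NOT_COMPLETE = "COMPLETE", "NOT_COMPLETE"
CONFORMANT, NOT_CONFORMANT = "CONFORMANT", "NOT_CONFORMANT"
CONSISTENT, NOT_CONSISTENT = "CONSISTENT", "NOT_CONSISTENT"


class ConfigurationError(ValueError):
    """Criterion and measure value domains do not match."""


@dataclass(frozen=True)
class TaxonNode:
    name: str
    rank: str
    parent: Optional[str]


@dataclass(frozen=True)
class NameSuggestion:
    candidate: str
    distance: int
    rank_position: int


@dataclass
class ReferenceData:
    """User-supplied lookup data consumed by mechanisms.

    boundaries: case-folded country name -> (display name, geometry)
    taxonomy:   exact name -> list of nodes bearing that name
    gazetteer:  normalized locality -> (lat, lon, uncertainty in meters)
    accepted_names: valid scientific names for suggestion/prevention
    """

    boundaries: dict[str, tuple[str, BaseGeometry]] = field(default_factory=dict)
    taxonomy: dict[str, list[TaxonNode]] = field(default_factory=dict)
    gazetteer: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    accepted_names: list[str] = field(default_factory=list)

    def match_country(self, name: str) -> Optional[tuple[str, BaseGeometry]]:
        """Exact match after case-folding; no fuzzy geography."""
        return self.boundaries.get(name.strip().casefold())

    def add_country(self, name: str, geometry: BaseGeometry) -> None:
        key = name.strip().casefold()
        if key in self.boundaries:
            raise ValueError(f"duplicate country name after case-folding: {name!r}")
        self.boundaries[key] = (name, geometry)

    def lineage(self, node: TaxonNode) -> list[TaxonNode]:
        """Walk parent links from *node* to the root (node first)."""
        chain = [node]
        seen = {node.name}
        current = node
        while current.parent is not None:
            parents = self.taxonomy.get(current.parent, [])
            if not parents:
                break
            current = parents[0]
            if current.name in seen:  # defensive: loader rejects cycles already
                raise ValueError(f"taxonomy cycle at {current.name!r}")
            seen.add(current.name)
            chain.append(current)
        return chain


def normalize_locality(text: str) -> str:
    """Case-fold and collapse internal whitespace for gazetteer lookup."""
    return re.sub(r"\s+", " ", text.strip()).casefold()


# ---------------------------------------------------------------------------
# Coordinate value sub-checks (SPECIFIC mechanisms, reused by the broad
# conformity mechanism).

#: Strict decimal-degree dialect: optional sign, digits, at most one dot.
_VALID_CHARS_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)$")


def check_is_number(value: str) -> bool:
    """Can the text be read as a plain decimal number?"""
    try:
        float(value)
    except (TypeError, ValueError):
        return False
    # float() admits inf/nan spellings; those are not decimal numbers here.
    return value.strip().lower() not in {"inf", "+inf", "-inf", "infinity", "nan"}


def check_valid_characters(value: str) -> bool:
    """No commas, letters or exponent notation; one optional dot and sign."""
    return bool(_VALID_CHARS_RE.match(value.strip()))


def check_latitude_range(value: str) -> bool:
    """Latitude in [-90, 90], both bounds inclusive."""
    if not check_is_number(value):
        return False
    return -90.0 <= float(value) <= 90.0


def check_longitude_range(value: str) -> bool:
    """Longitude in [-180, 180], both bounds inclusive."""
    if not check_is_number(value):
        return False
    return -180.0 <= float(value) <= 180.0


def parse_coordinate(value: object) -> Optional[float]:
    """Strictly parse a coordinate value; None when missing or malformed."""
    if is_missing(value) or not isinstance(value, str):
        return None
    if not check_valid_characters(value):
        return None
    return float(value)


# ---------------------------------------------------------------------------
# Measures

def measure_completeness_record(
    record: Mapping[str, str], ie: InformationElement
) -> MeasureResult:
    """COMPLETE iff every term of the information element has a value."""
    missing = [t for t in ie.terms if is_missing(record.get(t))]
    if missing:
        return MeasureResult(
            status=MeasureStatus.COMPLETED,
            qualitative=NOT_COMPLETE,
            detail="missing: " + ", ".join(missing),
        )
    return MeasureResult(status=MeasureStatus.COMPLETED, qualitative=COMPLETE)


def measure_completeness_dataset(
    dataset: DataResource, ie: InformationElement
) -> MeasureResult:
    """Proportion of records complete for the information element.

    Counted in exact rational arithmetic before the final float conversion.
    Empty dataset -> PREREQUISITES_NOT_MET.
    """
    if dataset.resource_type is not ResourceType.DATASET:
        raise ValueError("dataset-level completeness requires a DATASET resource")
    n = dataset.n_records
    if n == 0:
        return MeasureResult(
            status=MeasureStatus.PREREQUISITES_NOT_MET, detail="empty dataset"
        )
    k = sum(
        1
        for _, rec in dataset.iter_rows()
        if measure_completeness_record(rec, ie).qualitative == COMPLETE
    )
    frac = Fraction(k, n)
    return MeasureResult(
        status=MeasureStatus.COMPLETED,
        quantitative=float(frac),
        detail=f"{k}/{n} records complete",
    )


def measure_coordinate_conformity_record(
    record: Mapping[str, str],
    lat_term: str = "decimalLatitude",
    lon_term: str = "decimalLongitude",
) -> MeasureResult:
    """CONFORMANT iff four sub-checks pass on the latitude/longitude pair:
    each value is a number, each value has only valid characters, latitude
    is in [-90, 90] and longitude is in [-180, 180].

    Either coordinate missing -> PREREQUISITES_NOT_MET.
    """
    lat = record.get(lat_term)
    lon = record.get(lon_term)
    missing = [t for t, v in ((lat_term, lat), (lon_term, lon)) if is_missing(v)]
    if missing:
        return MeasureResult(
            status=MeasureStatus.PREREQUISITES_NOT_MET,
            detail="missing coordinate term(s): " + ", ".join(missing),
        )
    checks = {
        "is-number": check_is_number(lat) and check_is_number(lon),
        "valid-characters": check_valid_characters(lat) and check_valid_characters(lon),
        "latitude-range": check_latitude_range(lat),
        "longitude-range": check_longitude_range(lon),
    }
    detail = "; ".join(f"{k}={'pass' if v else 'fail'}" for k, v in checks.items())
    qualitative = CONFORMANT if all(checks.values()) else NOT_CONFORMANT
    return MeasureResult(
        status=MeasureStatus.COMPLETED, qualitative=qualitative, detail=detail
    )


def _planar_distance_m(lat: float, lon: float, geometry: BaseGeometry) -> float:
    """Planar distance in meters from (lat, lon) to the geometry boundary,
    under the local equirectangular approximation evaluated at *lat*."""
    import math

    kx = METERS_PER_DEGREE * math.cos(math.radians(lat))
    ky = METERS_PER_DEGREE
    # Affine map degrees -> local meters centred on the point.
    flat = affinity.affine_transform(
        geometry, [kx, 0.0, 0.0, ky, -lon * kx, -lat * ky]
    )
    return Point(0.0, 0.0).distance(flat)


def measure_coordinate_consistency_record(
    record: Mapping[str, str],
    reference: ReferenceData,
    lat_term: str = "decimalLatitude",
    lon_term: str = "decimalLongitude",
    uncertainty_term: str = "coordinateUncertaintyInMeters",
    country_term: str = "country",
) -> MeasureResult:
    """Point-radius vs. country test: CONSISTENT iff the circle around the
    coordinate, with radius equal to the coordinate uncertainty in meters,
    intersects the named country's boundary polygon set (tangency counts).

    Prerequisites: latitude/longitude parse as in-range numbers and the
    country name matches the reference boundaries (case-insensitive);
    otherwise PREREQUISITES_NOT_MET naming the unmet prerequisite.  A
    missing or unparseable uncertainty is treated as 0 m (pure point test),
    with the substitution noted in the detail.
    """
    lat_raw, lon_raw = record.get(lat_term), record.get(lon_term)
    for term, raw in ((lat_term, lat_raw), (lon_term, lon_raw)):
        if is_missing(raw):
            return MeasureResult(
                status=MeasureStatus.PREREQUISITES_NOT_MET,
                detail=f"missing {term}",
            )
    lat, lon = parse_coordinate(lat_raw), parse_coordinate(lon_raw)
    if lat is None or lon is None or not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
        return MeasureResult(
            status=MeasureStatus.PREREQUISITES_NOT_MET,
            detail="coordinates not parseable as in-range decimal degrees",
        )
    country_raw = record.get(country_term)
    if is_missing(country_raw):
        return MeasureResult(
            status=MeasureStatus.PREREQUISITES_NOT_MET,
            detail=f"missing {country_term}",
        )
    match = reference.match_country(country_raw)
    if match is None:
        return MeasureResult(
            status=MeasureStatus.PREREQUISITES_NOT_MET,
            detail=f"unknown country name {country_raw.strip()!r}",
        )
    name, geometry = match

    notes = []
    unc_raw = record.get(uncertainty_term)
    uncertainty = None
    if not is_missing(unc_raw):
        try:
            uncertainty = float(unc_raw)
        except (TypeError, ValueError):
            uncertainty = None
    if uncertainty is None or uncertainty < 0:
        uncertainty = 0.0
        notes.append("uncertainty missing/unparseable; using 0 m (point test)")

    point = Point(lon, lat)
    if geometry.covers(point):
        detail = f"point inside {name}"
    else:
        dist = _planar_distance_m(lat, lon, geometry)
        if dist <= uncertainty:
            detail = f"point {dist:.1f} m outside {name}, within {uncertainty:g} m radius"
        else:
            notes.append(
                f"point {dist:.1f} m outside {name}, beyond {uncertainty:g} m radius"
            )
            return MeasureResult(
                status=MeasureStatus.COMPLETED,
                qualitative=NOT_CONSISTENT,
                detail="; ".join(notes),
            )
    return MeasureResult(
        status=MeasureStatus.COMPLETED,
        qualitative=CONSISTENT,
        detail="; ".join([detail] + notes),
    )


# ---------------------------------------------------------------------------
# Validation

_COMPARATORS = {
    Comparator.EQ: lambda a, b: a == b,
    Comparator.GE: lambda a, b: a >= b,
    Comparator.LE: lambda a, b: a <= b,
    Comparator.GT: lambda a, b: a > b,
    Comparator.LT: lambda a, b: a < b,
}


def validate_against_criterion(
    measure: MeasureResult, criterion: ContextualizedCriterion
) -> ValidationResult:
    """Judge a measure against a criterion.

    Quantitative measures are compared with the criterion's comparator and
    numeric threshold; qualitative measures must equal the required value
    (EQ only).  A measure with unmet prerequisites propagates to a
    validation with unmet prerequisites.
    """
    if measure.status is MeasureStatus.PREREQUISITES_NOT_MET:
        return ValidationResult(
            status=MeasureStatus.PREREQUISITES_NOT_MET,
            detail="underlying measure has unmet prerequisites",
        )
    if measure.quantitative is not None:
        if not isinstance(criterion.threshold, (int, float)) or isinstance(
            criterion.threshold, bool
        ):
            raise ConfigurationError(
                f"criterion {criterion.id!r}: quantitative measure needs a numeric threshold"
            )
        ok = _COMPARATORS[criterion.comparator](
            float(measure.quantitative), float(criterion.threshold)
        )
    else:
        if not isinstance(criterion.threshold, str):
            raise ConfigurationError(
                f"criterion {criterion.id!r}: qualitative measure needs a required value"
            )
        if criterion.comparator is not Comparator.EQ:
            raise ConfigurationError(
                f"criterion {criterion.id!r}: qualitative measures support only EQ"
            )
        ok = measure.qualitative == criterion.threshold
    return ValidationResult(
        status=MeasureStatus.COMPLETED,
        outcome=ValidationOutcome.COMPLIANT if ok else ValidationOutcome.NOT_COMPLIANT,
    )


# ---------------------------------------------------------------------------
# Amendments (always pure: the input record is never modified)

def amend_fill_taxon_hierarchy(
    record: Mapping[str, str], reference: ReferenceData
) -> AmendmentResult:
    """Fill blank higher taxon ranks from the most specific resolvable name.

    The most specific provided name (searching species up to kingdom, then
    scientificName) is resolved in the reference taxonomy and its lineage
    walked upward.  Only blank fields receive proposals; a filled field that
    conflicts with the derived lineage is left alone and the conflict is
    reported in the rationale.
    """
    anchor: Optional[TaxonNode] = None
    anchor_term = None
    candidates = [(t, record.get(t)) for t in reversed(RANK_ORDER)]
    candidates.append(("scientificName", record.get("scientificName")))
    for term, value in candidates:
        if is_missing(value):
            continue
        nodes = reference.taxonomy.get(value.strip(), [])
        if len(nodes) > 1:
            return AmendmentResult(
                status=AmendmentStatus.PREREQUISITES_NOT_MET,
                rationale=f"ambiguous name: {value.strip()!r} occurs at multiple taxonomy nodes",
            )
        if len(nodes) == 1:
            anchor, anchor_term = nodes[0], term
            break
    if anchor is None:
        return AmendmentResult(
            status=AmendmentStatus.PREREQUISITES_NOT_MET,
            rationale="no provided taxon name resolvable in the reference taxonomy",
        )

    lineage = {node.rank: node.name for node in reference.lineage(anchor)}
    proposals: dict[str, str] = {}
    conflicts: list[str] = []
    anchor_idx = _RANK_INDEX.get(anchor.rank, len(RANK_ORDER))
    for rank in RANK_ORDER[:anchor_idx]:
        expected = lineage.get(rank)
        if expected is None:
            continue
        current = record.get(rank)
        if is_missing(current):
            proposals[rank] = expected
        elif current.strip() != expected:
            conflicts.append(
                f"{rank}={current.strip()!r} conflicts with lineage value {expected!r}"
            )
    rationale = f"lineage derived from {anchor_term}={anchor.name!r}"
    if conflicts:
        rationale += "; " + "; ".join(conflicts)
    if not proposals:
        return AmendmentResult(
            status=AmendmentStatus.NOT_PROPOSED,
            rationale=rationale + "; no blank rank to fill",
        )
    return AmendmentResult(
        status=AmendmentStatus.PROPOSED,
        proposed_changes=proposals,
        rationale=rationale,
    )


def amend_country_from_coordinates(
    record: Mapping[str, str],
    reference: ReferenceData,
    lat_term: str = "decimalLatitude",
    lon_term: str = "decimalLongitude",
    country_term: str = "country",
) -> AmendmentResult:
    """Recommend a country name from the coordinates.

    If the point falls inside exactly one country's polygon set the name is
    proposed when the country field is blank, or proposed as a replacement
    (flagged via ``replaces_existing``) when filled with a different name.
    """
    lat = parse_coordinate(record.get(lat_term))
    lon = parse_coordinate(record.get(lon_term))
    if lat is None or lon is None or not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
        return AmendmentResult(
            status=AmendmentStatus.PREREQUISITES_NOT_MET,
            rationale="coordinates missing or not in-range decimal degrees",
        )
    point = Point(lon, lat)
    containing = [
        display
        for display, geometry in reference.boundaries.values()
        if geometry.covers(point)
    ]
    if not containing:
        return AmendmentResult(
            status=AmendmentStatus.NOT_PROPOSED, rationale="no containing boundary"
        )
    if len(containing) > 1:
        return AmendmentResult(
            status=AmendmentStatus.NOT_PROPOSED,
            rationale="ambiguous containment: " + ", ".join(sorted(containing)),
        )
    name = containing[0]
    current = record.get(country_term)
    if is_missing(current):
        return AmendmentResult(
            status=AmendmentStatus.PROPOSED,
            proposed_changes={country_term: name},
            rationale=f"point ({lat}, {lon}) lies inside {name}",
        )
    if current.strip().casefold() == name.casefold():
        return AmendmentResult(
            status=AmendmentStatus.NOT_PROPOSED,
            rationale=f"country already consistent with containing boundary {name}",
        )
    return AmendmentResult(
        status=AmendmentStatus.PROPOSED,
        proposed_changes={country_term: name},
        replaces_existing=(country_term,),
        rationale=(
            f"recommended replacement: point lies inside {name} "
            f"but country is {current.strip()!r}"
        ),
    )


def amend_coordinates_from_locality(
    record: Mapping[str, str],
    reference: ReferenceData,
    locality_term: str = "locality",
    lat_term: str = "decimalLatitude",
    lon_term: str = "decimalLongitude",
    uncertainty_term: str = "coordinateUncertaintyInMeters",
) -> AmendmentResult:
    """Recommend coordinates by exact gazetteer lookup of the locality.

    The locality string is matched after case-folding and whitespace
    collapsing; there is no free-text georeferencing.
    """
    locality = record.get(locality_term)
    if is_missing(locality):
        return AmendmentResult(
            status=AmendmentStatus.PREREQUISITES_NOT_MET,
            rationale="locality missing",
        )
    if not reference.gazetteer:
        return AmendmentResult(
            status=AmendmentStatus.PREREQUISITES_NOT_MET,
            rationale="no gazetteer loaded",
        )
    lat_blank = is_missing(record.get(lat_term))
    lon_blank = is_missing(record.get(lon_term))
    if not (lat_blank or lon_blank):
        return AmendmentResult(
            status=AmendmentStatus.NOT_PROPOSED,
            rationale="coordinates already populated",
        )
    entry = reference.gazetteer.get(normalize_locality(locality))
    if entry is None:
        return AmendmentResult(
            status=AmendmentStatus.NOT_PROPOSED,
            rationale=f"locality {locality.strip()!r} not found in gazetteer",
        )
    lat, lon, unc = entry
    return AmendmentResult(
        status=AmendmentStatus.PROPOSED,
        proposed_changes={
            lat_term: repr(lat) if isinstance(lat, float) else str(lat),
            lon_term: repr(lon) if isinstance(lon, float) else str(lon),
            uncertainty_term: f"{unc:g}",
        },
        rationale=f"exact gazetteer match for {locality.strip()!r}",
    )


def suggest_scientific_names(
    value: str,
    reference: ReferenceData,
    max_distance: int = 2,
    limit: int = 5,
) -> list[NameSuggestion]:
    """All accepted names within Levenshtein distance *max_distance* of
    *value*, sorted by (distance, name), truncated to *limit*.

    An exact match yields distance 0 at rank 1.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    hits: list[tuple[int, str]] = []
    for name in reference.accepted_names:
        res = edlib.align(value, name, task="distance", k=max_distance)
        d = res["editDistance"]
        if d != -1:
            hits.append((d, name))
    hits.sort()
    return [
        NameSuggestion(candidate=name, distance=d, rank_position=i + 1)
        for i, (d, name) in enumerate(hits[:limit])
    ]


def suggest_name_amendment(
    record: Mapping[str, str],
    reference: ReferenceData,
    max_distance: int = 2,
    limit: int = 5,
    name_term: str = "scientificName",
) -> AmendmentResult:
    """Prevention-style advisory: list similar accepted names for a
    scientific name that is not itself accepted.  Never proposes a change —
    prevention suggestions are for data-entry support only."""
    value = record.get(name_term)
    if is_missing(value):
        return AmendmentResult(
            status=AmendmentStatus.PREREQUISITES_NOT_MET,
            rationale=f"missing {name_term}",
        )
    value = value.strip()
    if value in reference.accepted_names:
        return AmendmentResult(
            status=AmendmentStatus.NOT_PROPOSED,
            rationale=f"{value!r} is an accepted name",
        )
    suggestions = suggest_scientific_names(value, reference, max_distance, limit)
    if not suggestions:
        return AmendmentResult(
            status=AmendmentStatus.NOT_PROPOSED,
            rationale=f"no accepted name within distance {max_distance} of {value!r}",
        )
    listing = ", ".join(f"{s.candidate} (d={s.distance})" for s in suggestions)
    return AmendmentResult(
        status=AmendmentStatus.NOT_PROPOSED,
        rationale=f"suggestions for {value!r}: {listing}",
    )


def aggregate_record_outcomes(
    outcomes: Sequence[MeasureResult], positive_value: str
) -> MeasureResult:
    """Dataset-level proportion of record outcomes equal to *positive_value*.

    Record-level results with unmet prerequisites count as not positive
    (unassessable records are not demonstrably fit).  Empty input ->
    PREREQUISITES_NOT_MET.  Exact rational arithmetic before float.
    """
    n = len(outcomes)
    if n == 0:
        return MeasureResult(
            status=MeasureStatus.PREREQUISITES_NOT_MET, detail="no record outcomes"
        )
    k = sum(
        1
        for m in outcomes
        if m.status is MeasureStatus.COMPLETED and m.qualitative == positive_value
    )
    return MeasureResult(
        status=MeasureStatus.COMPLETED,
        quantitative=float(Fraction(k, n)),
        detail=f"{k}/{n} records {positive_value}",
    )
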