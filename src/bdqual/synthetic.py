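"""Deterministic synthetic occurrence data with known quality defects.

The generator emits Darwin Core occurrence records placed strictly inside
toy countries, then injects defects — missing coordinates, non-numeric
coordinates, out-of-range coordinates, wrong country labels, blanked taxon
ranks, misspelled scientific names — at user-set per-record rates, and
records per-record ground-truth flags computed *by construction*, not by
running the mechanisms under test.  Identical (n, rates, seed) calls give
byte-identical output.

Coordinate defects follow a fixed precedence (missing > non-numeric >
out-of-range > wrong-country) so at most one coordinate defect applies per
record and the ground-truth classes are disjoint.  Taxon-rank blanking and
name misspelling are independent of the coordinate defects.

A coarse Brazil polygon is included so the classic point-radius worked
example (a coordinate in the South Atlantic labelled "Brazil") evaluates to
NOT_CONSISTENT against realistic reference data.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Union

from shapely.geometry import Polygon, mapping

from .mechanisms import RANK_ORDER, ReferenceData, TaxonNode, normalize_locality
from .model import DataResource, ResourceType

PathLike = Union[str, Path]

# Toy countries: convex squares >=10 degrees apart, so a wrong-country label
# is always inconsistent at sub-kilometre uncertainty radii.
_TOY_COUNTRIES = {
    "Atlantis": (0.0, 0.0, 10.0, 10.0),     # (lon_min, lat_min, lon_max, lat_max)
    "Lemuria": (20.0, 0.0, 30.0, 10.0),
    "Mu": (40.0, 0.0, 50.0, 10.0),
}

# Coarse Brazil outline (lon, lat), counter-clockwise, good to ~1 degree.
_BRAZIL_OUTLINE = [
    (-51.7, 4.2), (-60.0, 5.2), (-69.9, -4.2), (-73.9, -7.3), (-70.5, -9.4),
    (-65.3, -10.7), (-61.0, -15.0), (-58.0, -20.0), (-57.6, -22.2),
    (-55.0, -24.0), (-53.9, -25.6), (-57.6, -30.2), (-53.6, -33.7),
    (-48.0, -25.5), (-40.9, -22.0), (-39.0, -17.5), (-37.1, -11.0),
    (-34.8, -7.5), (-44.0, -2.8), (-50.0, 0.0),
]

_LINEAGES = [
    ["Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Apidae",
     "Tetragonisca", "Tetragonisca angustula"],
    ["Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Apidae",
     "Apis", "Apis mellifera"],
    ["Plantae", "Tracheophyta", "Magnoliopsida", "Fabales", "Fabaceae",
     "Mimosa", "Mimosa pudica"],
]

_GENERA = ["Tetragonisca", "Apis", "Mimosa", "Melipona", "Bombus",
           "Trigona", "Euglossa", "Centris", "Xylocopa", "Paspalum"]
_EPITHETS = ["angustula", "mellifera", "pudica", "quadrifasciata",
             "terrestris", "spinipes"]

_GAZETTEER = [
    # (display locality, country, offsets into the country square)
    ("Campinas, SP", "Atlantis", 2.1, 3.4),
    ("Porto Real", "Atlantis", 4.7, 1.9),
    ("Nova Lima", "Atlantis", 6.3, 7.2),
    ("Vila Flor", "Atlantis", 8.2, 5.5),
    ("Alto Verde", "Atlantis", 1.4, 8.8),
    ("Santa Clara", "Atlantis", 5.5, 5.1),
    ("Ponta Azul", "Atlantis", 3.8, 6.6),
    ("Lagoa Seca", "Lemuria", 2.9, 2.2),
    ("Monte Sol", "Lemuria", 5.0, 4.8),
    ("Rio Claro", "Lemuria", 7.6, 6.9),
    ("Serra Alta", "Lemuria", 1.8, 8.1),
    ("Campo Largo", "Lemuria", 6.4, 1.5),
    ("Boa Vista do Sul", "Lemuria", 8.8, 8.6),
    ("Pedra Branca", "Lemuria", 4.2, 7.4),
    ("Ilha Verde", "Mu", 2.5, 5.9),
    ("Morro Alto", "Mu", 5.7, 2.7),
    ("Baia Funda", "Mu", 7.1, 7.8),
    ("Costa Nova", "Mu", 8.5, 4.1),
    ("Vale Fundo", "Mu", 1.2, 1.3),
    ("Praia Longa", "Mu", 6.8, 9.0),
]

_DATUMS = ["WGS84", "SIRGAS2000"]


class InvalidRatesError(ValueError):
    """A defect rate falls outside [0, 1]."""


@dataclass(frozen=True)
class DefectRates:
    """Per-record probabilities for each injected defect class."""

    p_missing_coord: float = 0.0
    p_nonnumeric_coord: float = 0.0
    p_out_of_range: float = 0.0
    p_wrong_country: float = 0.0
    p_missing_taxon_ranks: float = 0.0
    p_misspelled_name: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not 0.0 <= float(value) <= 1.0:
                raise InvalidRatesError(f"{f.name}={value} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruthRow:
    """By-construction quality flags for one generated record."""

    row_id: int
    coord_complete: bool
    coord_conformant: bool
    coord_consistent: bool
    taxon_complete: bool
    name_exact: bool


@dataclass
class GroundTruth:
    """Per-record flags plus exact realized counts per dataset."""

    rows: list[GroundTruthRow] = field(default_factory=list)

    def count(self, flag: str) -> int:
        return sum(1 for r in self.rows if getattr(r, flag))

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def coord_complete_count(self) -> int:
        return self.count("coord_complete")

    @property
    def coord_conformant_count(self) -> int:
        return self.count("coord_conformant")

    @property
    def coord_consistent_count(self) -> int:
        return self.count("coord_consistent")

    @property
    def taxon_complete_count(self) -> int:
        return self.count("taxon_complete")

    @property
    def name_exact_count(self) -> int:
        return self.count("name_exact")


def accepted_name_list() -> list[str]:
    """Fifty deterministic accepted binomials, including the three species
    carried by the fixture taxonomy."""
    names = []
    for genus in _GENERA:
        for epithet in _EPITHETS:
            names.append(f"{genus} {epithet}")
            if len(names) == 50:
                return names
    return names


def generate_reference_fixtures(seed: int = 0) -> ReferenceData:
    """Toy reference data: three convex toy countries plus a coarse Brazil
    polygon, a three-lineage taxonomy, a 20-entry gazetteer whose points lie
    inside their toy countries, and a 50-name accepted list.

    The content is fixed by design; *seed* is accepted for interface
    symmetry with the dataset generator and does not alter the fixtures.
    """
    del seed  # fixtures are deliberately constant
    reference = ReferenceData()
    for name, (lon0, lat0, lon1, lat1) in _TOY_COUNTRIES.items():
        reference.add_country(
            name,
            Polygon([(lon0, lat0), (lon1, lat0), (lon1, lat1), (lon0, lat1)]),
        )
    reference.add_country("Brazil", Polygon(_BRAZIL_OUTLINE))

    for lineage in _LINEAGES:
        parent = None
        for rank, name in zip(RANK_ORDER, lineage):
            nodes = reference.taxonomy.setdefault(name, [])
            if not any(n.rank == rank and n.parent == parent for n in nodes):
                nodes.append(TaxonNode(name=name, rank=rank, parent=parent))
            parent = name

    for display, country, dx, dy in _GAZETTEER:
        lon0, lat0, _, _ = _TOY_COUNTRIES[country]
        reference.gazetteer[normalize_locality(display)] = (
            lat0 + dy, lon0 + dx, 250.0
        )

    reference.accepted_names = accepted_name_list()
    return reference


def gazetteer_display_entries() -> list[tuple[str, str, float, float]]:
    """(display locality, country, lat, lon) for each fixture gazetteer entry."""
    out = []
    for display, country, dx, dy in _GAZETTEER:
        lon0, lat0, _, _ = _TOY_COUNTRIES[country]
        out.append((display, country, lat0 + dy, lon0 + dx))
    return out


def _misspell(name: str, rng: random.Random) -> str:
    """Substitute one interior letter with a different one."""
    idx = rng.randrange(1, len(name) - 1)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    old = name[idx]
    choices = [c for c in alphabet if c != old.lower()]
    new = rng.choice(choices)
    return name[:idx] + new + name[idx + 1:]


def generate_dataset(
    n: int,
    rates: DefectRates,
    seed: int,
    resource_id: str = "synthetic",
) -> tuple[DataResource, GroundTruth]:
    """Generate *n* occurrence records with defects injected per *rates*.

    Clean records sit strictly inside a toy country (0.5-degree margin) with
    uncertainty 10-1000 m, full taxon lineage and an accepted name, so every
    ground-truth flag is positive before defects.  One seeded stream is
    consumed in fixed field order for cross-platform reproducibility.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    country_names = list(_TOY_COUNTRIES)
    records: list[dict[str, str]] = []
    truth = GroundTruth()

    for i in range(n):
        c_idx = rng.randrange(len(country_names))
        country = country_names[c_idx]
        lon0, lat0, lon1, lat1 = _TOY_COUNTRIES[country]
        lat = round(rng.uniform(lat0 + 0.5, lat1 - 0.5), 6)
        lon = round(rng.uniform(lon0 + 0.5, lon1 - 0.5), 6)
        unc = rng.randrange(10, 1001)
        datum = _DATUMS[rng.randrange(len(_DATUMS))]
        lineage = _LINEAGES[rng.randrange(len(_LINEAGES))]
        year = rng.randrange(2000, 2021)
        month = rng.randrange(1, 13)
        day = rng.randrange(1, 29)
        g_idx = rng.randrange(len(_GAZETTEER))
        locality = _GAZETTEER[g_idx][0]

        record = {
            "occurrenceID": f"occ-{i:06d}",
            "scientificName": lineage[-1],
            **{rank: name for rank, name in zip(RANK_ORDER, lineage)},
            "decimalLatitude": f"{lat:.6f}",
            "decimalLongitude": f"{lon:.6f}",
            "coordinateUncertaintyInMeters": str(unc),
            "geodeticDatum": datum,
            "country": country,
            "locality": locality,
            "eventDate": f"{year:04d}-{month:02d}-{day:02d}",
        }

        # Defect draws, always consumed in fixed order.
        u_missing = rng.random()
        u_nonnum = rng.random()
        u_oor = rng.random()
        u_wrong = rng.random()
        u_taxon = rng.random()
        u_name = rng.random()
        wrong_choice = rng.randrange(len(country_names) - 1)
        oor_axis = rng.randrange(2)
        miss_idx = rng.randrange(1, len(lineage) - 1)  # pre-draw for _misspell
        alphabet_idx = rng.randrange(25)

        missing = u_missing < rates.p_missing_coord
        nonnumeric = (not missing) and u_nonnum < rates.p_nonnumeric_coord
        out_of_range = (not missing and not nonnumeric) and u_oor < rates.p_out_of_range
        wrong_country = (
            not missing and not nonnumeric and not out_of_range
        ) and u_wrong < rates.p_wrong_country
        taxon_blanked = u_taxon < rates.p_missing_taxon_ranks
        misspelled = u_name < rates.p_misspelled_name

        if missing:
            record["decimalLatitude"] = ""
        elif nonnumeric:
            record["decimalLatitude"] = record["decimalLatitude"].replace(".", ",")
        elif out_of_range:
            if oor_axis == 0:
                record["decimalLatitude"] = "95.500000"
            else:
                record["decimalLongitude"] = "200.500000"
        elif wrong_country:
            others = [c for c in country_names if c != country]
            record["country"] = others[wrong_choice % len(others)]

        if taxon_blanked:
            record["genus"] = ""
            record["family"] = ""

        if misspelled:
            name = record["scientificName"]
            idx = 1 + (miss_idx % (len(name) - 2))
            old = name[idx]
            choices = [c for c in "abcdefghijklmnopqrstuvwxyz" if c != old.lower()]
            record["scientificName"] = (
                name[:idx] + choices[alphabet_idx % len(choices)] + name[idx + 1:]
            )

        records.append(record)
        truth.rows.append(
            GroundTruthRow(
                row_id=i,
                coord_complete=not missing,
                coord_conformant=not (missing or nonnumeric or out_of_range),
                coord_consistent=not (
                    missing or nonnumeric or out_of_range or wrong_country
                ),
                taxon_complete=not taxon_blanked,
                name_exact=not misspelled,
            )
        )

    resource = DataResource(
        resource_type=ResourceType.DATASET,
        records=records,
        resource_id=resource_id,
    )
    return resource, truth


# ---------------------------------------------------------------------------
# Fixture writers (plain-text formats only)

def write_reference_fixtures(reference: ReferenceData, out_dir: PathLike) -> dict:
    """Write boundaries.geojson, taxonomy.csv, gazetteer.csv and
    accepted_names.txt under *out_dir*; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    features = []
    for display, geometry in reference.boundaries.values():
        features.append({
            "type": "Feature",
            "properties": {"name": display},
            "geometry": mapping(geometry),
        })
    boundaries = out / "boundaries.geojson"
    boundaries.write_text(
        json.dumps({"type": "FeatureCollection", "features": features},
                   indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )

    taxonomy = out / "taxonomy.csv"
    with taxonomy.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["name", "rank", "parent"])
        rows = [
            (node.name, node.rank, node.parent or "")
            for nodes in reference.taxonomy.values()
            for node in nodes
        ]
        for row in sorted(set(rows), key=lambda r: (RANK_ORDER.index(r[1]), r[0])):
            writer.writerow(row)

    gazetteer = out / "gazetteer.csv"
    with gazetteer.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["locality", "decimalLatitude", "decimalLongitude",
                         "coordinateUncertaintyInMeters"])
        for locality, (lat, lon, unc) in sorted(reference.gazetteer.items()):
            writer.writerow([locality, f"{lat:.6f}", f"{lon:.6f}", f"{unc:g}"])

    names = out / "accepted_names.txt"
    names.write_text("\n".join(reference.accepted_names) + "\n", encoding="utf-8")
    return {
        "boundaries": boundaries, "taxonomy": taxonomy,
        "gazetteer": gazetteer, "names": names,
    }


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    path = Path(path)
    flags = ["coord_complete", "coord_conformant", "coord_consistent",
             "taxon_complete", "name_exact"]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["row_id"] + flags)
        for row in truth.rows:
            writer.writerow(
                [row.row_id] + [int(getattr(row, f)) for f in flags]
            )
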