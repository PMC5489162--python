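# bdqual

Fitness-for-use quality assessment and management for Darwin Core
occurrence data.

Biodiversity aggregators serve hundreds of millions of occurrence records
of very uneven quality, and whether a record is "good enough" depends
entirely on what you want to do with it: a coordinate rounded to a degree
may be fine for a country checklist and useless for a species distribution
model.  `bdqual` makes that judgement executable.  You declare a **data
quality profile** — a use case, the information elements that matter to
it, and measurement / validation / enhancement policies — and the engine
evaluates records and datasets against it, producing a **DQ status
report** of assertions:

- **Measures** — per dimension in context: qualitative for single records
  (`COMPLETE`, `CONFORMANT`, `CONSISTENT`, …), a proportion in [0, 1] for
  datasets;
- **Validations** — `COMPLIANT` / `NOT_COMPLIANT` judgements of measures
  against criteria such as *coordinate completeness of a dataset must
  equal 100%*;
- **Amendments** — *proposed* changes (taxon-hierarchy backfill, country
  from coordinates, coordinates from a gazetteer locality), never silent
  edits: acceptance is a curator decision.

Every assertion carries five components — element in context,
specification, mechanism, data resource, result — so reports from
different tools and datasets stay comparable.  On top of the report sit
the two management modes: *assurance* (`filter`: keep only records
compliant with every record-level criterion) and *control* (`amend`:
apply accepted proposals to a copy, with a changelog).

The built-in mechanism catalogue covers coordinate completeness,
conformity (number / character / inclusive range sub-checks composed into
one broad mechanism), point-radius vs. country-boundary consistency under
a planar metric, taxon backfill, country and coordinate recommendations,
and fuzzy accepted-name suggestion.  A deterministic synthetic-data module
generates occurrence datasets with seeded defect rates and by-construction
ground truth, so every property of the engine is testable offline.

## Worked example

The classic point-radius consistency check: a record at
decimalLatitude −35.3848, decimalLongitude 13.8352 (South Atlantic, off
Namibia), uncertainty 100 m, labelled country "Brazil".

```python
from bdqual import (default_registry, generate_reference_fixtures,
                    measure_coordinate_consistency_record)

reference = generate_reference_fixtures(0)
record = {
    "decimalLatitude": "-35.3848", "decimalLongitude": "13.8352",
    "coordinateUncertaintyInMeters": "100",
    "geodeticDatum": "SIRGAS2000", "country": "Brazil",
}
result = measure_coordinate_consistency_record(record, reference)
print(result.status.value, result.qualitative)
print(result.detail)
```

prints

```
COMPLETED NOT_CONSISTENT
point 5182080.6 m outside Brazil, beyond 100 m radius
```

— the point is ~5 182 km outside the Brazil boundary, far beyond the
100 m uncertainty radius, so the coordinate is not consistent with the
stated country and a distribution model for a Brazilian bee should not
ingest it as-is.

The full pipeline from the shell, using the bundled
`examples/coordinates-completeness.yaml` profile (one composed coordinates
element, record- and dataset-level completeness dimensions, and the
"must equal 100%" criterion):

```bash
bdqual synth --n 100 --seed 1 --out-dir work/        # synthetic data + fixtures
bdqual report examples/coordinates-completeness.yaml work/occurrences.csv \
    --boundaries work/boundaries.geojson --out work/report.json
```

prints (to standard error)

```
n=100 complete=100 conformant=100 consistent=100
measures[101]: COMPLETED=101 | validations[1]: COMPLIANT=1 | amendments[0]: none
```

— 100 record-level completeness measures plus one dataset roll-up, and the
dataset criterion is COMPLIANT because no defects were injected.  The
`filter` and `amend` subcommands take the same arguments plus
`--out`/`--log` and `--policy`/`--changelog` respectively; the JSON report
nests every assertion with all five components spelled out by id.

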