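# Methods

## The model

`bdqual` implements fitness-for-use quality assessment for biodiversity
occurrence data.  Quality is never absolute: it is defined relative to a
**use case** (e.g. building a species distribution model for the stingless
bee *Tetragonisca angustula*).  A **profile** makes that definition
executable with five parts:

1. the use case (a data-use story and its purpose);
2. the **valuable information elements** (IEs) — named single fields or
   composed field sets, such as "coordinates" = decimalLatitude +
   decimalLongitude + coordinateUncertaintyInMeters + geodeticDatum;
3. a **measurement policy**: quality dimensions (completeness, conformity,
   consistency, …) contextualized by an IE and a resource type.
   Single-record dimensions yield qualitative outcomes (COMPLETE /
   NOT_COMPLETE, …); dataset dimensions yield a proportion in [0, 1];
4. a **validation policy**: criteria that turn measures into pass/fail
   judgements (e.g. "coordinate completeness of a dataset must be equal to
   100%" ⇔ comparator EQ, threshold 1.0);
5. an **enhancement policy**: improvement activities of three types —
   prevention (advisory only), correction, recommendation.

Evaluating a profile over a data resource produces **assertions**, each
carrying five components: the contextualized element, the specification
(method description), the mechanism (the artifact that executed it), the
data resource, and the result.  The report contains one measure per
dimension (per record for record-level dimensions), one validation per
criterion, and one amendment per enhancement per record — amendments with
nothing to propose are recorded as NOT_PROPOSED rather than omitted, so
report shape is a function of the profile and the record count alone.

Two management modes act on a report.  *Quality assurance*
(`filter_fit_for_use`) retains exactly the records whose record-level
validations are all COMPLIANT; unassessable records
(PREREQUISITES_NOT_MET) are excluded too, because an unassessable record
is not demonstrably fit.  *Quality control* (`apply_amendments`) applies
accepted proposals to a copy of the data, never in place, with a
changelog; all proposals are computed against the original values, so no
within-report chaining and no order dependence.

## Mechanism catalogue

- **Completeness** — a value is missing iff the field is absent or its
  text, after trimming, is empty or one of NULL/NA/N/A (case-insensitive).
  These sentinels dominate real occurrence exports; no other coercion is
  applied.
- **Coordinate conformity** — the conjunction of four independently
  registered sub-checks (is-number, valid-characters, latitude range
  [−90, 90] inclusive, longitude range [−180, 180] inclusive).  The broad
  mechanism delegates to the four specific ones; tests assert the
  composition law on arbitrary inputs.  "Valid characters" means the
  strict decimal-degree dialect: optional leading sign, digits, at most
  one dot — no comma, letters, or exponent notation.
- **Coordinate consistency** — the point-radius test: consistent iff the
  circle of radius coordinateUncertaintyInMeters around the coordinate
  intersects the named country's polygon set, tangency included.  Distances
  are planar: 1° latitude = 111 320 m, 1° longitude = 111 320·cos(lat) m
  evaluated at the record's latitude.  No geodesic model and no datum
  transformation — geodeticDatum participates only in completeness.  At the
  scale of the bundled geometries (coarse country outlines, sub-kilometre
  radii) the approximation error is orders of magnitude below the
  uncertainty radii involved.  A missing *or unparseable* uncertainty is
  treated as 0 m (pure point test) with the substitution noted in the
  result detail — the strictest reading of the radius rule.  An unknown
  country name is a prerequisite failure, not an inconsistency; country
  matching is exact after case-folding, never fuzzy.
- **Taxon backfill** — the most specific provided rank name (species up to
  kingdom, then scientificName) is resolved in the reference taxonomy and
  its parent chain walked; only blank higher ranks receive proposals.  A
  filled rank that contradicts the derived lineage is left untouched and
  the conflict is reported in the rationale.  A name occurring at multiple
  taxonomy nodes is an "ambiguous name" prerequisite failure.
- **Country from coordinates** — proposes the unique containing country
  for a blank country field; a differing filled value yields a
  replacement-flagged recommendation; containment by zero (open ocean) or
  more than one polygon set proposes nothing.
- **Coordinates from locality** — exact gazetteer lookup after
  case-folding and whitespace collapsing; deliberately no free-text
  georeferencing.
- **Name suggestions** — accepted names within a bounded Levenshtein
  distance (default 2), sorted by (distance, name).  Edit distances come
  from `edlib`; the test suite verifies them against an independent
  quadratic dynamic-programming oracle.  This is a prevention-type
  enhancement: it never proposes a change, only lists candidates.

## Numerical choices

Dataset proportions are counted in exact rational arithmetic
(`fractions.Fraction`) and converted to float once, so a measure equals
`k/n` bit-for-bit and "equal to 100%" means exactly 1.0.  Thresholds
written as percentages ("100%") are normalized to proportions at parse
time.  Assertion order is measurement-policy order then row order, making
reports byte-stable for fixed inputs (timestamp aside).  Record-level
criteria also produce a convenience dataset roll-up; it lives in a
separate `derived_summaries` list so the core profile→report counting law
stays exact over `validations`.

## Synthetic data

The generator emulates an occurrence export whose records are, before
defect injection, perfectly clean: points strictly inside one of three
convex toy countries (0.5° interior margin), uncertainty 10–1000 m, full
seven-rank taxon lineage, an accepted binomial, a gazetteer locality.
Defects are injected per record at user-set rates; coordinate defects
follow the fixed precedence missing ≻ non-numeric ≻ out-of-range ≻
wrong-country, so at most one applies per record and the ground-truth
classes nest cleanly (consistent ⊂ conformant ⊂ complete).  Ground-truth
flags are set by construction at generation time, independent of the
mechanisms under test, which makes the realized counts an exact oracle for
every dataset measure.  One seeded `random.Random` stream is consumed in a
fixed field order (auxiliary draws are consumed even when unused), so
identical (n, rates, seed) calls are byte-identical across platforms.

Toy countries are 10°×10° squares at least 10° apart; a mislabelled record
is therefore ≥ ~1 100 km from its claimed country, guaranteeing
inconsistency at the sub-kilometre uncertainty radii generated.  The toy
reference set also ships a coarse ~20-vertex Brazil outline — sufficient
for the classic worked example in which a South Atlantic coordinate
labelled "Brazil" must evaluate NOT_CONSISTENT — plus a three-lineage
taxonomy, a 20-entry gazetteer whose points all lie inside their toy
countries, and 50 accepted names.  The fixtures are deliberately constant;
the `seed` parameter exists for interface symmetry.

What the generator does **not** emulate: real-world defect correlations
(missingness clustered by provider or era), heaped coordinate precision,
real GADM-scale boundary complexity, datum shifts, or taxonomic synonymy.
Passing tests therefore demonstrate correctness of the measurement,
validation, filtering and amendment logic under controlled error rates —
not performance on any particular real aggregator's error distribution.

## Problem sizes

The default verification runs use n = 10 000 records for exact
ground-truth recovery (5 seeds), 100 random profile/dataset pairs
(n ≤ 200) for the report-shape law, ≥1000 random points for the geometry
oracles, and 100 generated instances for serialization round-trips.  These
sizes give exact combinatorial coverage of the properties involved;
nothing in the engine is stochastic, so larger inputs change runtime, not
conclusions.

## Open design points resolved here

- A criterion references exactly one dimension; multi-dimension criteria
  can be expressed as several criteria.
- Only flat field→value records are supported as "single record";
  structured multi-table representations are out of scope.
- Disjoint territories sharing a country name are treated as one polygon
  set.
- The two classic consistency specifications ("inside the boundary" vs
  "within 1 km of it") are both expressible through the uncertainty-radius
  parameter; the mechanism implements the radius form with 0 m as the
  strict default.
- Amendment applicability: every enhancement produces an assertion for
  every record, with NOT_PROPOSED / PREREQUISITES_NOT_MET stated
  explicitly, rather than silently skipping inapplicable records.

## Known limitations

- Planar distances degrade near the poles and for continent-scale radii;
  both are far outside the intended regime.
- The in-process mechanism registry is not a shared network service; ids
  like `spec:coordinate-consistency` are stable strings intended to be
  citable in shared profile files.
- No Darwin Core Archive (`meta.xml`) handling — point the readers at the
  occurrence core CSV/TSV directly.
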