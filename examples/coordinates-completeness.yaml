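format_version: "1.0"
use_case:
  id: uc-coordinates-completeness
  label: Coordinate completeness for distribution modelling
  description: >-
    Generating a distribution model for the wild bee Tetragonisca angustula
    requires every record to carry a full point-radius georeference:
    latitude, longitude, uncertainty radius and geodetic datum.
information_elements:
- id: coordinates
  label: coordinates
  kind: COMPOSED
  terms:
  - decimalLatitude
  - decimalLongitude
  - coordinateUncertaintyInMeters
  - geodeticDatum
  description: Point-radius georeference of the occurrence.
measurement_policy:
- id: coord-completeness-record
  dimension: COMPLETENESS
  information_element: coordinates
  resource_type: SINGLE_RECORD
  specification: spec:completeness
- id: coord-completeness-dataset
  dimension: COMPLETENESS
  information_element: coordinates
  resource_type: DATASET
  specification: spec:completeness
validation_policy:
- id: completeness-must-be-total
  statement: coordinate completeness of a dataset must be equal to 100%
  dimension: coord-completeness-dataset
  comparator: EQ
  threshold: 100%
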