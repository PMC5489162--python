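"""Seeded random generators for profiles used across the suite.

Profiles draw only on the built-in mechanism catalogue so every generated
profile is evaluable by the default registry.
"""

from __future__ import annotations

import random

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

# (spec id, positive qualitative value) for measurement specifications
MEASURE_SPECS = [
    ("spec:completeness", "COMPLETE"),
    ("spec:coordinate-conformity", "CONFORMANT"),
    ("spec:coordinate-consistency", "CONSISTENT"),
    ("spec:value-is-number", "CONFORMANT"),
    ("spec:value-valid-characters", "CONFORMANT"),
    ("spec:latitude-range", "CONFORMANT"),
    ("spec:longitude-range", "CONFORMANT"),
]

AMEND_SPECS = [
    ("spec:fill-taxon-hierarchy", EnhancementType.CORRECTION),
    ("spec:country-from-coordinates", EnhancementType.RECOMMENDATION),
    ("spec:coordinates-from-locality", EnhancementType.RECOMMENDATION),
    ("spec:name-suggestions", EnhancementType.PREVENTION),
]

_TERM_POOL = [
    "decimalLatitude", "decimalLongitude", "coordinateUncertaintyInMeters",
    "geodeticDatum", "country", "locality", "scientificName", "eventDate",
    "kingdom", "family", "genus", "species",
]

_DIMENSION_NAMES = ["COMPLETENESS", "CONFORMITY", "CONSISTENCY"]


def random_profile(rng: random.Random, max_per_section: int = 5) -> Profile:
    """A structurally valid profile with up to *max_per_section* dimensions,
    criteria and enhancements over 1-3 information elements."""
    n_ies = rng.randint(1, 3)
    ies = []
    for i in range(n_ies):
        n_terms = rng.randint(1, 4)
        terms = rng.sample(_TERM_POOL, n_terms)
        ies.append(InformationElement(
            id=f"ie-{i}",
            label=f"element {i}",
            kind=IEKind.SINGLE if n_terms == 1 else IEKind.COMPOSED,
            terms=tuple(terms),
        ))

    n_dims = rng.randint(1, max_per_section)
    dims = []
    positive_by_dim = {}
    for i in range(n_dims):
        spec_id, positive = MEASURE_SPECS[rng.randrange(len(MEASURE_SPECS))]
        dim = ContextualizedDimension(
            id=f"dim-{i}",
            dimension=_DIMENSION_NAMES[rng.randrange(len(_DIMENSION_NAMES))],
            ie_ref=ies[rng.randrange(n_ies)].id,
            resource_type=(ResourceType.SINGLE_RECORD if rng.random() < 0.5
                           else ResourceType.DATASET),
            specification_ref=spec_id,
        )
        dims.append(dim)
        positive_by_dim[dim.id] = positive

    n_crits = rng.randint(0, max_per_section)
    crits = []
    for i in range(n_crits):
        dim = dims[rng.randrange(n_dims)]
        if dim.resource_type is ResourceType.DATASET:
            crits.append(ContextualizedCriterion(
                id=f"crit-{i}",
                dimension_ref=dim.id,
                comparator=rng.choice(list(Comparator)),
                threshold=round(rng.random(), 3),
            ))
        else:
            crits.append(ContextualizedCriterion(
                id=f"crit-{i}",
                dimension_ref=dim.id,
                comparator=Comparator.EQ,
                threshold=positive_by_dim[dim.id],
            ))

    n_enhs = rng.randint(0, max_per_section)
    enhs = []
    for i in range(n_enhs):
        spec_id, etype = AMEND_SPECS[rng.randrange(len(AMEND_SPECS))]
        targets = tuple({dims[rng.randrange(n_dims)].id
                         for _ in range(rng.randint(1, 2))})
        enhs.append(ContextualizedEnhancement(
            id=f"enh-{i}",
            enhancement_type=etype,
            target_dimension_refs=targets,
            specification_ref=spec_id,
        ))

    return Profile(
        use_case=UseCase(id=f"uc-{rng.randrange(10**6)}", label="generated"),
        valuable_ies=tuple(ies),
        measurement_policy=tuple(dims),
        validation_policy=tuple(crits),
        enhancement_policy=tuple(enhs),
    )
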