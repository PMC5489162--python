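"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: ray casting over explicit vertex lists, quadratic
dynamic-programming Levenshtein, and a re-resolving profile reference
checker.  None of these share code with the package paths they verify.
"""

from __future__ import annotations

import math

METERS_PER_DEGREE = 111_320.0


def polygon_rings(geometry) -> list[list[tuple[float, float]]]:
    """Extract all rings (exterior and holes) as (lon, lat) vertex lists."""
    polys = getattr(geometry, "geoms", [geometry])
    rings = []
    for poly in polys:
        rings.append(list(poly.exterior.coords))
        for interior in poly.interiors:
            rings.append(list(interior.coords))
    return rings


def ray_cast_contains(lon: float, lat: float,
                      rings: list[list[tuple[float, float]]]) -> bool:
    """Even-odd rule over all rings: crossings of a ray to +x."""
    crossings = 0
    for ring in rings:
        for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
            if (y1 > lat) != (y2 > lat):
                x_at = x1 + (lat - y1) * (x2 - x1) / (y2 - y1)
                if x_at > lon:
                    crossings += 1
    return crossings % 2 == 1


def point_segment_distance(px, py, x1, y1, x2, y2) -> float:
    dx, dy = x2 - x1, y2 - y1
    if dx == 0 and dy == 0:
        return math.hypot(px - x1, py - y1)
    t = ((px - x1) * dx + (py - y1) * dy) / (dx * dx + dy * dy)
    t = max(0.0, min(1.0, t))
    return math.hypot(px - (x1 + t * dx), py - (y1 + t * dy))


def planar_boundary_distance_m(lat: float, lon: float,
                               rings: list[list[tuple[float, float]]]) -> float:
    """Min distance in meters from the point to any polygon edge, in the
    equirectangular local plane evaluated at the point's latitude."""
    kx = METERS_PER_DEGREE * math.cos(math.radians(lat))
    ky = METERS_PER_DEGREE
    best = math.inf
    for ring in rings:
        for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
            d = point_segment_distance(
                0.0, 0.0,
                (x1 - lon) * kx, (y1 - lat) * ky,
                (x2 - lon) * kx, (y2 - lat) * ky,
            )
            best = min(best, d)
    return best


def levenshtein_dp(a: str, b: str) -> int:
    """Classic quadratic dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i]
        for j, cb in enumerate(b, start=1):
            curr.append(min(
                prev[j] + 1,
                curr[j - 1] + 1,
                prev[j - 1] + (ca != cb),
            ))
        prev = curr
    return prev[-1]


def resolve_all_references(profile) -> list[tuple[str, str, str]]:
    """Brute-force reference resolver: every (section, item id, dangling ref)
    triple found by re-resolving each id against freshly built id sets."""
    ie_ids = {ie.id for ie in profile.valuable_ies}
    dim_ids = {d.id for d in profile.measurement_policy}
    dangling = []
    for d in profile.measurement_policy:
        if d.ie_ref not in ie_ids:
            dangling.append(("measurement_policy", d.id, d.ie_ref))
    for c in profile.validation_policy:
        if c.dimension_ref not in dim_ids:
            dangling.append(("validation_policy", c.id, c.dimension_ref))
    for e in profile.enhancement_policy:
        for ref in e.target_dimension_refs:
            if ref not in dim_ids:
                dangling.append(("enhancement_policy", e.id, ref))
    return dangling
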