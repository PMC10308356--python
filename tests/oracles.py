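"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools


def _cross(o, a, b):
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _on_segment(p, a, b) -> bool:
    """p strictly or terminally on segment [a, b] (p != a, p != b assumed deduped)."""
    if _cross(a, b, p) != 0:
        return False
    return (min(a[0], b[0]) <= p[0] <= max(a[0], b[0])
            and min(a[1], b[1]) <= p[1] <= max(a[1], b[1]))


def _strictly_inside_triangle(p, a, b, c) -> bool:
    d1 = _cross(p, a, b)
    d2 = _cross(p, b, c)
    d3 = _cross(p, c, a)
    return (d1 > 0 and d2 > 0 and d3 > 0) or (d1 < 0 and d2 < 0 and d3 < 0)


def brute_force_hull_vertices(points) -> set[tuple[float, float]]:
    """Hull vertex set by exhaustive convexity testing, O(n^4).

    After deduplication, a point is a hull vertex iff it is not in the convex
    hull of the remaining points: not on a segment between two others and not
    strictly inside any triangle of others. Degenerate inputs (all collinear
    or < 3 distinct points) return the empty set. Exact for integer inputs.
    """
    pts = sorted({(p[0], p[1]) for p in points})
    if len(pts) < 3:
        return set()
    if all(_cross(pts[0], pts[1], q) == 0 for q in pts[2:]):
        return set()
    vertices = set()
    for p in pts:
        others = [q for q in pts if q != p]
        dominated = any(_on_segment(p, a, b) for a, b in itertools.combinations(others, 2))
        if not dominated:
            dominated = any(_strictly_inside_triangle(p, a, b, c)
                            for a, b, c in itertools.combinations(others, 3))
        if not dominated:
            vertices.add(p)
    return vertices


def brute_force_thin(records, cell_of) -> set[str]:
    """Surviving record ids by exhaustive grouping: for every (species, cell)
    group keep the smallest record_id."""
    groups: dict[tuple, list[str]] = {}
    for r in records:
        groups.setdefault((r.species_id, cell_of(r)), []).append(r.record_id)
    return {min(ids) for ids in groups.values()}
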