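"""Fibril topologies as periodic graph templates and the fibril-fraction assay.

The five amyloid fibril topologies observed in the PDB — 1-ribbon,
2-ribbon, 1,2 2-ribbon (the steric-zipper motif), double 1,2 2-ribbon and
3-prism — are periodic graphs: a repeat unit of ``strands`` nodes stacked
along the fibril growth axis, with edges given by offset rules
((strand a, strand b), delta) meaning node (a, i) bonds node (b, i+delta).

The *fibril fraction* of a graph is the number of nodes belonging to a
region of perfect fibril divided by the total number of nodes.  The assay
is strict, rewarding long defect-free fibrils: a node counts only if it
sits in an embedded template segment spanning at least ``min_units`` repeat
units (wrap-around, i.e. cyclic fibrils, allowed), its complete interior
template neighborhood is present, and it has no bonds outside the matched
pattern.  Free ends therefore never count, which slightly undercounts
fibrillar material but strongly favors interior (bulk) structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .netstats import Graph

__all__ = [
    "FibrilTemplate",
    "TEMPLATES",
    "AssayResult",
    "build_fibril",
    "fibril_nodes",
    "fibril_fraction",
    "assay",
]

Offset = tuple[int, int, int]  # (strand a, strand b, axial offset)


@dataclass(frozen=True)
class FibrilTemplate:
    """Periodic motif defining one fibril topology.

    ``edge_offsets`` entries (a, b, d) place an edge between node (a, i)
    and node (b, i + d) for every repeat-unit index i; axial offsets are
    restricted to d in {0, 1}.  ``min_units`` is the shortest segment that
    counts as fibril; ``min_wrap_units`` the shortest valid cyclic fibril.
    """

    name: str
    strands: int
    edge_offsets: tuple[Offset, ...]
    min_units: int = 3
    min_wrap_units: int = 3

    # derived, not part of the public constructor contract
    intra: tuple[tuple[int, int], ...] = field(init=False, repr=False, compare=False)
    inter: tuple[tuple[int, int], ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strands < 1:
            raise ValueError("strands must be positive")
        if self.min_units < 1 or self.min_wrap_units < 3:
            raise ValueError("min_units must be >= 1 and min_wrap_units >= 3")
        intra: list[tuple[int, int]] = []
        inter: list[tuple[int, int]] = []
        seen = set()
        for a, b, d in self.edge_offsets:
            if not (0 <= a < self.strands and 0 <= b < self.strands):
                raise ValueError(f"offset ({a}, {b}, {d}) outside strand range")
            if d not in (0, 1):
                raise ValueError("axial offsets must be 0 or 1")
            if d == 0:
                if a == b:
                    raise ValueError("zero-offset rule may not be a self-loop")
                key = (min(a, b), max(a, b), 0)
                if key in seen:
                    raise ValueError(f"duplicate offset rule {key}")
                seen.add(key)
                intra.append((min(a, b), max(a, b)))
            else:
                key = (a, b, 1)
                if key in seen:
                    raise ValueError(f"duplicate offset rule {key}")
                seen.add(key)
                inter.append((a, b))
        if not inter:
            raise ValueError("template needs at least one axial (offset-1) rule")
        object.__setattr__(self, "intra", tuple(intra))
        object.__setattr__(self, "inter", tuple(inter))
        self._validate_connectivity()

    def _validate_connectivity(self) -> None:
        # intra edges must connect the repeat unit so embeddings can be
        # enumerated strand-by-strand; axial rules must reach every strand
        if self.strands > 1:
            comp = {0}
            grown = True
            while grown:
                grown = False
                for a, b in self.intra:
                    if (a in comp) != (b in comp):
                        comp |= {a, b}
                        grown = True
            if len(comp) != self.strands:
                raise ValueError(
                    f"template {self.name!r}: intra-unit edges must connect all strands"
                )
        anchored = {b for _, b in self.inter} | {a for a, _ in self.inter}
        grown = True
        while grown:
            grown = False
            for a, b in self.intra:
                if (a in anchored) != (b in anchored):
                    anchored |= {a, b}
                    grown = True
        if len(anchored) != self.strands:
            raise ValueError(
                f"template {self.name!r}: axial rules must anchor every strand"
            )

    def interior_degree(self, strand: int) -> int:
        """Degree of an interior node on ``strand`` in an infinite fibril."""
        d = sum(1 for a, b in self.intra if strand in (a, b))
        d += sum(1 for a, _ in self.inter if a == strand)
        d += sum(1 for _, b in self.inter if b == strand)
        return d


#: The five experimentally observed fibril topologies.
TEMPLATES: dict[str, FibrilTemplate] = {
    "1-ribbon": FibrilTemplate("1-ribbon", 1, ((0, 0, 1),)),
    "2-ribbon": FibrilTemplate("2-ribbon", 2, ((0, 1, 0), (0, 0, 1), (1, 1, 1))),
    "1,2 2-ribbon": FibrilTemplate(
        "1,2 2-ribbon", 2, ((0, 1, 0), (0, 0, 1), (1, 1, 1), (0, 1, 1))
    ),
    "double 1,2 2-ribbon": FibrilTemplate(
        "double 1,2 2-ribbon",
        4,
        (
            (0, 1, 0), (2, 3, 0), (1, 2, 0),
            (0, 0, 1), (1, 1, 1), (2, 2, 1), (3, 3, 1),
            (0, 1, 1), (2, 3, 1),
        ),
    ),
    "3-prism": FibrilTemplate(
        "3-prism", 3, ((0, 1, 0), (1, 2, 0), (0, 2, 0), (0, 0, 1), (1, 1, 1), (2, 2, 1))
    ),
}


@dataclass(frozen=True)
class AssayResult:
    """Fibrillar node set and the resulting fibril fraction."""

    fibrillar_nodes: frozenset[int]
    fraction: float


def build_fibril(template: FibrilTemplate, units: int, cyclic: bool = False) -> Graph:
    """Perfect fibril of ``units`` repeat units; node (s, i) has index
    ``i * strands + s``.  Cyclic fibrils wrap the axial rules around."""
    if units < 1:
        raise ValueError("units must be positive")
    if cyclic and units < template.min_wrap_units:
        raise ValueError(
            f"cyclic {template.name} needs at least {template.min_wrap_units} units"
        )
    S = template.strands
    g = Graph(units * S)
    for i in range(units):
        for a, b in template.intra:
            g.add_edge(i * S + a, i * S + b)
        if i + 1 < units or cyclic:
            j = (i + 1) % units
            for a, b in template.inter:
                g.add_edge(i * S + a, j * S + b)
    return g


# ---------------------------------------------------------------------------
# template matching
# ---------------------------------------------------------------------------

def _bfs_strand_order(template: FibrilTemplate, start: int) -> list[int]:
    order = [start]
    seen = {start}
    i = 0
    while i < len(order):
        s = order[i]
        for a, b in template.intra:
            for o, t in ((a, b), (b, a)):
                if o == s and t not in seen:
                    seen.add(t)
                    order.append(t)
        i += 1
    return order


def _complete_unit(
    g: Graph,
    template: FibrilTemplate,
    assigned: dict[int, int],
    order: list[int],
    pos: int,
    forbidden: set[int],
) -> Iterator[tuple[int, ...]]:
    """Backtracking completion of a partial strand->node assignment; strands
    are filled in ``order`` so each new strand has an assigned intra-edge
    neighbor (or an external constraint already applied by the caller)."""
    if pos == len(order):
        yield tuple(assigned[s] for s in range(template.strands))
        return
    s = order[pos]
    if s in assigned:
        yield from _complete_unit(g, template, assigned, order, pos + 1, forbidden)
        return
    # candidates: common neighbors of all already-assigned intra partners
    anchors = [
        assigned[o]
        for a, b in template.intra
        for o, t in ((a, b), (b, a))
        if t == s and o in assigned
    ]
    if not anchors:  # pragma: no cover - excluded by template validation
        raise RuntimeError("unanchored strand during unit completion")
    cands = set(g.neighbors(anchors[0]))
    for x in anchors[1:]:
        cands &= g.neighbors(x)
    for node in sorted(cands):
        if node in forbidden or node in assigned.values():
            continue
        assigned[s] = node
        yield from _complete_unit(g, template, assigned, order, pos + 1, forbidden)
        del assigned[s]


def _unit_instances_at(
    g: Graph, template: FibrilTemplate, v: int, strand: int
) -> Iterator[tuple[int, ...]]:
    """Unit instances (injective strand->node maps realizing the intra
    edges) that place node v on the given strand."""
    order = _bfs_strand_order(template, strand)
    yield from _complete_unit(g, template, {strand: v}, order, 0, set())


def _adjacent_units(
    g: Graph,
    template: FibrilTemplate,
    unit: tuple[int, ...],
    direction: int,
    forbidden: set[int],
) -> Iterator[tuple[int, ...]]:
    """Units that can sit axially next to ``unit`` (direction +1 = toward
    increasing repeat index), node-disjoint from ``forbidden``."""
    # per-strand candidate constraints from the axial rules
    constraints: dict[int, list[int]] = {}
    for a, b in template.inter:
        if direction == +1:
            constraints.setdefault(b, []).append(unit[a])
        else:
            constraints.setdefault(a, []).append(unit[b])

    def fill(strands_left: list[int], assigned: dict[int, int]) -> Iterator[tuple[int, ...]]:
        if not strands_left:
            # verify intra edges of the new unit
            for a, b in template.intra:
                if not g.has_edge(assigned[a], assigned[b]):
                    return
            yield tuple(assigned[s] for s in range(template.strands))
            return
        s = strands_left[0]
        anchors = list(constraints.get(s, []))
        anchors += [
            assigned[o]
            for a, b in template.intra
            for o, t in ((a, b), (b, a))
            if t == s and o in assigned
        ]
        if not anchors:  # pragma: no cover - excluded by template validation
            raise RuntimeError("unanchored strand during axial extension")
        cands = set(g.neighbors(anchors[0]))
        for x in anchors[1:]:
            cands &= g.neighbors(x)
        for node in sorted(cands):
            if node in forbidden or node in assigned.values():
                continue
            assigned[s] = node
            yield from fill(strands_left[1:], assigned)
            del assigned[s]

    # fill constrained strands first so every step is anchored
    strand_order = sorted(range(template.strands), key=lambda s: s not in constraints)
    yield from fill(strand_order, {})


def _expected_neighbors(
    template: FibrilTemplate,
    strand: int,
    center: tuple[int, ...],
    nxt: tuple[int, ...],
    prv: tuple[int, ...],
) -> set[int]:
    exp: set[int] = set()
    for a, b in template.intra:
        if a == strand:
            exp.add(center[b])
        elif b == strand:
            exp.add(center[a])
    for a, b in template.inter:
        if a == strand:
            exp.add(nxt[b])
        if b == strand:
            exp.add(prv[a])
    return exp


def _chain_reaches(
    g: Graph,
    template: FibrilTemplate,
    left: tuple[int, ...],
    right: tuple[int, ...],
    used: set[int],
    have: int,
    target: int,
) -> bool:
    """Can the 3-unit core extend (either direction) to ``target`` units of
    pairwise node-disjoint segment?"""
    if have >= target:
        return True
    for u2 in _adjacent_units(g, template, right, +1, used):
        if _chain_reaches(g, template, left, u2, used | set(u2), have + 1, target):
            return True
    for u2 in _adjacent_units(g, template, left, -1, used):
        if _chain_reaches(g, template, u2, right, used | set(u2), have + 1, target):
            return True
    return False


def _node_is_fibrillar(g: Graph, template: FibrilTemplate, v: int) -> bool:
    deg_v = g.degree(v)
    candidate_strands = [
        s for s in range(template.strands) if template.interior_degree(s) == deg_v
    ]
    for strand in candidate_strands:
        for center in _unit_instances_at(g, template, v, strand):
            used = set(center)
            for nxt in _adjacent_units(g, template, center, +1, used):
                used_n = used | set(nxt)
                for prv in _adjacent_units(g, template, center, -1, used_n):
                    exp = _expected_neighbors(template, strand, center, nxt, prv)
                    if g.neighbors(v) != exp:
                        continue
                    if template.min_units <= 3:
                        return True
                    if _chain_reaches(
                        g, template, prv, nxt, used_n | set(prv), 3, template.min_units
                    ):
                        return True
    return False


def fibril_nodes(g: Graph, template: FibrilTemplate) -> set[int]:
    """Nodes belonging to a region of perfect fibril.

    A node counts if and only if it is interior to an embedded template
    segment of at least ``min_units`` repeat units (cyclic wrap-around
    allowed) and its graph neighborhood is *exactly* its interior template
    neighborhood — no missing template bonds, no extra bonds.  Overlapping
    segments contribute the union of their interior nodes.
    """
    return {v for v in range(g.n_nodes) if _node_is_fibrillar(g, template, v)}


def assay(g: Graph, template: FibrilTemplate) -> AssayResult:
    nodes = frozenset(fibril_nodes(g, template))
    frac = len(nodes) / g.n_nodes if g.n_nodes else 0.0
    return AssayResult(fibrillar_nodes=nodes, fraction=frac)


def fibril_fraction(g: Graph, template: FibrilTemplate) -> float:
    """|fibrillar nodes| / |nodes|, in [0, 1]."""
    return assay(g, template).fraction
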