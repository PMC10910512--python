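"""Graph container, ERGM sufficient statistics, and change statistics.

A network Hamiltonian model represents a system of aggregating protein
molecules as a simple undirected graph: one node per molecule, one edge per
noncovalent bond.  The model's energy is a linear function of *sufficient
statistics* — counts of small subgraph motifs.  This module provides the
graph container, exact counts for the ten supported statistics, and the
*change statistics* (the difference in each count caused by toggling a
single edge), computed from the local neighborhood of the toggled dyad so
that Markov-chain sampling never needs a full recount.

Supported statistics
--------------------
``edges``
    number of edges, |E|.
``twostar``
    number of 2-stars, sum over nodes of C(deg, 2); a node bound to two
    neighbors contributes one 2-star per unordered neighbor pair.
``nsp1``, ``nsp2``
    null shared partners: non-adjacent node pairs with exactly 1 (resp. 2)
    common neighbors.
``esp0``, ``esp1``
    edgewise shared partners: edges whose endpoints have exactly 0
    (resp. 1) common neighbors.
``cycle3``, ``cycle5``, ``cycle6``, ``cycle7``
    simple cycles of length exactly k, each counted once regardless of
    orientation or starting node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "STAT_NAMES",
    "Graph",
    "StatSpec",
    "UnknownStatisticError",
    "compute_statistic",
    "compute_stats",
    "change_stats",
]

#: All supported statistic names, in canonical order.
STAT_NAMES: tuple[str, ...] = (
    "edges",
    "twostar",
    "nsp1",
    "nsp2",
    "esp0",
    "esp1",
    "cycle3",
    "cycle5",
    "cycle6",
    "cycle7",
)

_CYCLE_LENGTH = {"cycle3": 3, "cycle5": 5, "cycle6": 6, "cycle7": 7}


class UnknownStatisticError(KeyError):
    """Raised for a statistic name outside the supported set."""

    def __init__(self, name: object) -> None:
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"unknown statistic {self.name!r}; supported: {', '.join(STAT_NAMES)}"


class Graph:
    """Simple undirected graph on ``n_nodes`` labeled nodes (0-based).

    No self-loops, no parallel edges.  Mutable: the sampler toggles edges
    in place.  Adjacency is kept as per-node sets, so membership tests and
    neighbor iteration are O(1)/O(deg).
    """

    __slots__ = ("n_nodes", "_adj", "_n_edges")

    def __init__(self, n_nodes: int, edges: Iterable[tuple[int, int]] = ()) -> None:
        if n_nodes < 0:
            raise ValueError("n_nodes must be nonnegative")
        self.n_nodes = int(n_nodes)
        self._adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        self._n_edges = 0
        for u, v in edges:
            self.add_edge(u, v)

    # -- basic queries ----------------------------------------------------
    @property
    def n_edges(self) -> int:
        return self._n_edges

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def neighbors(self, u: int) -> set[int]:
        return self._adj[u]

    def has_edge(self, u: int, v: int) -> bool:
        self._check_dyad(u, v)
        return v in self._adj[u]

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield each edge once as (u, v) with u < v, sorted."""
        for u in range(self.n_nodes):
            for v in self._adj[u]:
                if u < v:
                    yield (u, v)

    # -- mutation ---------------------------------------------------------
    def add_edge(self, u: int, v: int) -> None:
        self._check_dyad(u, v)
        if v in self._adj[u]:
            raise ValueError(f"edge ({u}, {v}) already present")
        self._adj[u].add(v)
        self._adj[v].add(u)
        self._n_edges += 1

    def remove_edge(self, u: int, v: int) -> None:
        self._check_dyad(u, v)
        if v not in self._adj[u]:
            raise ValueError(f"edge ({u}, {v}) not present")
        self._adj[u].remove(v)
        self._adj[v].remove(u)
        self._n_edges -= 1

    def toggle(self, u: int, v: int) -> None:
        if self.has_edge(u, v):
            self.remove_edge(u, v)
        else:
            self.add_edge(u, v)

    def copy(self) -> "Graph":
        g = Graph(self.n_nodes)
        g._adj = [set(a) for a in self._adj]
        g._n_edges = self._n_edges
        return g

    def _check_dyad(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError(f"self-loop ({u}, {u}) not allowed")
        if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
            raise ValueError(f"dyad ({u}, {v}) out of range for {self.n_nodes} nodes")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.n_nodes == other.n_nodes and self._adj == other._adj

    def __repr__(self) -> str:
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self._n_edges})"


@dataclass(frozen=True)
class StatSpec:
    """An ordered, fixed choice of sufficient statistics for one model."""

    names: tuple[str, ...]

    def __init__(self, names: Sequence[str]) -> None:
        names = tuple(names)
        if not names:
            raise ValueError("StatSpec needs at least one statistic")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate statistic names in {names}")
        for name in names:
            if name not in STAT_NAMES:
                raise UnknownStatisticError(name)
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


# ---------------------------------------------------------------------------
# full counts
# ---------------------------------------------------------------------------

def _common_neighbors(g: Graph, u: int, v: int) -> int:
    a, b = g.neighbors(u), g.neighbors(v)
    if len(b) < len(a):
        a, b = b, a
    return sum(1 for w in a if w in b)


def _count_twostar(g: Graph) -> int:
    return sum(d * (d - 1) // 2 for d in (g.degree(u) for u in range(g.n_nodes)))


def _count_sp(g: Graph, k: int, adjacent: bool) -> int:
    """Shared-partner count: pairs (adjacent or not) with exactly k common neighbors."""
    count = 0
    for u in range(g.n_nodes):
        for v in range(u + 1, g.n_nodes):
            if g.has_edge(u, v) is not adjacent:
                continue
            if _common_neighbors(g, u, v) == k:
                count += 1
    return count


def _count_cycles(g: Graph, k: int) -> int:
    """Number of simple cycles of length exactly k, each counted once.

    Enumerates cycles anchored at their smallest node; each cycle is found
    twice (once per direction), so the raw tally is halved.
    """
    total = 0
    n = g.n_nodes

    def paths_back(start: int, node: int, depth: int, visited: set[int]) -> int:
        # count simple paths of (k - depth) further edges returning to start,
        # through nodes > start only
        if depth == k - 1:
            return 1 if start in g.neighbors(node) else 0
        found = 0
        for w in g.neighbors(node):
            if w > start and w not in visited:
                visited.add(w)
                found += paths_back(start, w, depth + 1, visited)
                visited.remove(w)
        return found

    for s in range(n):
        for w in g.neighbors(s):
            if w > s:
                total += paths_back(s, w, 1, {w})
    return total // 2


def compute_statistic(g: Graph, name: str) -> int:
    """Exact count of subgraphs of type ``name`` in ``g``."""
    if name == "edges":
        return g.n_edges
    if name == "twostar":
        return _count_twostar(g)
    if name == "nsp1":
        return _count_sp(g, 1, adjacent=False)
    if name == "nsp2":
        return _count_sp(g, 2, adjacent=False)
    if name == "esp0":
        return _count_sp(g, 0, adjacent=True)
    if name == "esp1":
        return _count_sp(g, 1, adjacent=True)
    if name in _CYCLE_LENGTH:
        return _count_cycles(g, _CYCLE_LENGTH[name])
    raise UnknownStatisticError(name)


def compute_stats(g: Graph, spec: StatSpec) -> list[int]:
    """Vector of counts aligned with ``spec.names``."""
    return [compute_statistic(g, name) for name in spec.names]


# ---------------------------------------------------------------------------
# change statistics
# ---------------------------------------------------------------------------

def _count_paths(g: Graph, u: int, v: int, length: int) -> int:
    """Simple paths from u to v with exactly ``length`` edges (u, v excluded
    as intermediates).  Used for cycle change statistics: toggling dyad
    (u, v) changes the k-cycle count by the number of (k-1)-edge paths
    between its endpoints."""
    if length == 1:
        return 1 if g.has_edge(u, v) else 0

    count = 0
    visited = {u}

    def walk(node: int, depth: int) -> None:
        nonlocal count
        if depth == length - 1:
            if v in g.neighbors(node):
                count += 1
            return
        for w in g.neighbors(node):
            if w != v and w not in visited:
                visited.add(w)
                walk(w, depth + 1)
                visited.remove(w)

    walk(u, 0)
    return count


def change_stats(g: Graph, dyad: tuple[int, int], spec: StatSpec) -> list[int]:
    """Change in each statistic caused by toggling ``dyad``.

    Toggle semantics: the edge is added if absent and removed if present.
    Equals ``compute_stats(after) - compute_stats(before)`` but inspects
    only the neighborhood of the dyad.
    """
    u, v = dyad
    g._check_dyad(u, v)
    present = g.has_edge(u, v)
    if present:
        g.remove_edge(u, v)
    try:
        base = _base_change(g, u, v, spec)
    finally:
        if present:
            g.add_edge(u, v)
    if present:
        return [-d for d in base]
    return base


def _base_change(g: Graph, u: int, v: int, spec: StatSpec) -> list[int]:
    """Change vector for *adding* edge (u, v) to g, which must lack it."""
    nu, nv = g.neighbors(u), g.neighbors(v)
    du, dv = len(nu), len(nv)
    c_uv = sum(1 for w in nu if w in nv)

    need_sp = any(n in ("nsp1", "nsp2", "esp0", "esp1") for n in spec.names)
    d_nsp1 = d_nsp2 = d_esp0 = d_esp1 = 0
    if need_sp:
        # the dyad itself moves from NSP class c_uv to ESP class c_uv
        if c_uv == 0:
            d_esp0 += 1
        elif c_uv == 1:
            d_esp1 += 1
            d_nsp1 -= 1
        elif c_uv == 2:
            d_nsp2 -= 1
        # every pair (u, w) with w a neighbor of v gains common neighbor v,
        # and symmetrically (v, w) for w a neighbor of u gains u
        for (a, b) in ((u, v), (v, u)):
            for w in g.neighbors(b):
                if w == a:
                    continue
                c = _common_neighbors(g, a, w)
                if w in g.neighbors(a):  # adjacent pair: ESP class c -> c+1
                    if c == 0:
                        d_esp0 -= 1
                        d_esp1 += 1
                    elif c == 1:
                        d_esp1 -= 1
                else:  # non-adjacent pair: NSP class c -> c+1
                    if c == 0:
                        d_nsp1 += 1
                    elif c == 1:
                        d_nsp1 -= 1
                        d_nsp2 += 1
                    elif c == 2:
                        d_nsp2 -= 1

    deltas: list[int] = []
    for name in spec.names:
        if name == "edges":
            deltas.append(1)
        elif name == "twostar":
            deltas.append(du + dv)
        elif name == "nsp1":
            deltas.append(d_nsp1)
        elif name == "nsp2":
            deltas.append(d_nsp2)
        elif name == "esp0":
            deltas.append(d_esp0)
        elif name == "esp1":
            deltas.append(d_esp1)
        elif name == "cycle3":
            deltas.append(c_uv)
        elif name in _CYCLE_LENGTH:
            deltas.append(_count_paths(g, u, v, _CYCLE_LENGTH[name] - 1))
        else:  # pragma: no cover - StatSpec already validated
            raise UnknownStatisticError(name)
    return deltas
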