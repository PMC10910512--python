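"""Independent brute-force oracles for graph statistics.

Deliberately naive implementations over networkx graphs: pairwise
common-neighbor counting and exhaustive simple-cycle enumeration.  These
never share code with the package so they can arbitrate its counts.
"""

from __future__ import annotations

import itertools
import math
import random

import networkx as nx

from netham.netstats import Graph


def to_nx(g: Graph) -> nx.Graph:
    ng = nx.Graph()
    ng.add_nodes_from(range(g.n_nodes))
    ng.add_edges_from(g.edges())
    return ng


def brute_statistic(ng: nx.Graph, name: str) -> int:
    if name == "edges":
        return ng.number_of_edges()
    if name == "twostar":
        return sum(math.comb(d, 2) for _, d in ng.degree())
    if name.startswith("nsp") or name.startswith("esp"):
        k = int(name[3:])
        adjacent = name.startswith("esp")
        count = 0
        for u, v in itertools.combinations(ng.nodes(), 2):
            if ng.has_edge(u, v) is not adjacent:
                continue
            if len(list(nx.common_neighbors(ng, u, v))) == k:
                count += 1
        return count
    if name.startswith("cycle"):
        k = int(name[5:])
        return sum(1 for c in nx.simple_cycles(ng, length_bound=k) if len(c) == k)
    raise KeyError(name)


def random_graph(n: int, p: float, rng: random.Random) -> Graph:
    edges = [e for e in itertools.combinations(range(n), 2) if rng.random() < p]
    return Graph(n, edges)
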