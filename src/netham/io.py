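"""Graph and table I/O: edge lists, GraphML, CSV ledgers, run metadata.

Edge lists are whitespace-delimited "u v" pairs, one per line, 0-based
node indices; a leading ``# n_nodes N`` comment preserves isolated nodes.
GraphML goes through networkx for interoperability.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .netstats import Graph, StatSpec

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
    "load_graph",
    "save_graph",
    "to_networkx",
    "from_networkx",
    "write_stats_table",
    "write_ga_ledger",
    "write_run_metadata",
    "config_hash",
]


def to_networkx(g: Graph) -> nx.Graph:
    ng = nx.Graph()
    ng.add_nodes_from(range(g.n_nodes))
    ng.add_edges_from(g.edges())
    return ng


def from_networkx(ng: nx.Graph) -> Graph:
    nodes = sorted(ng.nodes())
    index = {node: i for i, node in enumerate(nodes)}
    return Graph(len(nodes), [(index[u], index[v]) for u, v in ng.edges()])


def read_edgelist(path: str | Path, n_nodes: int | None = None) -> Graph:
    edges: list[tuple[int, int]] = []
    declared = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "n_nodes":
                declared = int(parts[1])
            continue
        u, v = line.split()
        edges.append((int(u), int(v)))
    if n_nodes is None:
        n_nodes = declared
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=-1)
    return Graph(n_nodes, edges)


def write_edgelist(g: Graph, path: str | Path) -> None:
    lines = [f"# n_nodes {g.n_nodes}"]
    lines += [f"{u} {v}" for u, v in g.edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_graphml(path: str | Path) -> Graph:
    return from_networkx(nx.read_graphml(path, node_type=int))


def write_graphml(g: Graph, path: str | Path) -> None:
    nx.write_graphml(to_networkx(g), path)


def load_graph(path: str | Path) -> Graph:
    """Dispatch on extension: .graphml, otherwise edge list."""
    if str(path).endswith(".graphml"):
        return read_graphml(path)
    return read_edgelist(path)


def save_graph(g: Graph, path: str | Path) -> None:
    if str(path).endswith(".graphml"):
        write_graphml(g, path)
    else:
        write_edgelist(g, path)


def write_stats_table(
    rows: Iterable[dict], path: str | Path, spec: StatSpec | None = None
) -> pd.DataFrame:
    """Per-draw statistics table; one row per draw, locale-independent CSV."""
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False)
    return df


def write_ga_ledger(history, cfg, path: str | Path) -> pd.DataFrame:
    """Full GA ledger: one row per evaluated individual, with phi
    coordinates, fitness mean/SD and every rep draw."""
    import numpy as np

    names = cfg.spec.names
    rows = []
    for ind in history.individuals:
        row: dict = {
            "id": ind.id,
            "origin": ind.origin,
            "parents": ";".join(str(p) for p in ind.parents),
        }
        for name, x in zip(names, ind.phi):
            row[f"phi_{name}"] = x
        if ind.fitness_draws is not None:
            row["fitness_mean"] = ind.fitness_mean
            row["fitness_sd"] = float(np.std(ind.fitness_draws))
            for r, d in enumerate(ind.fitness_draws):
                row[f"draw_{r}"] = d
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def config_hash(payload: dict) -> str:
    """Stable hash of a config mapping, for replayable run metadata."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_run_metadata(path: str | Path, *, master_seed: int, config: dict) -> None:
    meta = {
        "netham_version": __version__,
        "master_seed": master_seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
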