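"""Equilibrium graph draws by Metropolis-Hastings edge-toggle MCMC.

The target distribution is P(g) proportional to exp(theta^T t(g)) over
simple graphs on N labeled nodes.  Proposals toggle a uniformly random
dyad; a toggle with change statistics dt is accepted with probability
min(1, exp(theta^T dt)).  The proposal kernel is symmetric, so detailed
balance holds by construction.

Chains start from the empty graph by default (a fully disaggregated
monomer system), and a draw is the state after a configurable number of
burn-in proposals — default 50 per dyad, i.e. 50 * C(N, 2).  A degeneracy
guard aborts runaway densification, the classic ERGM failure mode in bad
parameter regions, so parameter searches survive them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _kernel
from ._kernel import STAT_CODES
from .hamiltonian import ModelSpec, ThetaVector, phi_to_theta
from .netstats import Graph, StatSpec, compute_stats

__all__ = [
    "SamplerConfig",
    "DrawResult",
    "DegeneracyError",
    "default_burnin",
    "mh_log_ratio",
    "simulate_draw",
    "simulate_draw_theta",
    "simulate_ensemble",
]


class DegeneracyError(RuntimeError):
    """Raised when the edge count exceeds the degeneracy guard: the chain is
    densifying without bound and equilibrium is not fibril-like."""

    def __init__(self, n_edges: int, guard: int, proposed: int) -> None:
        super().__init__(
            f"degenerate densification: {n_edges} edges exceeded the guard of "
            f"{guard} after {proposed} proposals"
        )
        self.n_edges = n_edges
        self.guard = guard
        self.proposed = proposed


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings for one draw.

    ``burnin_proposals`` defaults to 50 * C(N, 2); ``init`` None means the
    empty graph; ``max_edges_guard`` defaults to 8 * N (0 disables it).
    """

    burnin_proposals: int | None = None
    seed: int = 0
    init: Graph | None = None
    max_edges_guard: int | None = None
    chunk_size: int = 1 << 17

    def __post_init__(self) -> None:
        if self.burnin_proposals is not None and self.burnin_proposals < 1:
            raise ValueError("burnin_proposals must be >= 1")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


@dataclass(frozen=True)
class DrawResult:
    """One equilibrated draw: final graph, its statistic vector (maintained
    incrementally, exactly equal to a recount), and acceptance counters."""

    graph: Graph
    stats: tuple[int, ...]
    accepted: int
    proposed: int

    def __post_init__(self) -> None:
        if not (0 <= self.accepted <= self.proposed):
            raise ValueError("need 0 <= accepted <= proposed")


def default_burnin(n_nodes: int) -> int:
    """Default burn-in: 50 proposals per dyad."""
    return 50 * n_nodes * (n_nodes - 1) // 2


def mh_log_ratio(theta: ThetaVector | Sequence[float], delta: Sequence[float]) -> float:
    """log acceptance ratio theta^T dt; acceptance prob is min(1, exp(.))."""
    tvals = theta.values if isinstance(theta, ThetaVector) else np.asarray(theta, float)
    dvals = np.asarray(delta, dtype=np.float64)
    if tvals.shape != dvals.shape:
        raise ValueError(
            f"misaligned vectors: theta has {tvals.shape[0]} entries, "
            f"delta has {dvals.shape[0]}"
        )
    return float(tvals @ dvals)


def _arrays_from_graph(g: Graph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = g.n_nodes
    amat = np.zeros((n, n), dtype=np.uint8)
    nbr = np.zeros((n, n), dtype=np.int64)
    nnbr = np.zeros(n, dtype=np.int64)
    for u, v in g.edges():
        amat[u, v] = amat[v, u] = 1
        nbr[u, nnbr[u]] = v
        nnbr[u] += 1
        nbr[v, nnbr[v]] = u
        nnbr[v] += 1
    return amat, nbr, nnbr


def _graph_from_arrays(n: int, nbr: np.ndarray, nnbr: np.ndarray) -> Graph:
    g = Graph(n)
    for u in range(n):
        for i in range(int(nnbr[u])):
            v = int(nbr[u, i])
            if u < v:
                g.add_edge(u, v)
    return g


def simulate_draw_theta(
    theta: ThetaVector, n_nodes: int, config: SamplerConfig
) -> DrawResult:
    """One draw from P(g) proportional to exp(theta^T t(g))."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    spec: StatSpec = theta.spec
    codes = np.asarray([STAT_CODES[name] for name in spec.names], dtype=np.int64)
    tvals = theta.values.astype(np.float64)

    if config.init is None:
        init = Graph(n_nodes)
    else:
        if config.init.n_nodes != n_nodes:
            raise ValueError("init graph size does not match n_nodes")
        init = config.init
    amat, nbr, nnbr = _arrays_from_graph(init)
    stats = np.asarray(compute_stats(init, spec), dtype=np.int64)
    n_edges = init.n_edges

    guard = config.max_edges_guard
    if guard is None:
        guard = 8 * n_nodes
    burnin = config.burnin_proposals
    if burnin is None:
        burnin = default_burnin(n_nodes)

    rng = np.random.default_rng(config.seed)
    remaining = burnin
    accepted = 0
    proposed = 0
    while remaining > 0:
        m = min(config.chunk_size, remaining)
        us = rng.integers(0, n_nodes, size=m, dtype=np.int64)
        vs = rng.integers(0, n_nodes - 1, size=m, dtype=np.int64)
        vs += (vs >= us).astype(np.int64)
        logu = np.log(rng.random(m))
        acc, n_edges, status, consumed = _kernel.mh_chunk(
            amat, nbr, nnbr, stats, tvals, codes, us, vs, logu, guard, n_edges
        )
        accepted += int(acc)
        proposed += int(consumed)
        remaining -= int(consumed)
        if status == 1:
            raise DegeneracyError(int(n_edges), guard, proposed)

    graph = _graph_from_arrays(n_nodes, nbr, nnbr)
    return DrawResult(
        graph=graph, stats=tuple(int(x) for x in stats), accepted=accepted, proposed=proposed
    )


def simulate_draw(model: ModelSpec, n_nodes: int, config: SamplerConfig) -> DrawResult:
    """One draw from the model: phi is converted to theta at this system
    size (with the edge offset) and the chain run per ``config``."""
    theta = phi_to_theta(model, n_nodes)
    return simulate_draw_theta(theta, n_nodes, config)


def ensemble_seed(master_seed: int, rep: int) -> int:
    """Deterministic per-rep seed, keyed by rep index (not schedule)."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(rep,)).generate_state(1)[0])


def simulate_ensemble(
    model: ModelSpec,
    n_nodes: int,
    reps: int,
    master_seed: int,
    config: SamplerConfig | None = None,
) -> list[DrawResult]:
    """``reps`` independent draws with per-rep seeds derived from
    ``master_seed``; the result is independent of evaluation order."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = config if config is not None else SamplerConfig()
    out = []
    for rep in range(reps):
        cfg = replace(base, seed=ensemble_seed(master_seed, rep))
        out.append(simulate_draw(model, n_nodes, cfg))
    return out
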