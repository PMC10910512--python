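"""Hot loop for Metropolis-Hastings edge-toggle sampling.

Array-based graph state (adjacency matrix + packed neighbor lists) and
locally computed change statistics, written in a numba-compilable subset of
Python.  When numba is importable the chunk driver is JIT-compiled; the
identical source runs uncompiled otherwise, so results are bitwise equal
across the two modes.

Statistic codes: 0=edges, 1=twostar, 2=nsp1, 3=nsp2, 4=esp0, 5=esp1,
6=cycle3, 7=cycle5, 8=cycle6, 9=cycle7.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba present in supported envs
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


STAT_CODES = {
    "edges": 0,
    "twostar": 1,
    "nsp1": 2,
    "nsp2": 3,
    "esp0": 4,
    "esp1": 5,
    "cycle3": 6,
    "cycle5": 7,
    "cycle6": 8,
    "cycle7": 9,
}

_CODE_PATH_LEN = {7: 4, 8: 5, 9: 6}  # cycle k -> path length k-1


@njit(cache=True)
def _add_edge(amat, nbr, nnbr, u, v):
    amat[u, v] = 1
    amat[v, u] = 1
    nbr[u, nnbr[u]] = v
    nnbr[u] += 1
    nbr[v, nnbr[v]] = u
    nnbr[v] += 1


@njit(cache=True)
def _remove_edge(amat, nbr, nnbr, u, v):
    amat[u, v] = 0
    amat[v, u] = 0
    for a, b in ((u, v), (v, u)):
        k = nnbr[a]
        for i in range(k):
            if nbr[a, i] == b:
                nbr[a, i] = nbr[a, k - 1]
                break
        nnbr[a] = k - 1


@njit(cache=True)
def _common_count(amat, nbr, nnbr, u, w):
    a, b = (u, w) if nnbr[u] <= nnbr[w] else (w, u)
    c = 0
    for i in range(nnbr[a]):
        if amat[b, nbr[a, i]] == 1:
            c += 1
    return c


@njit(cache=True)
def _sp_scan(amat, nbr, nnbr, a, b):
    """Shared-partner reclassification deltas from node ``a`` gaining common
    neighbor ``b``: every pair (a, w) with w a neighbor of b moves up one
    shared-partner class when edge (a, b) is added."""
    d_nsp1 = d_nsp2 = d_esp0 = d_esp1 = 0
    for i in range(nnbr[b]):
        w = nbr[b, i]
        if w == a:
            continue
        cw = _common_count(amat, nbr, nnbr, a, w)
        if amat[a, w] == 1:
            if cw == 0:
                d_esp0 -= 1
                d_esp1 += 1
            elif cw == 1:
                d_esp1 -= 1
        else:
            if cw == 0:
                d_nsp1 += 1
            elif cw == 1:
                d_nsp1 -= 1
                d_nsp2 += 1
            elif cw == 2:
                d_nsp2 -= 1
    return d_nsp1, d_nsp2, d_esp0, d_esp1


@njit(cache=True)
def _count_paths(amat, nbr, nnbr, u, v, length, visited, stack_node, stack_child):
    """Simple paths u -> v with exactly ``length`` edges, v not used as an
    intermediate; iterative DFS with preallocated scratch."""
    count = 0
    visited[u] = 1
    depth = 0
    stack_node[0] = u
    stack_child[0] = 0
    while depth >= 0:
        nd = stack_node[depth]
        if depth == length - 1:
            if amat[nd, v] == 1:
                count += 1
            visited[nd] = 0
            depth -= 1
            continue
        i = stack_child[depth]
        if i < nnbr[nd]:
            stack_child[depth] += 1
            w = nbr[nd, i]
            if w != v and visited[w] == 0:
                depth += 1
                stack_node[depth] = w
                stack_child[depth] = 0
                visited[w] = 1
        else:
            visited[nd] = 0
            depth -= 1
    return count


@njit(cache=True)
def _base_delta(amat, nbr, nnbr, u, v, codes, delta, visited, stack_node, stack_child):
    """Change statistics for *adding* edge (u, v); the edge must be absent
    from the array state when called."""
    du = nnbr[u]
    dv = nnbr[v]
    c = _common_count(amat, nbr, nnbr, u, v)

    need_sp = False
    for j in range(codes.shape[0]):
        if 2 <= codes[j] <= 5:
            need_sp = True
    d_nsp1 = d_nsp2 = d_esp0 = d_esp1 = 0
    if need_sp:
        # the dyad itself moves from NSP class c to ESP class c
        if c == 0:
            d_esp0 += 1
        elif c == 1:
            d_esp1 += 1
            d_nsp1 -= 1
        elif c == 2:
            d_nsp2 -= 1
        a1, a2, a3, a4 = _sp_scan(amat, nbr, nnbr, u, v)
        b1, b2, b3, b4 = _sp_scan(amat, nbr, nnbr, v, u)
        d_nsp1 += a1 + b1
        d_nsp2 += a2 + b2
        d_esp0 += a3 + b3
        d_esp1 += a4 + b4

    for j in range(codes.shape[0]):
        cd = codes[j]
        if cd == 0:
            delta[j] = 1
        elif cd == 1:
            delta[j] = du + dv
        elif cd == 2:
            delta[j] = d_nsp1
        elif cd == 3:
            delta[j] = d_nsp2
        elif cd == 4:
            delta[j] = d_esp0
        elif cd == 5:
            delta[j] = d_esp1
        elif cd == 6:
            delta[j] = c
        elif cd == 7:
            delta[j] = _count_paths(amat, nbr, nnbr, u, v, 4, visited, stack_node, stack_child)
        elif cd == 8:
            delta[j] = _count_paths(amat, nbr, nnbr, u, v, 5, visited, stack_node, stack_child)
        else:
            delta[j] = _count_paths(amat, nbr, nnbr, u, v, 6, visited, stack_node, stack_child)


@njit(cache=True)
def mh_chunk(amat, nbr, nnbr, stats, theta, codes, us, vs, logu, max_edges, n_edges):
    """Run one chunk of uniform dyad-toggle proposals in place.

    Returns (accepted, n_edges, status, consumed); status 1 signals the
    degeneracy guard tripped after ``consumed`` proposals.
    """
    n = amat.shape[0]
    S = codes.shape[0]
    delta = np.zeros(S, dtype=np.int64)
    visited = np.zeros(n, dtype=np.uint8)
    stack_node = np.zeros(8, dtype=np.int64)
    stack_child = np.zeros(8, dtype=np.int64)
    accepted = 0
    for i in range(us.shape[0]):
        u = int(us[i])
        v = int(vs[i])
        present = amat[u, v] == 1
        if present:
            _remove_edge(amat, nbr, nnbr, u, v)
            n_edges -= 1
        _base_delta(amat, nbr, nnbr, u, v, codes, delta, visited, stack_node, stack_child)
        lr = 0.0
        for j in range(S):
            lr += theta[j] * delta[j]
        if present:
            # accept the removal with min(1, exp(-lr))
            if -lr >= 0.0 or logu[i] < -lr:
                for j in range(S):
                    stats[j] -= delta[j]
                accepted += 1
            else:
                _add_edge(amat, nbr, nnbr, u, v)
                n_edges += 1
        else:
            if lr >= 0.0 or logu[i] < lr:
                _add_edge(amat, nbr, nnbr, u, v)
                n_edges += 1
                for j in range(S):
                    stats[j] += delta[j]
                accepted += 1
                if max_edges > 0 and n_edges > max_edges:
                    return accepted, n_edges, 1, i + 1
    return accepted, n_edges, 0, us.shape[0]
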