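"""Exact minimum-error 2-splittable flow (ME2SF) solver on layered graphs.

Given a layered directed graph with one source, one sink and integer vertex
capacities, and a total integer flow value ``f``, the ME2SF problem asks for
two source-to-sink paths with integer flows ``f1 + f2 = f`` minimising the
total capacity error ``sum_v |f(v) - c(v)|`` over *all* vertices, where the
flow ``f(v)`` on a vertex sums the flows of the paths passing through it
(a vertex shared by both paths carries ``f1 + f2``) and an untouched vertex
contributes its full capacity as error.

The solver follows a packing/routing decomposition:

* *packing*: only ``|V| + 1`` candidate splits need to be considered --
  ``(c(v), f - c(v))`` for every vertex with ``c(v) < f`` plus the special
  single-path packing ``(f, 0)``.  An exchange argument (shifting flow
  between the two paths by the smallest vertex error) shows this candidate
  set always contains an optimal packing.
* *routing*: for a fixed packing, a dynamic program over ordered vertex
  pairs within each layer finds the error-minimising path pair in
  ``O(l^4 h)`` time for layer width ``l`` and ``h`` layers.

A brute-force oracle (exhaustive path pairs x all integer splits) is provided
for property testing, including a generalisation to k paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .massgraph import LayeredMassGraph

__all__ = [
    "Packing",
    "FlowSolution",
    "candidate_packings",
    "pair_error",
    "route",
    "solve_me2sf",
    "brute_force_me2sf",
    "brute_force_meksf",
]


@dataclass(frozen=True)
class Packing:
    f1: int
    f2: int

    def __post_init__(self) -> None:
        if self.f1 < 0 or self.f2 < 0:
            raise ValueError("packing flows must be nonnegative")

    @property
    def total(self) -> int:
        return self.f1 + self.f2


@dataclass(frozen=True)
class FlowSolution:
    """Two source-to-sink paths with flows and the total capacity error.

    Paths are tuples of per-layer vertex indices.  ``error`` is the
    Definition-style error summed over every vertex of the graph.
    """

    path1: tuple[int, ...]
    path2: tuple[int, ...]
    f1: int
    f2: int
    error: int

    @property
    def is_single(self) -> bool:
        return self.f2 == 0 or self.path1 == self.path2

    def recompute_error(self, graph: LayeredMassGraph) -> int:
        """Recompute sum_v |f(v) - c(v)| from the stored paths (audit)."""
        err = 0
        for i, layer in enumerate(graph.layers):
            for v in layer:
                flow = 0
                if self.path1[i] == v.index:
                    flow += self.f1
                if self.path2[i] == v.index:
                    flow += self.f2
                err += abs(flow - v.capacity)
        return err


def candidate_packings(graph: LayeredMassGraph, f: int) -> list[Packing]:
    """The candidate packing set S: (c(v), f-c(v)) per undersized vertex + (f, 0).

    Contains an optimal packing; at most ``|V| + 1`` members.  Returned in a
    deterministic order (f1 descending) used for tie-breaking.
    """
    if f < 1:
        raise ValueError("total flow must be >= 1")
    packings = {(f, 0)}
    for layer in graph.layers:
        for v in layer:
            if v.capacity < f:
                packings.add((v.capacity, f - v.capacity))
    return [Packing(a, b) for a, b in sorted(packings, key=lambda p: -p[0])]


def pair_error(v1, v2, packing: Packing) -> int:
    """Error of an ordered same-layer vertex pair under a packing.

    ``|c(v1) - f1 - f2|`` when the paths share the vertex, else
    ``|c(v1) - f1| + |c(v2) - f2|``.
    """
    if v1.layer != v2.layer:
        raise ValueError("vertex pair must lie in the same layer")
    if v1.index == v2.index:
        return abs(v1.capacity - packing.f1 - packing.f2)
    return abs(v1.capacity - packing.f1) + abs(v2.capacity - packing.f2)


def _layer_pair_error(
    caps: list[int], layer_total: int, i: int, j: int, f1: int, f2: int
) -> int:
    """Pair error plus the capacities of the untouched vertices of the layer."""
    if i == j:
        return abs(caps[i] - f1 - f2) + layer_total - caps[i]
    return abs(caps[i] - f1) + abs(caps[j] - f2) + layer_total - caps[i] - caps[j]


def route(graph: LayeredMassGraph, packing: Packing) -> FlowSolution:
    """Minimum-error path pair for a fixed packing, by DP over ordered pairs.

    ``D(v1, v2)`` is the minimum error of partial path pairs ending at the
    ordered pair ``(v1, v2)``; transitions range over predecessor pairs.
    Per-layer errors include the capacities of vertices touched by neither
    path, so ``D(t, t)`` is the full Definition error.  Ties resolve to the
    lexicographically smallest predecessor pair, making the result
    deterministic.
    """
    h = graph.n_layers
    if any(not layer for layer in graph.layers):
        raise ValueError("graph has an empty layer: no source-to-sink path")
    f1, f2 = packing.f1, packing.f2

    caps0 = graph.capacities(0)
    D_prev = [[_layer_pair_error(caps0, sum(caps0), 0, 0, f1, f2)]]
    parents: list[list[list[tuple[int, int] | None]]] = [[[None]]]

    for layer in range(1, h):
        caps = graph.capacities(layer)
        ctot = sum(caps)
        preds = graph.preds(layer)
        l = len(caps)
        D_cur = [[np.inf] * l for _ in range(l)]
        par = [[None] * l for _ in range(l)]
        for i in range(l):
            for j in range(l):
                eps = _layer_pair_error(caps, ctot, i, j, f1, f2)
                best = np.inf
                best_pq: tuple[int, int] | None = None
                for p in preds[i]:
                    row = D_prev[p]
                    for q in preds[j]:
                        d = row[q]
                        if d < best:
                            best = d
                            best_pq = (p, q)
                if best_pq is not None:
                    D_cur[i][j] = best + eps
                    par[i][j] = best_pq
        D_prev = D_cur
        parents.append(par)

    err = D_prev[0][0]
    if not np.isfinite(err):
        raise ValueError("no source-to-sink path pair exists")

    # Backtrack from (sink, sink).
    path1: list[int] = [0]
    path2: list[int] = [0]
    i, j = 0, 0
    for layer in range(h - 1, 0, -1):
        pq = parents[layer][i][j]
        assert pq is not None
        i, j = pq
        path1.append(i)
        path2.append(j)
    path1.reverse()
    path2.reverse()
    return FlowSolution(tuple(path1), tuple(path2), f1, f2, int(err))


def _canonicalize(sol: FlowSolution) -> FlowSolution:
    """Report the higher-flow path first; collapse (f, 0) to a single path."""
    if sol.f2 == 0:
        return FlowSolution(sol.path1, sol.path1, sol.f1, 0, sol.error)
    if sol.f1 < sol.f2 or (sol.f1 == sol.f2 and sol.path2 < sol.path1):
        return FlowSolution(sol.path2, sol.path1, sol.f2, sol.f1, sol.error)
    return sol


def solve_me2sf(graph: LayeredMassGraph, f: int | None = None) -> FlowSolution:
    """Exact ME2SF optimum: route every candidate packing, keep the best.

    ``f`` defaults to the graph's total flow value.  Overall complexity is
    ``O(l^4 h |V|)``.
    """
    if f is None:
        f = graph.total_flow
    best: FlowSolution | None = None
    for packing in candidate_packings(graph, f):
        sol = route(graph, packing)
        if best is None or sol.error < best.error:
            best = sol
    assert best is not None
    return _canonicalize(best)


# --------------------------------------------------------------------------
# Brute-force oracles
# --------------------------------------------------------------------------


def _path_matrix(graph: LayeredMassGraph) -> tuple[list[tuple[int, ...]], np.ndarray, np.ndarray]:
    """All s-t paths as vertex-incidence rows over a global vertex indexing."""
    offsets = []
    total = 0
    for layer in graph.layers:
        offsets.append(total)
        total += len(layer)
    caps = np.array(
        [v.capacity for layer in graph.layers for v in layer], dtype=np.int64
    )
    paths = list(graph.iter_st_paths())
    A = np.zeros((len(paths), total), dtype=np.int64)
    for r, path in enumerate(paths):
        for layer, idx in enumerate(path):
            A[r, offsets[layer] + idx] = 1
    return paths, A, caps


def brute_force_meksf(
    graph: LayeredMassGraph, f: int, k: int = 2, cap: int = 5_000_000
) -> tuple[int, tuple[tuple[tuple[int, ...], int], ...]]:
    """Exhaustive MEkSF optimum over path multisets and integer flow splits.

    Returns ``(error, ((path, flow), ...))``.  Guarded by ``cap`` on the
    enumeration size ``#paths^k * (f+1)^(k-1)``; larger instances should use
    the dynamic-programming solver.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    paths, A, caps = _path_matrix(graph)
    if not paths:
        raise ValueError("no source-to-sink path exists")
    if len(paths) ** k * (f + 1) ** (k - 1) > cap:
        raise ValueError(
            "instance too large for brute force; use the DP solver (solve_me2sf)"
        )
    base_err = None
    best = None
    splits = [
        s for s in itertools.product(range(f + 1), repeat=k) if sum(s) == f
    ]
    flows_mats = np.array(splits, dtype=np.int64)  # (n_splits, k)
    for combo in itertools.combinations_with_replacement(range(len(paths)), k):
        rows = A[list(combo)]  # (k, V)
        vertex_flows = flows_mats @ rows  # (n_splits, V)
        errs = np.abs(vertex_flows - caps).sum(axis=1)
        idx = int(errs.argmin())
        err = int(errs[idx])
        if base_err is None or err < base_err:
            base_err = err
            best = tuple(
                (paths[c], int(flows_mats[idx, pos])) for pos, c in enumerate(combo)
            )
    assert base_err is not None and best is not None
    return base_err, best


def brute_force_me2sf(
    graph: LayeredMassGraph, f: int, cap: int = 5_000_000
) -> FlowSolution:
    """Exhaustive ME2SF optimum (oracle for the DP solver)."""
    err, pairs = brute_force_meksf(graph, f, k=2, cap=cap)
    (p1, f1), (p2, f2) = pairs
    return _canonicalize(FlowSolution(p1, p2, f1, f2, err))
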