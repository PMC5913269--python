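"""Ollivier-Ricci curvature on positively weighted graphs.

For an undirected graph with edge weights ``w_xy >= 0``, each node carries a
probability measure over its neighbours,

    mu_x(y) = w_xy / d_x,    d_x = sum_z w_xz,

with no mass left on ``x`` itself.  The Ollivier-Ricci curvature of an edge
(x, y) compares the 1-Wasserstein (earth mover's) distance between the two
neighbour measures to the ground distance between the endpoints:

    k(x, y) = 1 - W1(mu_x, mu_y) / d(x, y).

The ground distance is the unweighted hop count by default (so d(x, y) = 1
for an existing edge).  The scalar curvature of a node is the sum of the edge
curvatures over its incident edges:  S_OR(x) = sum_y k(x, y).

W1 is computed exactly by solving the transportation linear program with
HiGHS.  An independent exact route — splitting rational masses into equal
atoms and solving the resulting assignment problem (the Hungarian method) —
is provided in :func:`wasserstein1_assignment` and serves as a cross-check.
"""

from __future__ import annotations

from fractions import Fraction
from math import lcm
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.sparse import coo_matrix

__all__ = [
    "neighbor_measure",
    "ground_distance",
    "wasserstein1",
    "wasserstein1_assignment",
    "edge_curvature",
    "compute_curvature",
    "scalar_curvature",
]

MASS_TOL = 1e-9  # marginal feasibility tolerance


def neighbor_measure(G: nx.Graph, x: Hashable) -> tuple[list, np.ndarray]:
    """Probability measure a node spreads over its neighbours.

    Returns the support (neighbour list, sorted for determinism) and the mass
    vector ``w_xy / d_x``.  Zero-weight edges stay in the topology but carry
    zero mass; their atoms are dropped from the support.
    """
    nbrs = sorted(G.neighbors(x))
    if not nbrs:
        raise ValueError(f"node {x!r} has no neighbors; measure undefined")
    w = np.array([G[x][z].get("weight", 1.0) for z in nbrs], dtype=float)
    if (w < 0).any() or not np.isfinite(w).all():
        raise ValueError(f"negative or non-finite edge weight at node {x!r}")
    d_x = w.sum()
    if d_x <= 0:
        raise ValueError(f"node {x!r} has zero total incident weight")
    masses = w / d_x
    keep = masses > 0
    return [z for z, k in zip(nbrs, keep) if k], masses[keep]


def ground_distance(
    G: nx.Graph, sources: Iterable[Hashable] | None = None, cutoff: int | None = None
) -> dict:
    """Hop-count shortest-path distances from each source (BFS).

    Returns ``{source: {node: hops}}``.  On a connected graph every pair is
    finite; a missing key downstream signals a disconnected pair.
    """
    if sources is None:
        sources = G.nodes
    return {
        s: dict(nx.single_source_shortest_path_length(G, s, cutoff=cutoff))
        for s in sources
    }


def _weighted_distance(G: nx.Graph, sources: Iterable[Hashable]) -> dict:
    # weighted mode: the edge weight itself is the edge length
    return {s: dict(nx.single_source_dijkstra_path_length(G, s, weight="weight")) for s in sources}


def wasserstein1(
    mu_x: tuple[list, np.ndarray],
    mu_y: tuple[list, np.ndarray],
    dist: Mapping,
    return_plan: bool = False,
):
    """Exact 1-Wasserstein cost between two discrete probability measures.

    Solves  min sum_ij pi_ij * d_ij  subject to the marginal constraints
    row-sums = mu_x, column-sums = mu_y, pi >= 0, as a linear program.

    ``dist`` maps source node -> {target node: distance} and must cover every
    support pair.  Returns the cost, or ``(cost, plan)`` where ``plan`` is the
    coupling matrix aligned with the two supports.
    """
    sup_x, a = mu_x
    sup_y, b = mu_y
    if abs(a.sum() - 1.0) > MASS_TOL or abs(b.sum() - 1.0) > MASS_TOL:
        raise ValueError("measures must sum to 1 within tolerance")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("measure masses must be non-negative")

    D = np.empty((len(sup_x), len(sup_y)))
    for i, u in enumerate(sup_x):
        du = dist[u]
        for j, v in enumerate(sup_y):
            D[i, j] = du[v]

    m, n = D.shape
    if m == 1 or n == 1:
        # forced plan: outer product of the marginals
        plan = np.outer(a, b)
        cost = float((plan * D).sum())
        return (cost, plan) if return_plan else cost

    # transportation LP over m*n variables; one marginal row is redundant but
    # HiGHS copes, and keeping both makes the plan audit exact.
    rows, cols, vals = [], [], []
    for i in range(m):
        rows.extend([i] * n)
        cols.extend(range(i * n, (i + 1) * n))
        vals.extend([1.0] * n)
    for j in range(n):
        rows.extend([m + j] * m)
        cols.extend(range(j, m * n, n))
        vals.extend([1.0] * m)
    A_eq = coo_matrix((vals, (rows, cols)), shape=(m + n, m * n))
    res = linprog(
        D.ravel(), A_eq=A_eq, b_eq=np.concatenate([a, b]), bounds=(0, None), method="highs"
    )
    if not res.success:  # pragma: no cover - HiGHS is exact on feasible instances
        raise RuntimeError(f"transport LP failed: {res.message}")
    cost = float(res.fun)
    if return_plan:
        return cost, res.x.reshape(m, n)
    return cost


def wasserstein1_assignment(
    mu_x: tuple[list, Iterable[Fraction]],
    mu_y: tuple[list, Iterable[Fraction]],
    dist: Mapping,
    max_atoms: int = 20000,
) -> float:
    """W1 by rational atom-splitting and optimal assignment (Hungarian route).

    Both measures are expanded into ``L`` equal atoms of mass ``1/L`` where
    ``L`` is the least common multiple of all mass denominators; the optimal
    coupling is then a perfect matching of atoms, solved exactly with the
    assignment algorithm.  Exact for rational masses; atom counts blow up for
    generic floats, which is why this is the cross-check route rather than
    the primary solver.
    """
    sup_x, a = mu_x
    sup_y, b = mu_y
    a = [Fraction(m) for m in a]
    b = [Fraction(m) for m in b]
    if sum(a) != 1 or sum(b) != 1:
        raise ValueError("rational masses must sum to exactly 1")
    L = lcm(*(f.denominator for f in list(a) + list(b)))
    if L > max_atoms:
        raise ValueError(f"atom count {L} exceeds max_atoms={max_atoms}")
    atoms_x = [u for u, f in zip(sup_x, a) for _ in range(int(f * L))]
    atoms_y = [v for v, f in zip(sup_y, b) for _ in range(int(f * L))]
    C = np.array([[dist[u][v] for v in atoms_y] for u in atoms_x], dtype=float)
    ri, ci = linear_sum_assignment(C)
    return float(C[ri, ci].sum() / L)


def edge_curvature(G: nx.Graph, edge: tuple, dist: Mapping | None = None) -> float:
    """Ollivier-Ricci curvature k(x,y) = 1 - W1(mu_x, mu_y) / d(x,y) of one edge."""
    x, y = edge
    if not G.has_edge(x, y):
        raise ValueError(f"edge {edge!r} not in graph")
    mu_x = neighbor_measure(G, x)
    mu_y = neighbor_measure(G, y)
    if dist is None:
        dist = ground_distance(G, sources=mu_x[0], cutoff=None)
    d_xy = dist[x][y] if x in dist and y in dist.get(x, {}) else None
    if d_xy is None:
        d_xy = nx.shortest_path_length(G, x, y)
    if d_xy <= 0:
        raise ValueError("ground distance between distinct endpoints must be positive")
    return 1.0 - wasserstein1(mu_x, mu_y, dist) / d_xy


def compute_curvature(G: nx.Graph, ground: str = "hop") -> dict[tuple, float]:
    """Edge curvatures for every edge of a connected weighted graph.

    ``ground`` selects the ground metric: ``"hop"`` (default, shortest path in
    edge count) or ``"weighted"`` (Dijkstra with the edge weight as length).
    Edges are processed in sorted order; results do not depend on the order
    since each edge's LP is independent.
    """
    if G.number_of_nodes() == 0:
        return {}
    if not nx.is_connected(G):
        raise ValueError("curvature requires a connected graph")
    if ground == "hop":
        # supports of the two endpoint measures lie within 3 hops of each other
        dist = ground_distance(G, cutoff=3)
    elif ground == "weighted":
        dist = _weighted_distance(G, G.nodes)
    else:
        raise ValueError(f"unknown ground distance mode {ground!r}")
    measures = {x: neighbor_measure(G, x) for x in G.nodes}
    out: dict[tuple, float] = {}
    for x, y in sorted(tuple(sorted(e)) for e in G.edges):
        d_xy = dist[x][y]
        k = 1.0 - wasserstein1(measures[x], measures[y], dist) / d_xy
        out[(x, y)] = k
    return out


def scalar_curvature(G: nx.Graph, edge_curv: Mapping[tuple, float]) -> dict:
    """Scalar curvature S_OR(x) = sum over neighbours y of k(x, y)."""
    S: dict = {x: 0.0 for x in G.nodes}
    for x, y in G.edges:
        key = (x, y) if (x, y) in edge_curv else (y, x)
        if key not in edge_curv:
            raise KeyError(f"missing curvature for edge ({x!r}, {y!r})")
        k = edge_curv[key]
        S[x] += k
        S[y] += k
    return S
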