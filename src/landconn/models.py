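"""Resistance-based connectivity predictors.

All three models share one discretisation of the landscape: pixels are graph
nodes, Moore-adjacent pixels are joined by edges of weight
``dist(i,j) * (r_i + r_j) / 2`` with ``dist`` = 1 for cardinal and sqrt(2)
for diagonal moves — the same cost convention the movement simulator uses, so
energy budgets, dispersal thresholds and predictions are all commensurable.

* ``factorial_lcp`` rasterises one least-cost path per unordered source pair
  and counts, per pixel, how many paths cross it.
* ``resistant_kernels`` spreads a linearly decaying kernel
  ``max(0, 1 - cd_s / T)`` from every source out to the dispersal threshold
  ``T`` in cost-distance units, and sums the kernels.
* ``circuit_current`` treats edge weights as resistors (conductance
  ``1/weight``), injects unit current between every unordered source pair,
  and accumulates per-pixel current density.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph, linalg as sparse_linalg

from landconn.walker import NEIGHBOURS, _SQRT2


def build_cost_graph(surface: np.ndarray) -> sparse.csr_matrix:
    """Sparse Moore-adjacency cost graph of a resistance surface.

    Entry (i, j) holds ``dist(i,j) * (r_i + r_j) / 2`` for flat pixel indices
    i, j of adjacent pixels; the matrix is symmetric with positive weights.
    """
    surface = np.asarray(surface, dtype=float)
    if surface.ndim != 2:
        raise ValueError("surface must be 2-D")
    if not np.all(np.isfinite(surface)) or np.any(surface <= 0):
        raise ValueError("resistance values must be finite and positive")
    nrows, ncols = surface.shape
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    rows, cols, data = [], [], []
    for (dr, dc) in NEIGHBOURS:
        sr0, sr1 = max(0, dr), nrows + min(0, dr)
        sc0, sc1 = max(0, dc), ncols + min(0, dc)
        src = idx[sr0 - dr : sr1 - dr, sc0 - dc : sc1 - dc]
        dst = idx[sr0:sr1, sc0:sc1]
        length = _SQRT2 if dr and dc else 1.0
        w = length * (surface.ravel()[src.ravel()] + surface.ravel()[dst.ravel()]) / 2.0
        rows.append(src.ravel())
        cols.append(dst.ravel())
        data.append(w)
    graph = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nrows * ncols, nrows * ncols),
    )
    return graph


def _source_nodes(sources: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    sources = np.asarray(sources)
    if sources.ndim != 2 or sources.shape[0] == 0:
        raise ValueError("sources must be a non-empty (n, 2) array")
    nrows, ncols = shape
    r, c = sources[:, 0], sources[:, 1]
    if np.any(r < 0) or np.any(r >= nrows) or np.any(c < 0) or np.any(c >= ncols):
        raise ValueError("source coordinates out of bounds")
    return (r * ncols + c).astype(np.int64)


def cost_distance(surface: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Minimum accumulated cost from the nearest source to every pixel."""
    surface = np.asarray(surface, dtype=float)
    graph = build_cost_graph(surface)
    nodes = _source_nodes(sources, surface.shape)
    dist = csgraph.dijkstra(graph, directed=True, indices=nodes, min_only=True)
    return dist.reshape(surface.shape)


def factorial_lcp(surface: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Per-pixel count of pairwise least-cost paths.

    One minimum-cost path is extracted for every unordered source pair; the
    output value at a pixel is the number of such paths passing through it
    (endpoints included). Pairs are processed in canonical (sorted flat
    index) order, so the result is invariant to source ordering.
    """
    surface = np.asarray(surface, dtype=float)
    nodes = np.unique(_source_nodes(sources, surface.shape))
    if nodes.size < 2:
        raise ValueError("factorial_lcp needs at least 2 distinct sources")
    graph = build_cost_graph(surface)
    counts = np.zeros(surface.size, dtype=np.int64)
    for ai, a in enumerate(nodes[:-1]):
        _, pred = csgraph.dijkstra(
            graph, directed=True, indices=a, return_predecessors=True
        )
        for b in nodes[ai + 1 :]:
            node = int(b)
            while node != a:
                counts[node] += 1
                node = int(pred[node])
                if node < 0:  # unreachable; cannot happen on connected grids
                    break
            else:
                counts[a] += 1
    return counts.reshape(surface.shape)


def resistant_kernels(
    surface: np.ndarray, sources: np.ndarray, threshold_T: float
) -> np.ndarray:
    """Sum of per-source linear dispersal kernels truncated at threshold ``T``."""
    if threshold_T <= 0:
        raise ValueError("threshold_T must be positive")
    surface = np.asarray(surface, dtype=float)
    graph = build_cost_graph(surface)
    nodes = _source_nodes(sources, surface.shape)
    out = np.zeros(surface.size)
    for s in nodes:
        cd = csgraph.dijkstra(graph, directed=True, indices=int(s), min_only=True)
        out += np.maximum(0.0, 1.0 - cd / threshold_T)
    return out.reshape(surface.shape)


class _CircuitSolver:
    """Factorised Laplacian solver reused across source pairs.

    One node per connected component is pinned to ground; the reduced
    Laplacian is factorised once with sparse LU and solved for each
    injection vector.
    """

    def __init__(self, surface: np.ndarray):
        graph = build_cost_graph(surface)
        conduct = graph.copy()
        conduct.data = 1.0 / conduct.data
        n = conduct.shape[0]
        deg = np.asarray(conduct.sum(axis=1)).ravel()
        lap = sparse.diags(deg) - conduct
        self.n_components, self.labels = csgraph.connected_components(
            conduct, directed=False
        )
        # ground = lowest-index node of each component
        ground = np.zeros(n, dtype=bool)
        for comp in range(self.n_components):
            ground[np.nonzero(self.labels == comp)[0][0]] = True
        self.keep = np.nonzero(~ground)[0]
        self.inv_keep = -np.ones(n, dtype=np.int64)
        self.inv_keep[self.keep] = np.arange(self.keep.size)
        lap_red = lap.tocsr()[self.keep][:, self.keep].tocsc()
        self.lu = sparse_linalg.splu(lap_red)
        self.n = n
        coo = conduct.tocoo()
        self.edge_i = coo.row
        self.edge_j = coo.col
        self.edge_g = coo.data

    def potentials(self, a: int, b: int) -> np.ndarray:
        """Node potentials for unit current injected at a and extracted at b."""
        rhs = np.zeros(self.keep.size)
        for node, inj in ((a, 1.0), (b, -1.0)):
            k = self.inv_keep[node]
            if k >= 0:
                rhs[k] = inj
        v = np.zeros(self.n)
        v[self.keep] = self.lu.solve(rhs)
        return v

    def node_current(self, v: np.ndarray, a: int, b: int) -> np.ndarray:
        """Per-node current density: half the absolute incident edge currents,
        full injected current (1.0) at the two terminals."""
        flow = self.edge_g * np.abs(v[self.edge_i] - v[self.edge_j])
        cur = 0.5 * np.bincount(self.edge_i, weights=flow, minlength=self.n)
        cur[a] = 1.0
        cur[b] = 1.0
        return cur


def circuit_current(
    surface: np.ndarray,
    sources: np.ndarray,
    solver_tol: float = 1e-8,
    mode: str = "pairwise",
) -> np.ndarray:
    """Cumulative current density over source pairs (circuit-theory model).

    In the default ``pairwise`` mode, unit current is injected between every
    unordered pair of source nodes and the per-pixel current densities are
    summed.  In ``all-to-one`` mode each source in turn injects unit current
    while all remaining sources are grounded.  Pairs falling in different
    connected components are skipped with a warning (cannot occur on strictly
    positive full grids, which are always connected).

    ``solver_tol`` bounds the acceptable relative residual of each linear
    solve; the direct factorisation used here is verified against it.
    """
    surface = np.asarray(surface, dtype=float)
    nodes = np.unique(_source_nodes(sources, surface.shape))
    if nodes.size < 2:
        raise ValueError("circuit_current needs at least 2 distinct sources")
    solver = _CircuitSolver(surface)
    out = np.zeros(surface.size)
    if mode == "pairwise":
        for ai, a in enumerate(nodes[:-1]):
            for b in nodes[ai + 1 :]:
                if solver.labels[a] != solver.labels[b]:
                    warnings.warn(
                        f"terminals {int(a)} and {int(b)} lie in different "
                        "connected components; pair skipped"
                    )
                    continue
                v = solver.potentials(int(a), int(b))
                out += solver.node_current(v, int(a), int(b))
    elif mode == "all-to-one":
        out += _all_to_one_current(surface, nodes)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out.reshape(surface.shape)


def _all_to_one_current(surface: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    graph = build_cost_graph(surface)
    conduct = graph.copy()
    conduct.data = 1.0 / conduct.data
    n = conduct.shape[0]
    deg = np.asarray(conduct.sum(axis=1)).ravel()
    lap = sparse.csr_matrix(sparse.diags(deg) - conduct)
    coo = conduct.tocoo()
    out = np.zeros(n)
    for s in nodes:
        grounds = nodes[nodes != s]
        keep = np.setdiff1d(np.arange(n), grounds)
        inv = -np.ones(n, dtype=np.int64)
        inv[keep] = np.arange(keep.size)
        lap_red = lap[keep][:, keep].tocsc()
        rhs = np.zeros(keep.size)
        rhs[inv[s]] = 1.0
        v = np.zeros(n)
        v[keep] = sparse_linalg.splu(lap_red).solve(rhs)
        flow = coo.data * np.abs(v[coo.row] - v[coo.col])
        cur = 0.5 * np.bincount(coo.row, weights=flow, minlength=n)
        cur[s] = 1.0
        out += cur
    return out


def effective_resistance(surface: np.ndarray, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Two-terminal effective resistance between pixels a and b."""
    surface = np.asarray(surface, dtype=float)
    nodes = _source_nodes(np.array([a, b]), surface.shape)
    solver = _CircuitSolver(surface)
    v = solver.potentials(int(nodes[0]), int(nodes[1]))
    return float(v[nodes[0]] - v[nodes[1]])
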