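"""Euclidean and least-cost-path ("ecological") distance matrices.

A non-Euclidean detection model replaces straight-line distance between an
activity center and a detector with the accumulated cost of the cheapest
grid path across a resistance surface.  The grid graph connects each cell to
its 8 queen neighbours (optionally plus the 8 knight moves, giving 16
directions) and weights each edge by the true step length times the mean of
the two endpoint-cell costs — the conductance-raster convention restated in
graph terms, with geometric correction implicit in the true diagonal/knight
step lengths.

Because the resistance coefficient alpha2 is estimated inside the
likelihood, the distance matrix must be cheap to recompute: the graph
topology and step lengths are built once per raster, only the edge weights
are refreshed when alpha2 changes, and resulting matrices are memoized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist

from .raster import CostRaster

# queen moves (8 directions) and knight moves (adding up to 16)
_QUEEN = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_KNIGHT = [(-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1)]


@dataclass
class DistanceMatrix:
    """Distances from a set of source points to a set of target points."""

    d: np.ndarray  # (n_from, n_to), metres or cost-weighted metres
    from_points: np.ndarray
    to_points: np.ndarray

    @property
    def unreachable(self) -> np.ndarray:
        """Boolean mask of pairs with no finite-cost path."""
        return ~np.isfinite(self.d)


def euclidean_distance_matrix(from_points, to_points) -> DistanceMatrix:
    """Straight-line distances between two point sets (projected metres)."""
    a = np.atleast_2d(np.asarray(from_points, dtype=float))
    b = np.atleast_2d(np.asarray(to_points, dtype=float))
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("coordinates must be finite")
    return DistanceMatrix(cdist(a, b), a, b)


class LcpGraph:
    """Reusable grid graph over a scaled covariate raster.

    Builds the edge list (cell pairs + step lengths) once; per-alpha2
    shortest-path solves reuse it with refreshed weights.  Points snap to
    the center of their containing cell before lookup.
    """

    def __init__(self, covariate: CostRaster, directions: int = 16):
        if directions not in (8, 16):
            raise ValueError("directions must be 8 or 16")
        self.raster = covariate
        self.directions = directions
        nr, nc = covariate.nrows, covariate.ncols
        self.n_nodes = nr * nc
        valid = ~covariate.nodata_mask

        moves = _QUEEN + (_KNIGHT if directions == 16 else [])
        # keep one orientation of each move; graph treated as undirected
        half = [(dr, dc) for dr, dc in moves if dr > 0 or (dr == 0 and dc > 0)]
        rows, cols = np.indices((nr, nc))
        src_list, dst_list, step_list = [], [], []
        for dr, dc in half:
            r0 = slice(max(0, -dr), min(nr, nr - dr))
            c0 = slice(max(0, -dc), min(nc, nc - dc))
            r1 = slice(max(0, dr), min(nr, nr + dr))
            c1 = slice(max(0, dc), min(nc, nc + dc))
            ok = valid[r0, c0] & valid[r1, c1]
            a = (rows[r0, c0] * nc + cols[r0, c0])[ok]
            b = (rows[r1, c1] * nc + cols[r1, c1])[ok]
            src_list.append(a)
            dst_list.append(b)
            step_list.append(
                np.full(a.size, covariate.cellsize * np.hypot(dr, dc))
            )
        self._src = np.concatenate(src_list) if src_list else np.empty(0, int)
        self._dst = np.concatenate(dst_list) if dst_list else np.empty(0, int)
        self._step = np.concatenate(step_list) if step_list else np.empty(0)
        self._z_flat = covariate.values.ravel()
        # CSR structure is fixed; per-alpha2 solves only swap edge weights.
        # Store the COO->CSR data permutation via an index-valued build.
        order = csr_matrix((np.arange(len(self._src), dtype=float),
                            (self._src, self._dst)),
                           shape=(self.n_nodes, self.n_nodes))
        self._csr = order
        self._perm = order.data.astype(int)

    def snap(self, points) -> np.ndarray:
        """Node indices of the cells containing the given points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.empty(len(pts), dtype=int)
        for i, (x, y) in enumerate(pts):
            r, c = self.raster.index_of(x, y)
            if np.isnan(self.raster.values[r, c]):
                raise ValueError(f"point ({x}, {y}) falls on a nodata cell")
            idx[i] = r * self.raster.ncols + c
        return idx

    def edge_weights(self, alpha2: float) -> np.ndarray:
        cost = np.exp(alpha2 * self._z_flat)
        return self._step * 0.5 * (cost[self._src] + cost[self._dst])

    def distances(self, source_nodes: np.ndarray, alpha2: float = 0.0) -> np.ndarray:
        """Least accumulated cost from each source node to every node."""
        self._csr.data = self.edge_weights(alpha2)[self._perm]
        return dijkstra(self._csr, directed=False, indices=source_nodes)


def lcp_distance_matrix(cost: CostRaster, from_points, to_points,
                        directions: int = 16, alpha2: float = 0.0,
                        graph: LcpGraph | None = None) -> DistanceMatrix:
    """Least-cost-path distances between two point sets over a cost surface.

    ``cost`` holds the scaled covariate z; the per-cell traversal cost is
    ``exp(alpha2 * z)`` so a uniform covariate with alpha2 = 0 reduces to
    plain grid-geodesic distance in metres.  Unreachable pairs (separated
    by nodata) are returned as ``inf`` and flagged via
    :attr:`DistanceMatrix.unreachable`.
    """
    if graph is None:
        graph = LcpGraph(cost, directions=directions)
    a = np.atleast_2d(np.asarray(from_points, dtype=float))
    b = np.atleast_2d(np.asarray(to_points, dtype=float))
    from_nodes = graph.snap(a)
    to_nodes = graph.snap(b)
    # run Dijkstra from whichever side has fewer unique cells
    uniq_to, inv_to = np.unique(to_nodes, return_inverse=True)
    uniq_from, inv_from = np.unique(from_nodes, return_inverse=True)
    if len(uniq_to) <= len(uniq_from):
        dist = graph.distances(uniq_to, alpha2)  # (n_to_uniq, n_nodes)
        d = dist[:, from_nodes][inv_to, :].T
    else:
        dist = graph.distances(uniq_from, alpha2)
        d = dist[:, to_nodes][inv_from, :]
    return DistanceMatrix(d, a, b)


class LcpDistanceCache:
    """Memoized mesh-to-detector distances as a function of alpha2.

    Used inside likelihood maximization, where line searches and numeric
    gradients repeatedly re-evaluate nearby alpha2 values.
    """

    def __init__(self, covariate: CostRaster, mesh_points, trap_points,
                 directions: int = 16):
        self.graph = LcpGraph(covariate, directions=directions)
        self.mesh_points = np.atleast_2d(np.asarray(mesh_points, float))
        self.trap_points = np.atleast_2d(np.asarray(trap_points, float))
        self._mesh_nodes = self.graph.snap(self.mesh_points)
        self._trap_nodes = self.graph.snap(self.trap_points)
        self._uniq_traps, self._inv = np.unique(self._trap_nodes,
                                                return_inverse=True)
        self._cache: dict[float, np.ndarray] = {}

    def matrix(self, alpha2: float) -> np.ndarray:
        """(n_mesh, n_traps) cost-weighted distances at the given alpha2."""
        key = round(float(alpha2), 12)
        if key not in self._cache:
            dist = self.graph.distances(self._uniq_traps, alpha2)
            self._cache[key] = dist[:, self._mesh_nodes][self._inv, :].T
        return self._cache[key]
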