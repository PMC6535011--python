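"""Circuit-theory landscape connectivity and isolation-by-resistance.

Landscape layers are reclassified to resistance cost surfaces (costs in
[1, 100]), discretized to a conductance-weighted grid graph (edge
conductance = mean of the two cells' conductances, diagonal edges divided
by sqrt(2)), and solved as an electrical network: pairwise effective
resistances come from sparse graph-Laplacian solves, and per-cell current
density maps the predicted density of movement between source (hot-dry)
and target (cold-wet) locations — the evolutionary-rescue surface.

Genetic differentiation (linearized F_ST) is regressed on resistance
distance with a Mantel test plus ordinary least squares; candidate
surfaces are ranked by R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from scipy.stats import pearsonr

from .rasters import Raster

__all__ = [
    "ResistanceSurface",
    "RasterGraph",
    "ResistanceDistanceMatrix",
    "CurrentDensityMap",
    "IBRRegressionResult",
    "reclassify_to_resistance",
    "combine_surfaces",
    "build_graph",
    "graph_from_edges",
    "effective_resistance",
    "current_density",
    "mantel_test",
    "ibr_regression",
    "rank_surfaces",
    "rescue_potential",
]

COST_MIN, COST_MAX = 1.0, 100.0


@dataclass
class ResistanceSurface:
    """Movement-cost grid; valid cells carry costs in [1, 100]."""

    raster: Raster
    provenance: str = ""

    def __post_init__(self) -> None:
        vals = self.raster.valid_values()
        if vals.size and (vals.min() < COST_MIN - 1e-9 or vals.max() > COST_MAX + 1e-9):
            raise ValueError("resistance costs must lie in [1, 100]")


@dataclass
class RasterGraph:
    """Conductance-weighted grid graph over valid raster cells."""

    laplacian: sparse.csr_matrix
    node_of_cell: np.ndarray        # grid of node indices, -1 for nodata
    cells_of_node: np.ndarray       # (n_nodes, 2) row/col per node
    edges: np.ndarray               # (n_edges, 2) node pairs
    conductances: np.ndarray        # (n_edges,)
    shape: tuple[int, int]

    @property
    def n_nodes(self) -> int:
        return self.cells_of_node.shape[0]


@dataclass
class ResistanceDistanceMatrix:
    """Pairwise effective resistances between focal nodes."""

    values: np.ndarray
    focal_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CurrentDensityMap:
    """Per-cell current magnitude accumulated over source-target pairs."""

    raster: Raster
    sources: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)


@dataclass
class IBRRegressionResult:
    """Mantel correlation and OLS fit of genetic vs resistance distance."""

    surface: str
    mantel_r: float
    mantel_p: float
    r_squared: float
    slope: float
    intercept: float
    n_pairs: int


# ---------------------------------------------------------------------------
# Resistance surfaces
# ---------------------------------------------------------------------------

def reclassify_to_resistance(
    layer: Raster,
    table: list[tuple[float, float]],
    interpolate: bool = False,
    provenance: str = "",
) -> ResistanceSurface:
    """Map layer values to movement costs via a breakpoint -> cost table.

    ``table`` is a list of (breakpoint, cost) pairs sorted by breakpoint.
    Piecewise-constant by default (a cell takes the cost of the last
    breakpoint <= its value; values below the first breakpoint take the
    first cost); with ``interpolate=True``, costs are linearly interpolated
    between breakpoints.  Nodata propagates.
    """
    if not table:
        raise ValueError("empty reclassification table")
    breaks = np.array([b for b, _ in table], dtype=float)
    costs = np.array([c for _, c in table], dtype=float)
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("breakpoints must be strictly increasing")
    if costs.min() < COST_MIN or costs.max() > COST_MAX:
        raise ValueError(f"costs must lie in [{COST_MIN:g}, {COST_MAX:g}]")
    valid = layer.valid_mask
    vals = layer.values[valid]
    if interpolate:
        out = np.interp(vals, breaks, costs)
    else:
        idx = np.clip(np.searchsorted(breaks, vals, side="right") - 1, 0, breaks.size - 1)
        out = costs[idx]
    values = np.full(layer.shape, layer.nodata)
    values[valid] = out
    return ResistanceSurface(layer.copy_with(values), provenance=provenance)


def combine_surfaces(
    surfaces: list[ResistanceSurface], method: str = "mean", provenance: str = ""
) -> ResistanceSurface:
    """Cellwise combination of resistance surfaces, rescaled into [1, 100].

    Methods: ``mean`` (default; already in range, left untouched),
    ``sum_rescaled`` and ``product_rescaled`` (affinely rescaled to span
    [1, 100]; a constant combination maps to the midpoint 50.5).
    """
    if not surfaces:
        raise ValueError("need at least one surface")
    first = surfaces[0].raster
    valid = first.valid_mask.copy()
    stack_vals = []
    for s in surfaces:
        if not s.raster.same_geometry(first):
            raise ValueError("surfaces are not co-registered")
        valid &= s.raster.valid_mask
        stack_vals.append(s.raster.values)
    arr = np.stack(stack_vals)
    if method == "mean":
        combo = arr.mean(axis=0)
        out = combo
    elif method in ("sum_rescaled", "product_rescaled"):
        combo = arr.sum(axis=0) if method == "sum_rescaled" else arr.prod(axis=0)
        v = combo[valid]
        span = v.max() - v.min()
        if span > 0:
            out = np.full_like(combo, np.nan)
            out[valid] = COST_MIN + (v - v.min()) / span * (COST_MAX - COST_MIN)
        else:
            out = np.full_like(combo, 0.5 * (COST_MIN + COST_MAX))
    else:
        raise ValueError(f"unknown combination method {method!r}")
    values = np.full(first.shape, first.nodata)
    values[valid] = out[valid]
    return ResistanceSurface(first.copy_with(values), provenance=provenance or method)


# ---------------------------------------------------------------------------
# Graph construction and Laplacian solves
# ---------------------------------------------------------------------------

def graph_from_edges(
    n_nodes: int, edges: np.ndarray, conductances: np.ndarray
) -> RasterGraph:
    """Build a :class:`RasterGraph` from an explicit edge list.

    Useful for arbitrary electrical networks (series/parallel circuits,
    random graphs) that do not come from a raster; nodes are laid out on a
    1 x n_nodes pseudo-grid."""
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    conductances = np.asarray(conductances, dtype=float)
    if (conductances <= 0).any():
        raise ValueError("conductances must be positive")
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.concatenate([conductances, conductances])
    A = sparse.coo_matrix((w, (i, j)), shape=(n_nodes, n_nodes)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sparse.diags(deg) - A
    node_of_cell = np.arange(n_nodes, dtype=int)[None, :]
    cells = np.column_stack([np.zeros(n_nodes, dtype=int), np.arange(n_nodes)])
    return RasterGraph(L.tocsr(), node_of_cell, cells, edges, conductances, (1, n_nodes))


def build_graph(surface: ResistanceSurface, connectivity: int = 8) -> RasterGraph:
    """Discretize a resistance surface into a conductance-weighted graph.

    One node per valid cell; edges connect 8- (or 4-) neighbors with
    conductance equal to the mean of the two cells' conductances (1/cost);
    diagonal edge conductances are divided by sqrt(2) to correct for edge
    length.  Nodata cells are isolated (no node).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    r = surface.raster
    valid = r.valid_mask
    nrows, ncols = r.shape
    node_of_cell = np.full((nrows, ncols), -1, dtype=int)
    cells = np.argwhere(valid)
    node_of_cell[cells[:, 0], cells[:, 1]] = np.arange(cells.shape[0])
    cond_cell = np.zeros((nrows, ncols))
    cond_cell[valid] = 1.0 / r.values[valid]

    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    edge_list = []
    cond_list = []
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows + min(0, dr) or None)
        c1 = slice(max(0, dc), ncols + min(0, dc) or None)
        a = node_of_cell[r0, c0]
        b = node_of_cell[r1, c1]
        ok = (a >= 0) & (b >= 0)
        g = 0.5 * (cond_cell[r0, c0] + cond_cell[r1, c1])
        if dr != 0 and dc != 0:
            g = g / np.sqrt(2.0)
        edge_list.append(np.column_stack([a[ok], b[ok]]))
        cond_list.append(g[ok])
    edges = np.vstack(edge_list) if edge_list else np.empty((0, 2), dtype=int)
    conductances = np.concatenate(cond_list) if cond_list else np.empty(0)

    n = cells.shape[0]
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.concatenate([conductances, conductances])
    A = sparse.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sparse.diags(deg) - A
    return RasterGraph(L.tocsr(), node_of_cell, cells, edges, conductances, (nrows, ncols))


def _components(graph: RasterGraph) -> np.ndarray:
    n = graph.n_nodes
    adj = sparse.coo_matrix(
        (np.ones(graph.edges.shape[0]), (graph.edges[:, 0], graph.edges[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def _grounded_solver(graph: RasterGraph, ground: int):
    """LU factorization of the Laplacian with one node grounded."""
    n = graph.n_nodes
    keep = np.arange(n) != ground
    L = graph.laplacian.tocsc()[keep][:, keep]
    lu = splu(L.tocsc())
    index_map = np.cumsum(keep) - 1  # node -> reduced index

    def solve(injection: np.ndarray) -> np.ndarray:
        """Solve L v = injection (injection must sum to 0); v[ground] = 0."""
        v = np.zeros(n)
        v[keep] = lu.solve(injection[keep])
        return v

    return solve, index_map


def effective_resistance(
    graph: RasterGraph, focal_nodes: list[int], focal_ids: list[str] | None = None
) -> ResistanceDistanceMatrix:
    """Pairwise effective resistances between focal nodes.

    For each pair, a unit current is injected at one node and extracted at
    the other (one node grounded) and the voltage difference read off.
    Pairs in different connected components get infinite distance (with a
    warning)."""
    focal = list(focal_nodes)
    k = len(focal)
    if focal_ids is None:
        focal_ids = [str(f) for f in focal]
    labels = _components(graph)
    R = np.zeros((k, k))
    solvers: dict[int, object] = {}
    for a in range(k):
        for b in range(a + 1, k):
            i, j = focal[a], focal[b]
            if labels[i] != labels[j]:
                warnings.warn(
                    f"focal nodes {focal_ids[a]} and {focal_ids[b]} are disconnected",
                    stacklevel=2,
                )
                R[a, b] = R[b, a] = np.inf
                continue
            comp = labels[i]
            if comp not in solvers:
                ground = int(np.flatnonzero(labels == comp)[0])
                solvers[comp] = _grounded_solver(graph, ground)[0]
            injection = np.zeros(graph.n_nodes)
            injection[i] = 1.0
            injection[j] = -1.0
            v = solvers[comp](injection)
            R[a, b] = R[b, a] = v[i] - v[j]
    return ResistanceDistanceMatrix(R, focal_ids)


def current_density(
    graph: RasterGraph,
    sources: list[int],
    targets: list[int],
    nodata: float = -9999.0,
    source_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> CurrentDensityMap:
    """Accumulated per-cell current over all source-target pairs.

    For each (source, target) pair a unit current is injected and the cell
    current is half the sum of absolute incident branch currents; maps are
    summed over pairs with equal weight.  Self-pairs (source == target) are
    skipped; disconnected pairs contribute nothing (warning)."""
    labels = _components(graph)
    total = np.zeros(graph.n_nodes)
    solvers: dict[int, object] = {}
    e0, e1 = graph.edges[:, 0], graph.edges[:, 1]
    for s in sources:
        for t in targets:
            if s == t:
                continue
            if labels[s] != labels[t]:
                warnings.warn("disconnected source-target pair skipped", stacklevel=2)
                continue
            comp = labels[s]
            if comp not in solvers:
                ground = int(np.flatnonzero(labels == comp)[0])
                solvers[comp] = _grounded_solver(graph, ground)[0]
            injection = np.zeros(graph.n_nodes)
            injection[s] = 1.0
            injection[t] = -1.0
            v = solvers[comp](injection)
            branch = graph.conductances * np.abs(v[e0] - v[e1])
            node_current = np.zeros(graph.n_nodes)
            np.add.at(node_current, e0, branch)
            np.add.at(node_current, e1, branch)
            total += 0.5 * node_current
    values = np.full(graph.shape, nodata)
    values[graph.cells_of_node[:, 0], graph.cells_of_node[:, 1]] = total
    raster = Raster(values, nodata=nodata)
    return CurrentDensityMap(
        raster,
        sources=source_ids or [str(s) for s in sources],
        targets=target_ids or [str(t) for t in targets],
    )


# ---------------------------------------------------------------------------
# Isolation-by-resistance regression
# ---------------------------------------------------------------------------

def _upper(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    A: np.ndarray, B: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over the off-diagonal upper triangle; the
    one-sided p-value permutes rows/columns of B simultaneously."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and conformable")
    a = _upper(A)
    r_obs = pearsonr(a, _upper(B))[0]
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = pearsonr(a, _upper(B[np.ix_(perm, perm)]))[0]
        if r_perm >= r_obs:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return float(r_obs), float(p)


def ibr_regression(
    genetic: np.ndarray,
    resistance: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    surface: str = "",
) -> IBRRegressionResult:
    """Regress linearized genetic distance on resistance distance.

    Mantel r with permutation p, plus OLS slope/intercept/R^2 over the
    off-diagonal pairs."""
    r, p = mantel_test(genetic, resistance, n_perm=n_perm, seed=seed)
    y = _upper(np.asarray(genetic, float))
    x = _upper(np.asarray(resistance, float))
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ coef
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return IBRRegressionResult(
        surface=surface,
        mantel_r=r,
        mantel_p=p,
        r_squared=r2,
        slope=float(coef[1]),
        intercept=float(coef[0]),
        n_pairs=x.size,
    )


def rank_surfaces(
    genetic: np.ndarray,
    resistance_by_surface: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
) -> list[IBRRegressionResult]:
    """Fit the IBR regression against each candidate surface; rank by R^2."""
    results = [
        ibr_regression(genetic, R, n_perm=n_perm, seed=seed, surface=name)
        for name, R in resistance_by_surface.items()
    ]
    return sorted(results, key=lambda r: r.r_squared, reverse=True)


# ---------------------------------------------------------------------------
# Evolutionary rescue
# ---------------------------------------------------------------------------

def rescue_potential(
    best_surface: ResistanceSurface,
    source_cells: list[tuple[int, int]],
    target_cells: list[tuple[int, int]],
    connectivity: int = 8,
    source_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> tuple[CurrentDensityMap, dict[str, float]]:
    """Gene-flow potential from hot-dry sources to cold-wet targets.

    Returns the accumulated current-density map plus, per target, the mean
    effective resistance from all sources — low values mean evolutionary
    rescue is plausible."""
    if not source_cells:
        raise ValueError("need at least one hot_dry source location")
    if not target_cells:
        raise ValueError("need at least one cold_wet target location")
    graph = build_graph(best_surface, connectivity=connectivity)
    to_node = lambda rc: int(graph.node_of_cell[rc[0], rc[1]])
    src_nodes = [to_node(rc) for rc in source_cells]
    tgt_nodes = [to_node(rc) for rc in target_cells]
    if any(n < 0 for n in src_nodes + tgt_nodes):
        raise ValueError("a focal location falls on a nodata cell")
    source_ids = source_ids or [f"src{i}" for i in range(len(src_nodes))]
    target_ids = target_ids or [f"tgt{i}" for i in range(len(tgt_nodes))]

    cmap = current_density(
        graph,
        src_nodes,
        tgt_nodes,
        nodata=best_surface.raster.nodata,
        source_ids=source_ids,
        target_ids=target_ids,
    )
    focal = src_nodes + tgt_nodes
    R = effective_resistance(graph, focal, focal_ids=source_ids + target_ids)
    ns = len(src_nodes)
    summary = {}
    for k, tid in enumerate(target_ids):
        pair_r = [
            R.values[i, ns + k] for i in range(ns) if src_nodes[i] != tgt_nodes[k]
        ]
        summary[tid] = float(np.mean(pair_r)) if pair_r else 0.0
    return cmap, summary
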