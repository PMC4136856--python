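"""Circuit-theory connectivity: the landscape as a resistor network.

Every passable cell is a node; each 8-neighbour edge gets resistance equal
to its least-cost edge weight (mean cell cost x step length), so the
circuit and least-cost analyses share one cost surface and are directly
comparable.  Injecting current between terminal sets and solving Kirchhoff's
equations (sparse graph Laplacian with the ground fixed at zero) yields node
potentials, per-cell current density — high current marks likely movement —
and the effective resistance between populations.  Omnidirectional maps
follow the buffered-perimeter approach: the surface is padded with a
uniform-cost ring, focal nodes are spread along the ring, and current maps
over node pairs are summed before cropping the buffer away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csgraph
from scipy.sparse.linalg import factorized

from .connectivity import CostSurface, grid_edges
from .grid import RasterGrid


@dataclass
class ConductanceGraph:
    """Sparse resistor network over the passable cells of a cost surface."""

    grid: RasterGrid
    node_of: np.ndarray        # flat cell index -> node id (-1 impassable)
    cells: np.ndarray          # node id -> (row, col)
    edge_i: np.ndarray
    edge_j: np.ndarray
    conductance: np.ndarray
    laplacian: "object"
    component: np.ndarray      # node id -> connected-component label

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    def node(self, cell: tuple[int, int]) -> int:
        n = int(self.node_of[cell[0] * self.grid.n_cols + cell[1]])
        if n < 0:
            raise ValueError(f"cell {cell} is impassable")
        return n


def build_conductance_graph(cost: CostSurface) -> ConductanceGraph:
    """Conductance g = 1 / (mean cell cost x step length) per 8-neighbour
    edge; nodata cells excluded; Laplacian rows sum to zero."""
    g = cost.grid
    passable = g.valid_mask.ravel()
    if passable.sum() < 2:
        raise ValueError("need at least two passable cells")
    node_of = np.full(passable.size, -1, dtype=int)
    node_of[passable] = np.arange(passable.sum())
    cells = np.argwhere(g.valid_mask)
    fi, fj, w = grid_edges(cost)
    i, j = node_of[fi], node_of[fj]
    cond = 1.0 / w
    n = passable.sum()
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([-cond, -cond, cond, cond])
    lap = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    n_comp, labels = csgraph.connected_components(
        coo_matrix((cond, (i, j)), shape=(n, n)), directed=False)
    return ConductanceGraph(g, node_of, cells, i, j, cond, lap, labels)


@dataclass
class CircuitResult:
    potentials: np.ndarray       # per node, ground fixed at 0
    current_map: RasterGrid      # per-cell current density
    effective_resistance: float
    source_cells: list
    ground_cells: list
    kirchhoff_residual: float    # max |net current| at non-terminal nodes


def _current_density(graph: ConductanceGraph, v: np.ndarray,
                     injected: np.ndarray) -> RasterGrid:
    """Per-cell current density: half the summed |branch current| over
    incident edges, plus half the |injected| current at terminal nodes
    (so terminals carry their share of the flow they source or sink)."""
    branch = graph.conductance * (v[graph.edge_i] - v[graph.edge_j])
    node_cur = np.zeros(graph.n_nodes)
    np.add.at(node_cur, graph.edge_i, np.abs(branch))
    np.add.at(node_cur, graph.edge_j, np.abs(branch))
    node_cur = 0.5 * (node_cur + np.abs(injected))
    out = np.full(graph.grid.shape, graph.grid.nodata)
    out[graph.cells[:, 0], graph.cells[:, 1]] = node_cur
    return graph.grid.like(out)


def solve_pairwise(
    graph: ConductanceGraph,
    source_cells: list[tuple[int, int]],
    ground_cells: list[tuple[int, int]],
    injected_current: float = 1.0,
) -> CircuitResult:
    """Solve the Kirchhoff system with the ground set fixed at 0 V.

    ``injected_current`` is split equally over the source cells; the
    effective resistance is the mean source potential divided by the total
    injected current (for single-cell terminals this is the classic
    two-point resistance).
    """
    src = [graph.node(c) for c in source_cells]
    gnd = [graph.node(c) for c in ground_cells]
    if set(src) & set(gnd):
        raise ValueError("source and ground cells must be disjoint")
    comp = set(graph.component[src]) | set(graph.component[gnd])
    if len(comp) > 1:
        raise ValueError("source and ground are in different components")
    n = graph.n_nodes
    keep = np.setdiff1d(np.arange(n), np.array(gnd))
    b = np.zeros(n)
    b[src] = injected_current / len(src)
    L = graph.laplacian
    sub = L[keep][:, keep].tocsc()
    v = np.zeros(n)
    v[keep] = factorized(sub)(b[keep])
    # net current actually flowing: L v = injection at sources, sink at ground
    net = L @ v
    interior = np.setdiff1d(keep, np.array(src))
    resid = float(np.abs(net[interior]).max()) if interior.size else 0.0
    r_eff = float(np.mean(v[src]) / injected_current)
    if r_eff <= 0:
        raise ValueError("singular system: non-positive effective resistance")
    cur = _current_density(graph, v, net)
    return CircuitResult(v, cur, r_eff, list(source_cells), list(ground_cells),
                         resid)


# ---------------------------------------------------------------------------
# Omnidirectional (buffered) connectivity
# ---------------------------------------------------------------------------

def _perimeter_cells(nr: int, nc: int, k: int) -> list[tuple[int, int]]:
    """k cells spread evenly (by arc position) along the outer ring."""
    ring = (
        [(0, c) for c in range(nc)]
        + [(r, nc - 1) for r in range(1, nr)]
        + [(nr - 1, c) for c in range(nc - 2, -1, -1)]
        + [(r, 0) for r in range(nr - 2, 0, -1)]
    )
    pos = np.linspace(0, len(ring), k, endpoint=False).astype(int)
    return [ring[p] for p in pos]


def omnidirectional_current(
    cost: CostSurface,
    buffer_width: int = 5,
    n_perimeter_nodes: int = 16,
    pair_subsample: int | None = None,
    seed: int = 0,
    buffer_cost: float | None = None,
) -> RasterGrid:
    """Cumulative current map over buffered-perimeter focal-node pairs.

    The surface is padded with ``buffer_width`` rings of uniform cost
    (default: the mean passable cost), focal nodes are placed evenly on the
    outer ring, all unordered pairs (or a seeded subsample) are solved with
    unit current, current-density maps are summed, and the buffer is
    cropped off.  Uniform landscapes give near-uniform interior current;
    the map scales linearly with the injected current.
    """
    if buffer_width < 1:
        raise ValueError("buffer_width must be >= 1")
    if n_perimeter_nodes < 2:
        raise ValueError("need at least two perimeter nodes")
    g = cost.grid
    if buffer_cost is None:
        buffer_cost = float(g.finite_values().mean())
    padded_vals = np.pad(g.values, buffer_width, constant_values=buffer_cost)
    # keep interior nodata impassable in the padded surface
    mask = np.pad(g.valid_mask, buffer_width, constant_values=True)
    padded_vals = np.where(mask, padded_vals, g.nodata)
    padded = CostSurface(RasterGrid(
        padded_vals, g.cell_size,
        g.origin_x - buffer_width * g.cell_size,
        g.origin_y - buffer_width * g.cell_size, g.nodata))
    graph = build_conductance_graph(padded)
    nr, nc = padded.grid.shape
    nodes = _perimeter_cells(nr, nc, n_perimeter_nodes)
    pairs = [(a, b) for ai, a in enumerate(nodes) for b in nodes[ai + 1:]]
    if pair_subsample is not None and pair_subsample < len(pairs):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), pair_subsample, replace=False)
        pairs = [pairs[int(t)] for t in idx]

    # one factorization, superposed unit injections per pair
    ref = graph.node(nodes[0])
    keep = np.setdiff1d(np.arange(graph.n_nodes), [ref])
    solve = factorized(graph.laplacian[keep][:, keep].tocsc())
    total = np.zeros(padded.grid.shape)
    for a, b in pairs:
        na, nb = graph.node(a), graph.node(b)
        rhs = np.zeros(graph.n_nodes)
        rhs[na] += 1.0
        rhs[nb] -= 1.0
        v = np.zeros(graph.n_nodes)
        v[keep] = solve(rhs[keep])
        cur = _current_density(graph, v, graph.laplacian @ v)
        total += np.where(cur.valid_mask, cur.values, 0.0)
    core = total[buffer_width:-buffer_width, buffer_width:-buffer_width]
    out = np.where(g.valid_mask, core, g.nodata)
    return g.like(out)


def measure_corridor_width(
    current: RasterGrid,
    transect: list[tuple[int, int]],
    quantile: float = 0.75,
) -> float:
    """Corridor width along a transect crossing the current map.

    Width = (largest contiguous run of transect cells with current above
    the ``quantile``-quantile of the transect's currents) x cell size.
    This transect-quantile definition is an artifact convention: published
    corridor widths are map readings with no stated method.
    """
    vals = []
    for r, c in transect:
        if not (0 <= r < current.n_rows and 0 <= c < current.n_cols):
            raise ValueError("transect leaves the grid")
        v = current.values[r, c]
        vals.append(np.nan if current.is_nodata(v) else v)
    vals = np.asarray(vals, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("transect has no passable cells")
    thr = np.quantile(finite, quantile)
    above = np.isfinite(vals) & (vals > thr)
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return best * current.cell_size


def row_transect(grid: RasterGrid, row: int) -> list[tuple[int, int]]:
    """Convenience: a full west-east transect along one raster row."""
    return [(row, c) for c in range(grid.n_cols)]
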