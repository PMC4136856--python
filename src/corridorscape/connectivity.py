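"""Least-cost corridor machinery on raster cost surfaces.

The suitability map is inverted into a movement-cost surface (affine, range
1-100 by default), cells become nodes of the 8-neighbour graph with edge
weight = mean of the two cell costs x step length (sqrt(2) x cell size on
diagonals), and Dijkstra yields accumulated-cost and backlink rasters from
which least-cost paths are traced.  A 5 x 5 source/sink design enumerates
25 candidate pathways (1 optimal + 24 alternatives) whose quality is
summarised as accumulated cost per 100 m of path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import RasterGrid

DEFAULT_COST_SCALE = 99.0
DEFAULT_COST_MIN = 1.0

# compass codes for the backlink raster: direction from a cell toward its
# optimal predecessor; 0 = source, -1 = unreachable/impassable
_DIRS = {  # code: (drow, dcol)
    1: (-1, 0),   # N
    2: (-1, 1),   # NE
    3: (0, 1),    # E
    4: (1, 1),    # SE
    5: (1, 0),    # S
    6: (1, -1),   # SW
    7: (0, -1),   # W
    8: (-1, -1),  # NW
}
_CODE_OF = {v: k for k, v in _DIRS.items()}


@dataclass
class CostSurface:
    """Per-cell movement cost; strictly positive where passable, nodata
    impassable."""

    grid: RasterGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = self.grid.finite_values()
        if vals.size and vals.min() <= 0:
            raise ValueError("cost must be strictly positive where passable")

    @property
    def values(self):
        return self.grid.values


def cost_surface(psi: RasterGrid, scale: float = DEFAULT_COST_SCALE,
                 cost_min: float = DEFAULT_COST_MIN,
                 mode: str = "affine") -> CostSurface:
    """Invert a suitability map into movement cost.

    ``affine`` (default): cost = cost_min + scale * (1 - psi), range
    [cost_min, cost_min + scale] — bounded and strictly positive.
    ``reciprocal``: cost = 1 / max(psi, 1/(cost_min + scale)), for
    sensitivity analyses.
    """
    vals = psi.finite_values()
    if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
        raise ValueError("suitability must lie in [0, 1]")
    if mode == "affine":
        c = cost_min + scale * (1.0 - psi.values)
    elif mode == "reciprocal":
        c = 1.0 / np.maximum(psi.values, 1.0 / (cost_min + scale))
    else:
        raise ValueError(f"unknown inversion mode {mode!r}")
    out = np.where(psi.valid_mask, c, psi.nodata)
    return CostSurface(psi.like(out),
                       {"mode": mode, "scale": scale, "cost_min": cost_min})


# ---------------------------------------------------------------------------
# Graph construction (shared with the circuit module)
# ---------------------------------------------------------------------------

def grid_edges(cost: CostSurface) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Undirected 8-neighbour edges between passable cells.

    Returns (i, j, w): flat node indices and weights
    w = mean(cost_i, cost_j) * step_length.
    """
    g = cost.grid
    nr, nc = g.shape
    passable = g.valid_mask
    c = g.values
    idx = np.arange(nr * nc).reshape(nr, nc)
    ii, jj, ww = [], [], []
    steps = [((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), np.sqrt(2.0)),
             ((1, -1), np.sqrt(2.0))]
    for (dr, dc), mult in steps:
        r0 = slice(max(0, -dr), nr - max(0, dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        r1 = slice(max(0, dr), nr + min(0, dr))
        c1 = slice(max(0, dc), nc + min(0, dc))
        a, b = idx[r0, c0], idx[r1, c1]
        ok = passable[r0, c0] & passable[r1, c1]
        w = 0.5 * (c[r0, c0] + c[r1, c1]) * mult * g.cell_size
        ii.append(a[ok]); jj.append(b[ok]); ww.append(w[ok])
    return (np.concatenate(ii), np.concatenate(jj), np.concatenate(ww))


def _sparse_graph(cost: CostSurface):
    n = cost.grid.n_rows * cost.grid.n_cols
    i, j, w = grid_edges(cost)
    return coo_matrix((np.concatenate([w, w]),
                       (np.concatenate([i, j]), np.concatenate([j, i]))),
                      shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# Accumulated cost + backlink
# ---------------------------------------------------------------------------

def accumulated_cost(
    cost: CostSurface, sources: list[tuple[int, int]]
) -> tuple[RasterGrid, RasterGrid]:
    """Dijkstra accumulated-cost and backlink rasters from a source set.

    Accumulation is the minimal cost-distance from any source; the backlink
    raster codes each cell's optimal predecessor direction (0 = source,
    1-8 = compass N, NE, E, SE, S, SW, W, NW; nodata = unreachable).
    """
    g = cost.grid
    nr, nc = g.shape
    src_nodes = []
    for r, c in sources:
        if not (0 <= r < nr and 0 <= c < nc) or not g.valid_mask[r, c]:
            raise ValueError(f"source ({r}, {c}) is not a passable cell")
        src_nodes.append(r * nc + c)
    if not src_nodes:
        raise ValueError("need at least one passable source")
    graph = _sparse_graph(cost)
    dist, pred, _ = dijkstra(graph, directed=False, indices=src_nodes,
                             min_only=True, return_predecessors=True)
    acc = np.where(np.isfinite(dist), dist, g.nodata).reshape(nr, nc)
    back = np.full(nr * nc, g.nodata)
    reach = np.isfinite(dist)
    for node in np.nonzero(reach)[0]:
        p = pred[node]
        if p < 0:
            back[node] = 0.0  # source cell
        else:
            dr = p // nc - node // nc
            dc = p % nc - node % nc
            back[node] = _CODE_OF[(dr, dc)]
    return g.like(acc), g.like(back.reshape(nr, nc))


@dataclass
class Path:
    """A least-cost pathway: ordered 8-connected cell list with its
    accumulated cost and geometric length."""

    cells: list[tuple[int, int]]
    total_cost: float
    length_m: float
    source_label: str = ""
    sink_label: str = ""
    flag: str = "alternative"  # "optimal" | "alternative" | "infeasible"

    def __post_init__(self):
        for (r0, c0), (r1, c1) in zip(self.cells, self.cells[1:]):
            if max(abs(r1 - r0), abs(c1 - c0)) != 1:
                raise ValueError("path cells must be 8-adjacent")

    @property
    def cost_index(self) -> float:
        return path_cost_index(self)


def path_cost_index(path: Path) -> float:
    """Movement-cost index: accumulated cost per 100 m of path length."""
    if path.length_m <= 0:
        raise ValueError("zero-length path has no cost index")
    return path.total_cost * 100.0 / path.length_m


def path_cost_on_surface(cells: list[tuple[int, int]], cost: CostSurface
                         ) -> tuple[float, float]:
    """(total cost, length m) of a fixed cell sequence on a cost surface.

    Raises ValueError if the path crosses an impassable cell.
    """
    g = cost.grid
    total = 0.0
    length = 0.0
    for (r0, c0), (r1, c1) in zip(cells, cells[1:]):
        if not (g.valid_mask[r0, c0] and g.valid_mask[r1, c1]):
            raise ValueError("path crosses an impassable cell")
        d = g.cell_size * (np.sqrt(2.0) if (r0 != r1 and c0 != c1) else 1.0)
        total += 0.5 * (g.values[r0, c0] + g.values[r1, c1]) * d
        length += d
    if len(cells) == 1:
        if not g.valid_mask[cells[0]]:
            raise ValueError("path crosses an impassable cell")
    return total, length


def trace_least_cost_path(
    acc: RasterGrid, back: RasterGrid, destination: tuple[int, int]
) -> Path:
    """Follow backlinks from a destination to the nearest source."""
    r, c = destination
    if back.is_nodata(back.values[r, c]):
        raise ValueError(f"destination {destination} unreachable from sources")
    cells = [(r, c)]
    length = 0.0
    guard = back.n_rows * back.n_cols + 1
    while back.values[r, c] != 0.0:
        code = int(back.values[r, c])
        dr, dc = _DIRS[code]
        length += acc.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        r, c = r + dr, c + dc
        cells.append((r, c))
        guard -= 1
        if guard == 0:
            raise RuntimeError("backlink cycle detected")
    cells.reverse()
    total = float(acc.values[destination[0], destination[1]])
    return Path(cells, total, length)


# ---------------------------------------------------------------------------
# Pathway enumeration
# ---------------------------------------------------------------------------

@dataclass
class PathSet:
    paths: list[Path]

    @property
    def optimal(self) -> Path:
        return next(p for p in self.paths if p.flag == "optimal")

    def to_records(self):
        return [
            {"source": p.source_label, "sink": p.sink_label, "flag": p.flag,
             "total_cost": p.total_cost, "length_m": p.length_m,
             "cost_index": p.cost_index if p.length_m > 0 else np.nan}
            for p in self.paths
        ]


def enumerate_pathways(
    cost: CostSurface,
    source_points: list[tuple[int, int]],
    sink_points: list[tuple[int, int]],
) -> PathSet:
    """One least-cost path per source x sink pair.

    With the study design of five detection locations per side of the
    valley this yields 25 pathways; the globally cheapest is flagged
    ``optimal`` and the other 24 ``alternative``.  Unreachable pairs are
    retained as ``infeasible`` records.
    """
    paths: list[Path] = []
    for si, s in enumerate(source_points):
        acc, back = accumulated_cost(cost, [s])
        for ti, t in enumerate(sink_points):
            try:
                p = trace_least_cost_path(acc, back, t)
            except ValueError:
                p = Path([t], float("inf"), 0.0, flag="infeasible")
            p.source_label = f"src{si}"
            p.sink_label = f"snk{ti}"
            paths.append(p)
    feasible = [p for p in paths if p.flag != "infeasible"]
    if feasible:
        best = min(feasible, key=lambda p: p.total_cost)
        best.flag = "optimal"
    return PathSet(paths)
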