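"""Cost surfaces, Dijkstra accumulation/backlinks against exact oracles,
path tracing, 25-pathway enumeration, and the cost-per-100-m index."""

import networkx as nx
import numpy as np
import pytest

from corridorscape.connectivity import (
    CostSurface,
    accumulated_cost,
    cost_surface,
    enumerate_pathways,
    path_cost_index,
    path_cost_on_surface,
    trace_least_cost_path,
)
from corridorscape.grid import RasterGrid


def _cost(vals, cell=100.0):
    return CostSurface(RasterGrid(np.asarray(vals, dtype=float), cell))


def _uniform(nr, nc, v=1.0, cell=100.0):
    return _cost(np.full((nr, nc), v), cell)


def exact_min_cost(cost: CostSurface, src, dst):
    """Exact label-correcting DFS relaxation: explores every improving
    path, so it provably finds the optimum (independent of scipy)."""
    g = cost.grid
    nr, nc = g.shape
    best = np.full((nr, nc), np.inf)
    best[src] = 0.0
    stack = [src]
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nr and 0 <= c2 < nc):
                    continue
                if g.is_nodata(g.values[r2, c2]) or g.is_nodata(g.values[r, c]):
                    continue
                d = g.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
                w = 0.5 * (g.values[r, c] + g.values[r2, c2]) * d
                if best[r, c] + w < best[r2, c2] - 1e-12:
                    best[r2, c2] = best[r, c] + w
                    stack.append((r2, c2))
    return best[dst]


class TestCostSurface:
    @pytest.mark.parametrize("psi,expected", [(1.0, 1.0), (0.0, 100.0),
                                              (0.5, 50.5)])
    def test_affine_inversion(self, psi, expected):
        g = RasterGrid(np.full((2, 2), psi), 100.0)
        assert cost_surface(g).values[0, 0] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        g = RasterGrid(np.full((2, 2), 1.2), 100.0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cost_surface(g)

    def test_nodata_propagates(self):
        vals = np.array([[0.5, -9999.0], [0.2, 0.9]])
        cs = cost_surface(RasterGrid(vals, 100.0))
        assert cs.grid.nodata_mask[0, 1]


class TestAccumulatedCost:
    def test_edge_weight_definition(self):
        acc, _ = accumulated_cost(_uniform(5, 5), [(2, 2)])
        assert acc.values[2, 3] == pytest.approx(100.0)
        assert acc.values[3, 3] == pytest.approx(100.0 * np.sqrt(2))
        assert acc.values[2, 2] == 0.0

    def test_four_cells_due_east(self):
        acc, _ = accumulated_cost(_uniform(3, 6), [(1, 0)])
        assert acc.values[1, 4] == pytest.approx(400.0)

    def test_impassable_source_rejected(self):
        vals = np.full((3, 3), 2.0)
        vals[1, 1] = -9999.0
        with pytest.raises(ValueError, match="passable"):
            accumulated_cost(_cost(vals), [(1, 1)])

    def test_matches_exact_oracle_random_grids(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            nr, nc = rng.integers(2, 6, 2)
            cs = _cost(rng.uniform(0.5, 10, (nr, nc)))
            src = (int(rng.integers(nr)), int(rng.integers(nc)))
            acc, back = accumulated_cost(cs, [src])
            for r in range(nr):
                for c in range(nc):
                    assert acc.values[r, c] == pytest.approx(
                        exact_min_cost(cs, src, (r, c)), abs=1e-8)

    def test_matches_networkx(self):
        rng = np.random.default_rng(29)
        cs = _cost(rng.uniform(1, 5, (5, 5)))
        G = nx.Graph()
        g = cs.grid
        for r in range(5):
            for c in range(5):
                for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < 5 and 0 <= c2 < 5:
                        d = g.cell_size * (np.sqrt(2) if dr and dc else 1.0)
                        G.add_edge((r, c), (r2, c2),
                                   weight=0.5 * (g.values[r, c]
                                                 + g.values[r2, c2]) * d)
        dist = nx.single_source_dijkstra_path_length(G, (0, 0))
        acc, _ = accumulated_cost(cs, [(0, 0)])
        for (r, c), v in dist.items():
            assert acc.values[r, c] == pytest.approx(v, abs=1e-8)

    def test_monotone_in_cell_cost(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 5, (4, 4))
        acc1, _ = accumulated_cost(_cost(vals), [(0, 0)])
        vals2 = vals.copy()
        vals2[2, 2] += 3.0
        acc2, _ = accumulated_cost(_cost(vals2), [(0, 0)])
        assert (acc2.values >= acc1.values - 1e-9).all()


class TestTracePath:
    def test_straight_path_on_uniform_cost(self):
        cs = _uniform(5, 7)
        acc, back = accumulated_cost(cs, [(2, 0)])
        p = trace_least_cost_path(acc, back, (2, 6))
        assert p.cells[0] == (2, 0) and p.cells[-1] == (2, 6)
        assert len(p.cells) == 7
        assert all(r == 2 for r, _ in p.cells)

    def test_path_cost_equals_accumulation(self):
        rng = np.random.default_rng(41)
        cs = _cost(rng.uniform(1, 9, (6, 6)))
        acc, back = accumulated_cost(cs, [(0, 0)])
        p = trace_least_cost_path(acc, back, (5, 5))
        total, length = path_cost_on_surface(p.cells, cs)
        assert p.total_cost == pytest.approx(acc.values[5, 5], abs=1e-9)
        assert total == pytest.approx(p.total_cost, abs=1e-9)
        assert length == pytest.approx(p.length_m, abs=1e-9)

    def test_source_sink_symmetry(self):
        rng = np.random.default_rng(19)
        cs = _cost(rng.uniform(1, 9, (5, 5)))
        acc1, b1 = accumulated_cost(cs, [(0, 0)])
        acc2, b2 = accumulated_cost(cs, [(4, 4)])
        c1 = trace_least_cost_path(acc1, b1, (4, 4)).total_cost
        c2 = trace_least_cost_path(acc2, b2, (0, 0)).total_cost
        assert c1 == pytest.approx(c2, abs=1e-9)

    def test_unreachable_destination(self):
        vals = np.full((3, 3), 1.0)
        vals[:, 1] = -9999.0
        acc, back = accumulated_cost(_cost(vals), [(1, 0)])
        with pytest.raises(ValueError, match="unreachable"):
            trace_least_cost_path(acc, back, (1, 2))


class TestEnumeratePathways:
    def test_single_pair(self):
        ps = enumerate_pathways(_uniform(4, 4), [(0, 0)], [(3, 3)])
        assert len(ps.paths) == 1
        assert ps.paths[0].flag == "optimal"

    def test_five_by_five_design(self):
        cs = _uniform(8, 10)
        srcs = [(r, 0) for r in range(2, 7)]
        snks = [(r, 9) for r in range(2, 7)]
        ps = enumerate_pathways(cs, srcs, snks)
        flags = [p.flag for p in ps.paths]
        assert len(ps.paths) == 25
        assert flags.count("optimal") == 1
        assert flags.count("alternative") == 24

    def test_optimal_is_cheapest(self):
        rng = np.random.default_rng(7)
        cs = _cost(rng.uniform(1, 20, (8, 8)))
        ps = enumerate_pathways(cs, [(r, 0) for r in range(1, 6)],
                                [(r, 7) for r in range(1, 6)])
        opt = ps.optimal
        assert all(p.total_cost >= opt.total_cost - 1e-9 for p in ps.paths)

    def test_unreachable_pair_marked_infeasible(self):
        vals = np.full((4, 4), 1.0)
        vals[:, 2] = -9999.0
        ps = enumerate_pathways(_cost(vals), [(0, 0)], [(0, 3)])
        assert ps.paths[0].flag == "infeasible"


class TestCostIndex:
    def test_uniform_example(self):
        from corridorscape.connectivity import Path
        p = Path([(0, c) for c in range(5)], total_cost=400.0,
                 length_m=400.0)
        assert path_cost_index(p) == pytest.approx(100.0)

    def test_doubling_cost_doubles_index(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 5, (5, 5))
        cs1, cs2 = _cost(vals), _cost(vals * 2)
        acc, back = accumulated_cost(cs1, [(0, 0)])
        p = trace_least_cost_path(acc, back, (4, 4))
        t1, l1 = path_cost_on_surface(p.cells, cs1)
        t2, l2 = path_cost_on_surface(p.cells, cs2)
        assert t2 * 100 / l2 == pytest.approx(2 * t1 * 100 / l1, rel=1e-12)

    def test_index_is_length_weighted_mean_density(self):
        rng = np.random.default_rng(8)
        cs = _cost(rng.uniform(1, 9, (5, 5)))
        acc, back = accumulated_cost(cs, [(0, 0)])
        p = trace_least_cost_path(acc, back, (4, 3))
        g = cs.grid
        densities, lengths = [], []
        for (r0, c0), (r1, c1) in zip(p.cells, p.cells[1:]):
            d = g.cell_size * (np.sqrt(2) if (r0 != r1 and c0 != c1) else 1)
            densities.append(0.5 * (g.values[r0, c0] + g.values[r1, c1]))
            lengths.append(d)
        oracle = np.average(densities, weights=lengths) * 100.0
        assert p.cost_index == pytest.approx(oracle, rel=1e-12)

    def test_zero_length_rejected(self):
        from corridorscape.connectivity import Path
        p = Path([(0, 0)], total_cost=0.0, length_m=0.0)
        with pytest.raises(ValueError):
            path_cost_index(p)
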