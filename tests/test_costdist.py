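"""Cost-weighted distance: edge-cost arithmetic, exact agreement with an
independent sparse-graph shortest-path oracle, backlink consistency, and
minimum mosaicking."""

import math

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from lynxlink.costdist import (
    cost_weighted_distance,
    edge_cost,
    mosaic_min,
    trace_backlinks,
)
from lynxlink.errors import ParameterError

from conftest import make_grid


def _oracle_cwd(res, cell, sources):
    """Independent oracle: scipy.sparse.csgraph Dijkstra on the same
    8-connected mean-resistance graph."""
    n_rows, n_cols = res.shape
    n = n_rows * n_cols
    rows, cols, data = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < n_rows and 0 <= nc < n_cols:
                    w = 0.5 * (res[r, c] + res[nr, nc]) * cell
                    if abs(dr) + abs(dc) == 2:
                        w *= math.sqrt(2.0)
                    rows.append(r * n_cols + c)
                    cols.append(nr * n_cols + nc)
                    data.append(w)
    graph = coo_matrix((data, (rows, cols)), shape=(n, n))
    d = csgraph_dijkstra(graph, directed=False, indices=sources)
    return d.min(axis=0).reshape(n_rows, n_cols)


def _source_mask(shape, cells, cell_size=100.0):
    m = np.zeros(shape, dtype=bool)
    for r, c in cells:
        m[r, c] = True
    return make_grid(m, cell_size=cell_size)


class TestEdgeCost:
    def test_unit_resistance_is_geometric_distance(self):
        assert edge_cost(1.0, 1.0, 100.0) == 100.0

    def test_diagonal_factor(self):
        assert edge_cost(1.0, 1.0, 100.0, diagonal=True) == pytest.approx(
            100.0 * math.sqrt(2)
        )

    def test_mean_of_endpoint_resistances(self):
        assert edge_cost(3.0, 5.0, 100.0) == 400.0

    def test_negative_resistance_rejected(self):
        with pytest.raises(ParameterError):
            edge_cost(-1.0, 5.0, 100.0)


class TestCostWeightedDistance:
    def test_uniform_chain(self):
        res = make_grid(np.ones((1, 3)), cell_size=100.0)
        surf = cost_weighted_distance(res, _source_mask((1, 3), [(0, 0)]))
        np.testing.assert_allclose(surf.cwd.values, [[0.0, 100.0, 200.0]])

    def test_graded_chain(self):
        res = make_grid(np.array([[1.0, 3.0, 5.0]]), cell_size=100.0)
        surf = cost_weighted_distance(res, _source_mask((1, 3), [(0, 0)]))
        np.testing.assert_allclose(surf.cwd.values, [[0.0, 200.0, 600.0]])

    def test_matches_sparse_graph_oracle_on_random_grids(self):
        rng = np.random.default_rng(777)
        for _ in range(50):
            res = rng.uniform(1.0, 10.0, size=(12, 12))
            src = (int(rng.integers(12)), int(rng.integers(12)))
            surf = cost_weighted_distance(
                make_grid(res, cell_size=100.0), _source_mask((12, 12), [src])
            )
            oracle = _oracle_cwd(res, 100.0, [src[0] * 12 + src[1]])
            np.testing.assert_allclose(surf.cwd.values, oracle, rtol=1e-9)

    def test_multi_source_matches_oracle(self):
        rng = np.random.default_rng(3)
        res = rng.uniform(1.0, 8.0, size=(10, 10))
        cells = [(0, 0), (9, 9), (4, 7)]
        surf = cost_weighted_distance(
            make_grid(res, cell_size=30.0), _source_mask((10, 10), cells, 30.0)
        )
        oracle = _oracle_cwd(res, 30.0, [r * 10 + c for r, c in cells])
        np.testing.assert_allclose(surf.cwd.values, oracle, rtol=1e-9)

    def test_detour_beats_straight_high_resistance_path(self):
        # straight east-west route crosses a resistance-10 wall; a 1-valued
        # corridor detours around it
        res = np.full((5, 7), 10.0)
        res[0, :] = 1.0  # top corridor
        res[:, 0] = 1.0
        res[:, 6] = 1.0
        res = make_grid(res, cell_size=100.0)
        surf = cost_weighted_distance(res, _source_mask((5, 7), [(4, 0)]))
        direct_cost = 10.0 * 600.0  # what plowing straight through would cost
        assert surf.cwd.values[4, 6] < direct_cost

    def test_zero_on_sources_and_positive_elsewhere(self):
        res = make_grid(np.ones((6, 6)), cell_size=100.0)
        surf = cost_weighted_distance(res, _source_mask((6, 6), [(2, 2), (3, 3)]))
        assert surf.cwd.values[2, 2] == 0.0
        assert surf.cwd.values[3, 3] == 0.0
        assert (surf.cwd.values[surf.backlink.values != 0] > 0).all()

    def test_uniform_resistance_bounded_by_euclidean_and_chebyshev_route(self):
        res = make_grid(np.ones((15, 15)), cell_size=100.0)
        surf = cost_weighted_distance(res, _source_mask((15, 15), [(7, 7)]))
        for r in range(15):
            for c in range(15):
                euclid = math.hypot(r - 7, c - 7) * 100.0
                assert surf.cwd.values[r, c] >= euclid - 1e-9
                assert surf.cwd.values[r, c] <= math.sqrt(2) * euclid + 1e-9

    def test_raising_resistance_never_decreases_cwd(self):
        rng = np.random.default_rng(21)
        res = rng.uniform(1.0, 5.0, size=(8, 8))
        before = cost_weighted_distance(
            make_grid(res, cell_size=100.0), _source_mask((8, 8), [(0, 0)])
        )
        res2 = res.copy()
        res2[4, 4] += 5.0
        after = cost_weighted_distance(
            make_grid(res2, cell_size=100.0), _source_mask((8, 8), [(0, 0)])
        )
        assert (after.cwd.values >= before.cwd.values - 1e-9).all()

    def test_adding_a_source_never_increases_cwd(self):
        rng = np.random.default_rng(22)
        res = make_grid(rng.uniform(1.0, 5.0, size=(8, 8)), cell_size=100.0)
        one = cost_weighted_distance(res, _source_mask((8, 8), [(0, 0)]))
        two = cost_weighted_distance(res, _source_mask((8, 8), [(0, 0), (7, 7)]))
        assert (two.cwd.values <= one.cwd.values + 1e-9).all()

    def test_backlinks_descend_to_a_source(self):
        rng = np.random.default_rng(8)
        res = make_grid(rng.uniform(1.0, 9.0, size=(10, 10)), cell_size=100.0)
        surf = cost_weighted_distance(res, _source_mask((10, 10), [(5, 5)]))
        for r, c in [(0, 0), (9, 9), (0, 9), (3, 8)]:
            path = trace_backlinks(surf, r, c)
            costs = [surf.cwd.values[p] for p in path]
            assert all(a > b for a, b in zip(costs[:-1], costs[1:]))
            assert path[-1] == (5, 5)

    def test_nodata_cells_are_impassable(self):
        res = np.ones((3, 3))
        res[:, 1] = -9999.0  # a nodata wall
        surf = cost_weighted_distance(
            make_grid(res, cell_size=100.0), _source_mask((3, 3), [(1, 0)])
        )
        assert np.isinf(surf.cwd.values[:, 2]).all()
        assert np.isinf(surf.cwd.values[:, 1]).all()

    def test_empty_source_rejected(self):
        res = make_grid(np.ones((3, 3)), cell_size=100.0)
        with pytest.raises(ParameterError):
            cost_weighted_distance(res, _source_mask((3, 3), []))

    def test_triangle_inequality_on_joint_paths(self):
        rng = np.random.default_rng(5)
        res = make_grid(rng.uniform(1.0, 9.0, size=(10, 10)), cell_size=100.0)
        a = cost_weighted_distance(res, _source_mask((10, 10), [(0, 0)]))
        b = cost_weighted_distance(res, _source_mask((10, 10), [(9, 9)]))
        ab = a.cwd.values[9, 9]
        joint = a.cwd.values + b.cwd.values
        assert (joint >= ab - 1e-9).all()  # any via-pixel route costs at least A->B


class TestMosaicMin:
    def _surfaces(self):
        res = make_grid(np.ones((6, 6)), cell_size=100.0)
        a = cost_weighted_distance(res, _source_mask((6, 6), [(0, 0)]), "1")
        b = cost_weighted_distance(res, _source_mask((6, 6), [(5, 5)]), "2")
        return a, b

    def test_single_surface_identity(self):
        a, _ = self._surfaces()
        m = mosaic_min([a])
        np.testing.assert_array_equal(m.cwd_min.values, a.cwd.values)
        assert (m.nearest_hca.values == 1).all()

    def test_dominated_surface_never_wins(self):
        a, _ = self._surfaces()
        shifted = cost_weighted_distance(
            make_grid(np.full((6, 6), 10.0), cell_size=100.0),
            _source_mask((6, 6), [(0, 0)]),
            "2",
        )
        m = mosaic_min([a, shifted])
        np.testing.assert_array_equal(m.cwd_min.values, a.cwd.values)

    def test_min_below_every_input(self):
        a, b = self._surfaces()
        m = mosaic_min([a, b])
        assert (m.cwd_min.values <= a.cwd.values + 1e-12).all()
        assert (m.cwd_min.values <= b.cwd.values + 1e-12).all()

    def test_tie_goes_to_earlier_surface(self):
        a, b = self._surfaces()
        m = mosaic_min([a, b])
        ties = np.isclose(a.cwd.values, b.cwd.values)
        assert (m.nearest_hca.values[ties] == 1).all()

    def test_allocation_attains_the_minimum(self):
        a, b = self._surfaces()
        m = mosaic_min([a, b])
        stack = np.stack([a.cwd.values, b.cwd.values])
        picked = np.take_along_axis(
            stack, (m.nearest_hca.values - 1)[None], axis=0
        )[0]
        np.testing.assert_array_equal(picked, m.cwd_min.values)
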