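"""Euclidean, least-cost and river distances; the max(cost, euclid) rule."""

import math

import networkx as nx
import numpy as np
import pytest

from clonalpop.differentiation import DistanceMatrix
from clonalpop.genotype_io import CoordinatesMissingError
from clonalpop.spatial import (CostSurface, RiverLine, cost_distance,
                               cost_distance_matrix, euclidean_pairwise,
                               read_ascii_grid, river_distance, river_extent,
                               site_centroids, site_pairwise_distance,
                               within_site_spacing)
from conftest import make_dataset


class TestEuclidean:
    def test_three_four_five(self):
        d = euclidean_pairwise(np.array([[0, 0], [3, 4]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_colocated_zero(self):
        d = euclidean_pairwise(np.array([[2, 2], [2, 2]]))
        assert d.values[0, 1] == 0.0

    def test_within_site_means_hand_computed(self):
        xy = [(0, 0), (3, 4), (0, 8), (6, 8)]
        ds = make_dataset([[(1, 2)]] * 4, xy=xy)
        t = within_site_spacing(ds)
        pts = np.asarray(xy, float)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(D, np.inf)
        assert t.iloc[0].mean_nn_m == pytest.approx(D.min(axis=1).mean())
        iu = np.triu_indices(4, 1)
        assert t.iloc[0].mean_allpair_m == pytest.approx(D[iu].mean())

    def test_missing_coordinates_raise(self):
        ds = make_dataset([[(1, 2)]] * 2)
        with pytest.raises(CoordinatesMissingError):
            within_site_spacing(ds)


class TestCentroids:
    def test_single_sample_is_itself(self):
        ds = make_dataset([[(1, 2)]], xy=[(7, 9)])
        c = site_centroids(ds)
        assert (c.iloc[0].easting, c.iloc[0].northing) == (7, 9)

    def test_square_center(self):
        xy = [(0, 0), (0, 2), (2, 0), (2, 2)]
        ds = make_dataset([[(1, 2)]] * 4, xy=xy)
        c = site_centroids(ds)
        assert (c.iloc[0].easting, c.iloc[0].northing) == (1.0, 1.0)

    def test_random_fixture_mean_oracle(self, rng):
        xy = rng.uniform(0, 100, size=(9, 2))
        sites = ["A"] * 4 + ["B"] * 5
        ds = make_dataset([[(1, 2)]] * 9, sites=sites, xy=xy)
        c = site_centroids(ds).set_index("site")
        np.testing.assert_allclose(c.loc["A"], xy[:4].mean(axis=0))
        np.testing.assert_allclose(c.loc["B"], xy[4:].mean(axis=0))


def _nx_oracle(surface: CostSurface, rc_a, rc_b) -> float:
    """Independent Dijkstra on an explicitly built 8-neighbor graph."""
    g = nx.Graph()
    nrow, ncol = surface.shape
    for r in range(nrow):
        for c in range(ncol):
            if not surface.grid[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < nrow and 0 <= c2 < ncol and surface.grid[r2, c2]:
                        w = surface.cell_size * (math.sqrt(2) if dr and dc else 1)
                        g.add_edge((r, c), (r2, c2), weight=w)
    try:
        return nx.dijkstra_path_length(g, rc_a, rc_b)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return math.inf


class TestCostDistance:
    def test_open_water_row(self):
        s = CostSurface(grid=np.ones((3, 12)), cell_size=10.0)
        a = s.cell_center(1, 0)
        b = s.cell_center(1, 10)
        assert cost_distance(s, a, b) == pytest.approx(100.0)

    def test_diagonal_geocorrection(self):
        s = CostSurface(grid=np.ones((12, 12)), cell_size=10.0)
        a = s.cell_center(0, 0)
        b = s.cell_center(10, 10)
        assert cost_distance(s, a, b) == pytest.approx(100 * math.sqrt(2))

    def test_wall_with_gap_matches_dijkstra_oracle(self):
        grid = np.ones((9, 9), dtype=bool)
        grid[:, 4] = False
        grid[7, 4] = True  # single gap
        s = CostSurface(grid=grid, cell_size=10.0)
        a = s.cell_center(1, 1)
        b = s.cell_center(1, 7)
        assert cost_distance(s, a, b) == pytest.approx(_nx_oracle(s, (1, 1), (1, 7)))

    def test_random_grids_match_oracle(self, rng):
        for rep in range(3):
            grid = rng.random((20, 20)) > 0.35
            s = CostSurface(grid=grid, cell_size=5.0)
            water = np.argwhere(grid)
            picks = water[rng.choice(len(water), size=4, replace=False)]
            pts = [s.cell_center(r, c) for r, c in picks]
            mine = cost_distance_matrix(s, pts, snap_radius_cells=0)
            for i in range(4):
                for j in range(i + 1, 4):
                    oracle = _nx_oracle(s, tuple(picks[i]), tuple(picks[j]))
                    assert mine.values[i, j] == pytest.approx(oracle)

    def test_unreachable_is_infinite(self):
        grid = np.ones((5, 5), dtype=bool)
        grid[:, 2] = False
        s = CostSurface(grid=grid, cell_size=10.0)
        d = cost_distance(s, s.cell_center(2, 0), s.cell_center(2, 4))
        assert math.isinf(d)

    def test_land_point_snaps_within_radius(self):
        grid = np.ones((5, 5), dtype=bool)
        grid[0, 0] = False
        s = CostSurface(grid=grid, cell_size=10.0)
        d = cost_distance(s, s.cell_center(0, 0), s.cell_center(0, 3))
        assert math.isfinite(d)
        with pytest.raises(ValueError, match="land"):
            cost_distance(s, s.cell_center(0, 0), s.cell_center(0, 3),
                          snap_radius_cells=0)

    def test_octile_bound_on_open_water(self, rng):
        s = CostSurface(grid=np.ones((30, 30)), cell_size=10.0)
        for _ in range(5):
            r1, c1, r2, c2 = rng.integers(0, 30, 4)
            if (r1, c1) == (r2, c2):
                continue
            a, b = s.cell_center(r1, c1), s.cell_center(r2, c2)
            euclid = math.dist(a, b)
            cost = cost_distance(s, a, b)
            assert euclid - 1e-9 <= cost <= math.sqrt(2) * euclid + 1e-9

    def test_triangle_inequality(self, rng):
        grid = rng.random((15, 15)) > 0.3
        s = CostSurface(grid=grid, cell_size=10.0)
        water = np.argwhere(grid)
        picks = water[rng.choice(len(water), size=5, replace=False)]
        pts = [s.cell_center(r, c) for r, c in picks]
        m = cost_distance_matrix(s, pts, snap_radius_cells=0).values
        finite = np.isfinite(m)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    if finite[i, j] and finite[j, k] and finite[i, k]:
                        assert m[i, k] <= m[i, j] + m[j, k] + 1e-9


class TestAsciiGrid:
    def test_round_trip_parse(self, tmp_path):
        txt = ("ncols 4\nnrows 3\nxllcorner 100.0\nyllcorner 200.0\n"
               "cellsize 10.0\nNODATA_value -9999\n"
               "1 1 0 1\n0 1 1 1\n1 1 1 -9999\n")
        p = tmp_path / "w.asc"
        p.write_text(txt)
        s = read_ascii_grid(p)
        assert s.shape == (3, 4)
        assert s.cell_size == 10.0
        assert bool(s.grid[0, 2]) is False
        assert bool(s.grid[2, 3]) is False  # nodata -> land
        assert s.cell_of((105.0, 205.0)) == (2, 0)  # lower-left cell


class TestRiverDistance:
    def test_straight_line_endpoints(self):
        line = RiverLine.from_coords([(0, 0), (1000, 0)])
        d = river_distance(line, [(0, 1), (1000, -2)])
        assert d.values[0, 1] == pytest.approx(1000.0)

    def test_same_vertex_zero(self):
        line = RiverLine.from_coords([(0, 0), (100, 0)])
        d = river_distance(line, [(50, 1), (50.2, -1)])
        assert d.values[0, 1] == pytest.approx(0.0, abs=1.0)

    def test_sinuous_line_arc_length_oracle(self):
        t = np.linspace(0, 4 * np.pi, 400)
        coords = list(zip(t * 50, 30 * np.sin(t)))
        line = RiverLine.from_coords(coords)
        pts = [coords[0], coords[-1]]
        seg = np.diff(np.asarray(coords), axis=0)
        arc = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
        assert river_extent(line, pts) == pytest.approx(arc, abs=1.0)

    def test_direction_reversal_invariance(self):
        coords = [(0, 0), (300, 100), (700, 50), (1200, 400)]
        pts = [(100, 50), (900, 200), (400, 80)]
        d1 = river_distance(RiverLine.from_coords(coords), pts)
        d2 = river_distance(RiverLine.from_coords(coords[::-1]), pts)
        np.testing.assert_allclose(d1.values, d2.values, atol=2.0)


class TestSiteDistanceRule:
    def test_elementwise_maximum(self):
        labels = ["a", "b", "c"]
        cost = DistanceMatrix(labels, [[0, 5, 2], [5, 0, 9], [2, 9, 0]])
        euc = DistanceMatrix(labels, [[0, 3, 4], [3, 0, 7], [4, 7, 0]])
        m = site_pairwise_distance(cost, euc)
        np.testing.assert_array_equal(
            m.values, [[0, 5, 4], [5, 0, 9], [4, 9, 0]])

    def test_quantized_near_pair_takes_euclidean(self):
        # two points in the same raster cell: cost 0, Euclidean wins
        s = CostSurface(grid=np.ones((3, 3)), cell_size=10.0)
        a, b = (5.0, 5.0), (9.0, 5.0)
        cost = cost_distance_matrix(s, [a, b], labels=["a", "b"])
        assert cost.values[0, 1] == 0.0
        euc = euclidean_pairwise(np.array([a, b]), labels=["a", "b"])
        m = site_pairwise_distance(cost, euc)
        assert m.values[0, 1] == pytest.approx(4.0)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="label"):
            site_pairwise_distance(
                DistanceMatrix(["a"], [[0.0]]), DistanceMatrix(["b"], [[0.0]]))
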