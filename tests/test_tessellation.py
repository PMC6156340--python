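import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from divmap import (
    CellTable,
    build_zone_map,
    compute_tissue_area,
    neighbor_graph,
    seed_count,
    select_seeds,
)
from divmap.tessellation import GeometryError, ZoneMap

from conftest import make_cells


def table_from_points(points, cell_class="cancer"):
    pts = np.asarray(points, dtype=float)
    df = pd.DataFrame({
        "cell_id": np.arange(len(pts)),
        "x": pts[:, 0], "y": pts[:, 1],
        "cell_class": cell_class,
        "nucleus_area": 30.0, "nucleus_perimeter": 21.0,
    })
    return CellTable(df)


class TestTissueArea:
    def test_square_corner_cells_give_square_hull(self):
        t = table_from_points([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        area, poly = compute_tissue_area(t)
        assert area == pytest.approx(1e6)
        assert poly.equals(box(0, 0, 1000, 1000))

    def test_two_cells_raise(self):
        with pytest.raises(GeometryError):
            compute_tissue_area(table_from_points([(0, 0), (1, 1)]))

    def test_collinear_cells_raise(self):
        with pytest.raises(GeometryError):
            compute_tissue_area(table_from_points([(0, 0), (1, 1), (2, 2)]))

    def test_hull_area_bounded_by_bbox(self, small_table):
        area, _ = compute_tissue_area(small_table)
        xy = small_table.coords
        bbox = np.ptp(xy[:, 0]) * np.ptp(xy[:, 1])
        assert 0 < area <= bbox

    def test_alpha_shape_smaller_than_hull(self):
        t = make_cells(n=400, seed=2)
        hull_area, _ = compute_tissue_area(t)
        alpha_area, _ = compute_tissue_area(t, method="alpha_shape", alpha=1 / 150)
        assert 0 < alpha_area <= hull_area


class TestSeedCount:
    @pytest.mark.parametrize("area, expected", [
        (36.0, 2),           # sqrt(36)/3 = 2
        (2_250_000.0, 500),  # sqrt = 1500, /3
        (1.0, 1),            # floored at 1
        (80.0, 2),           # floor(8.94/3) = 2
    ])
    def test_square_root_rule(self, area, expected):
        assert seed_count(area, area_unit_scale=1.0) == expected

    def test_area_unit_scale_rescales(self):
        assert seed_count(360.0, area_unit_scale=10.0) == 2

    def test_non_positive_inputs_raise(self):
        with pytest.raises(ValueError):
            seed_count(0.0)
        with pytest.raises(ValueError):
            seed_count(10.0, area_unit_scale=-1)


class TestSelectSeeds:
    def test_all_cancer_cells_when_n_equals_pool(self, mixed_table):
        n = int((mixed_table.data.cell_class == "cancer").sum())
        seeds = select_seeds(mixed_table, n, rng_seed=0)
        assert sorted(seeds) == sorted(
            mixed_table.subset("cancer")["cell_id"].tolist())

    def test_reproducible_from_seed(self, small_table):
        assert select_seeds(small_table, 10, 42) == select_seeds(small_table, 10, 42)
        assert select_seeds(small_table, 10, 42) != select_seeds(small_table, 10, 43)

    def test_target_class_respected(self, mixed_table):
        seeds = select_seeds(mixed_table, 5, 0, target_class="lymphocyte")
        pool = set(mixed_table.subset("lymphocyte")["cell_id"])
        assert set(seeds) <= pool

    def test_requesting_too_many_raises(self, mixed_table):
        with pytest.raises(ValueError, match="seeds"):
            select_seeds(mixed_table, 10_000, 0)

    def test_selection_frequency_is_uniform(self, small_table):
        # each of 60 cells should be drawn with frequency ~ N/n = 1/6
        counts = {cid: 0 for cid in small_table.data.cell_id}
        reps = 600
        for r in range(reps):
            for cid in select_seeds(small_table, 10, rng_seed=r):
                counts[cid] += 1
        freqs = np.array(list(counts.values())) / reps
        assert np.all(np.abs(freqs - 1 / 6) < 0.08)


class TestZoneMap:
    def test_cells_go_to_nearest_seed(self):
        t = table_from_points([(0, 0), (10, 0), (2, 0), (9, 0)])
        _, poly = None, box(-1, -1, 11, 1)
        zm = build_zone_map(t, [0, 1], poly)
        assert zm.assignment[2] == 0
        assert zm.assignment[3] == 1

    def test_tie_broken_by_smaller_seed_cell_id(self):
        t = table_from_points([(0, 0), (10, 0), (5.0, 3.0)])
        zm = build_zone_map(t, [1, 0], box(-1, -1, 11, 4))
        assert zm.assignment[2] == zm.seed_cell_ids.index(0)

    def test_brute_force_nearest_oracle(self):
        t = make_cells(n=100, seed=7)
        _, poly = compute_tissue_area(t)
        seeds = select_seeds(t, 12, rng_seed=3)
        zm = build_zone_map(t, seeds, poly)
        xy = t.coords
        seed_xy = zm.seed_coords
        for i in range(len(t)):
            d = np.hypot(*(xy[i] - seed_xy).T)
            assert d[zm.assignment[i]] <= d.min() + 1e-9

    def test_assignment_invariant_under_seed_order(self):
        t = make_cells(n=80, seed=9)
        _, poly = compute_tissue_area(t)
        seeds = select_seeds(t, 10, rng_seed=1)
        zm1 = build_zone_map(t, seeds, poly)
        zm2 = build_zone_map(t, seeds[::-1], poly)
        to_seed1 = np.array(zm1.seed_cell_ids)[zm1.assignment]
        to_seed2 = np.array(zm2.seed_cell_ids)[zm2.assignment]
        assert (to_seed1 == to_seed2).all()

    def test_every_zone_contains_its_seed(self):
        t = make_cells(n=150, seed=11)
        _, poly = compute_tissue_area(t)
        seeds = select_seeds(t, 20, rng_seed=5)
        zm = build_zone_map(t, seeds, poly)
        rows = t.data.set_index("cell_id")
        for k, sid in enumerate(zm.seed_cell_ids):
            row = t.data.index[t.data.cell_id == sid][0]
            assert zm.assignment[row] == k

    def test_clipped_regions_tile_the_tissue(self):
        t = make_cells(n=200, seed=13)
        area, poly = compute_tissue_area(t)
        zm = build_zone_map(t, select_seeds(t, 25, 2), poly)
        total = sum(r.area for r in zm.regions)
        assert total == pytest.approx(area, rel=1e-9)
        for i in range(zm.m):
            for j in range(i + 1, zm.m):
                inter = zm.regions[i].intersection(zm.regions[j])
                assert inter.area < 1e-6

    def test_duplicate_seed_coordinates_rejected(self):
        t = table_from_points([(0, 0), (0, 0), (5, 5)])
        with pytest.raises(GeometryError, match="duplicate"):
            build_zone_map(t, [0, 1], box(-1, -1, 6, 6))

    def test_empty_seed_list_rejected(self, small_table):
        with pytest.raises(ValueError):
            build_zone_map(small_table, [], box(0, 0, 1, 1))


def zone_map_from_polygons(polys):
    return ZoneMap(
        seed_cell_ids=list(range(len(polys))),
        seed_coords=np.array([[p.centroid.x, p.centroid.y] for p in polys]),
        regions=list(polys),
        assignment=np.arange(len(polys)),
        tissue_polygon=box(0, 0, 10, 10),
    )


class TestQueenContiguity:
    def test_2x2_grid_all_mutually_adjacent(self):
        squares = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(0, 1, 1, 2),
                   box(1, 1, 2, 2)]
        w = neighbor_graph(zone_map_from_polygons(squares))
        # corner contact (0,3) and (1,2) counts under the queen rule
        assert w.edge_list() == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

    def test_1x3_strip_ends_not_adjacent(self):
        strip = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(2, 0, 3, 1)]
        w = neighbor_graph(zone_map_from_polygons(strip))
        assert w.edge_list() == [(0, 1), (1, 2)]
        assert w.weight(0, 2) == 0

    def test_weights_symmetric_zero_diagonal(self):
        t = make_cells(n=300, seed=17)
        _, poly = compute_tissue_area(t)
        zm = build_zone_map(t, select_seeds(t, 30, 4), poly)
        w = neighbor_graph(zm)
        for i in range(zm.m):
            assert w.weight(i, i) == 0
            for j in w.neighbors(i):
                assert w.weight(j, i) == 1

    def test_adjacency_matches_geometric_brute_force(self):
        t = make_cells(n=500, seed=19)
        _, poly = compute_tissue_area(t)
        zm = build_zone_map(t, select_seeds(t, 50, 6), poly)
        w = neighbor_graph(zm)
        expected = set()
        for i in range(zm.m):
            for j in range(i + 1, zm.m):
                if zm.regions[i].intersects(zm.regions[j]):
                    expected.add((i, j))
        assert set(w.edge_list()) == expected

    def test_degenerate_polygon_raises(self):
        degenerate = Polygon([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(GeometryError):
            neighbor_graph(zone_map_from_polygons([degenerate, box(0, 0, 1, 1)]))
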