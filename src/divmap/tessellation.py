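"""Voronoi partitioning of a slide into cancer-seeded zones.

A slide is partitioned by (1) estimating the tissue region from the cell
point pattern, (2) choosing the number of seeds from the tissue area,
(3) drawing that many cancer cells uniformly at random as seeds, and
(4) assigning every cell to its nearest seed.  The Voronoi polygons, clipped
to the tissue boundary, carry the spatial structure: two zones are neighbors
under queen contiguity — they share a boundary edge or even a single point.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import GeometryCollection, MultiPoint, Point, Polygon
from shapely.ops import unary_union, voronoi_diagram

from .io import CellTable


class GeometryError(ValueError):
    """Raised for degenerate point patterns or polygons."""


@dataclasses.dataclass
class ZoneMap:
    """A seeded Voronoi partition of a slide.

    Attributes
    ----------
    seed_cell_ids : list
        Cell ids of the seed cancer cells; zone ``k`` is seeded by
        ``seed_cell_ids[k]``.
    regions : list of shapely.Polygon
        Zone polygons clipped to the tissue boundary, indexed by zone id.
    assignment : numpy.ndarray
        Zone id for every cell, aligned with the cell table's row order.
    tissue_polygon : shapely.Polygon
        The clipping boundary.
    slide_id : str
        Identity of the slide the map was built on.
    """

    seed_cell_ids: list
    seed_coords: np.ndarray
    regions: list
    assignment: np.ndarray
    tissue_polygon: Polygon
    slide_id: str = "slide"

    @property
    def m(self) -> int:
        """Number of zones."""
        return len(self.seed_cell_ids)

    def cells_in_zone(self, zone_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == zone_id)

    def to_geojson(self) -> dict:
        """Serialize zones as a GeoJSON FeatureCollection."""
        feats = []
        for k, poly in enumerate(self.regions):
            feats.append({
                "type": "Feature",
                "geometry": shapely.geometry.mapping(poly),
                "properties": {
                    "zone_id": k,
                    "seed_cell_id": self.seed_cell_ids[k],
                    "n_cells": int((self.assignment == k).sum()),
                },
            })
        return {"type": "FeatureCollection", "features": feats}


@dataclasses.dataclass
class WeightsGraph:
    """Binary symmetric queen-contiguity weights between zones."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self.graph.neighbors(i))

    def degree(self, i: int) -> int:
        return self.graph.degree[i]

    def weight(self, i: int, j: int) -> int:
        return int(i != j and self.graph.has_edge(i, j))

    def subgraph(self, nodes) -> "WeightsGraph":
        return WeightsGraph(nx.Graph(self.graph.subgraph(nodes)))

    def adjacency_matrix(self, order=None) -> np.ndarray:
        order = self.nodes if order is None else list(order)
        return nx.to_numpy_array(self.graph, nodelist=order, dtype=float)

    def edge_list(self):
        return sorted((min(i, j), max(i, j)) for i, j in self.graph.edges)


def compute_tissue_area(
    table: CellTable, method: str = "convex_hull", alpha: float | None = None
) -> tuple[float, Polygon]:
    """Estimate the tissue region covered by the cell point pattern.

    Parameters
    ----------
    method : {"convex_hull", "alpha_shape"}
        ``convex_hull`` (default) is the parameter-free choice;
        ``alpha_shape`` keeps Delaunay triangles with circumradius below
        ``1/alpha`` and can carve concavities for ragged sections.
    alpha : float, optional
        Inverse circumradius threshold (1/µm) for the alpha shape.

    Returns
    -------
    (area, polygon) : area in µm² and the polygon used for clipping.
    """
    pts = np.unique(table.coords, axis=0)
    if len(pts) < 3:
        raise GeometryError("need at least 3 distinct cells to form a tissue polygon")
    if method == "convex_hull":
        poly = MultiPoint(pts).convex_hull
    elif method == "alpha_shape":
        if alpha is None or alpha <= 0:
            raise ValueError("alpha_shape requires a positive alpha")
        poly = _alpha_shape(pts, alpha)
    else:
        raise ValueError(f"unknown tissue-area method {method!r}")
    if not isinstance(poly, Polygon) or poly.area <= 0:
        raise GeometryError("cell pattern is degenerate (collinear points?)")
    return float(poly.area), poly


def _alpha_shape(pts: np.ndarray, alpha: float) -> Polygon:
    """Union of Delaunay triangles with circumradius < 1/alpha."""
    tri = Delaunay(pts)
    keep = []
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                      np.linalg.norm(a - b))
        s = (la + lb + lc) / 2.0
        area2 = s * (s - la) * (s - lb) * (s - lc)
        if area2 <= 0:
            continue
        circum_r = la * lb * lc / (4.0 * np.sqrt(area2))
        if circum_r < 1.0 / alpha:
            keep.append(Polygon(pts[simplex]))
    if not keep:
        raise GeometryError("alpha too large: no triangles kept")
    merged = unary_union(keep)
    if isinstance(merged, (GeometryCollection,)) or merged.geom_type == "MultiPolygon":
        # keep the largest component
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged


def seed_count(area: float, area_unit_scale: float = 1.0) -> int:
    """Number of Voronoi seeds for a tissue of a given area.

    The seed count grows with the square root of the tissue area,
    ``N = floor(sqrt(area / area_unit_scale) / 3)``, floored at 1, so that
    zone size tracks tissue size rather than cell count.  ``area_unit_scale``
    (µm² per area unit) absorbs the unit in which the area is expressed
    before the square-root rule is applied.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if area_unit_scale <= 0:
        raise ValueError("area_unit_scale must be positive")
    return max(1, int(np.floor(np.sqrt(area / area_unit_scale) / 3.0)))


def select_seeds(
    table: CellTable, n_seeds: int, rng_seed: int, target_class: str = "cancer"
) -> list:
    """Draw ``n_seeds`` distinct cells of ``target_class`` uniformly at random.

    Reproducible from ``rng_seed``; returns their cell ids in draw order.
    """
    pool = table.subset(target_class)
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if len(pool) < n_seeds:
        raise ValueError(
            f"requested {n_seeds} seeds but table has only "
            f"{len(pool)} {target_class} cells"
        )
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(pool), size=n_seeds, replace=False)
    return pool["cell_id"].to_numpy()[idx].tolist()


def build_zone_map(
    table: CellTable, seeds: list, tissue_polygon: Polygon
) -> ZoneMap:
    """Assign every cell to its nearest seed and build clipped Voronoi polygons.

    Assignment is by Euclidean distance to the seed cells' centroids; a cell
    equidistant from several seeds goes to the seed with the smallest
    ``cell_id`` (deterministic and independent of seed order).  Voronoi
    polygons are clipped to ``tissue_polygon`` so every zone is a bounded
    polygon; a zone always contains at least its own seed cell.
    """
    if len(seeds) == 0:
        raise ValueError("empty seed list")
    df = table.data
    id_to_row = dict(zip(df["cell_id"], range(len(df))))
    try:
        rows = [id_to_row[s] for s in seeds]
    except KeyError as e:
        raise ValueError(f"seed cell id {e.args[0]!r} not present in table") from e
    if len(set(rows)) != len(rows):
        raise ValueError("duplicate seed cell ids")
    seed_xy = table.coords[rows]
    uniq = np.unique(seed_xy, axis=0)
    if len(uniq) != len(seed_xy):
        raise GeometryError("duplicate seed coordinates; cannot tessellate")

    assignment = _nearest_seed_assignment(table.coords, seed_xy, seeds)
    regions = _clipped_voronoi_polygons(seed_xy, tissue_polygon)
    return ZoneMap(
        seed_cell_ids=list(seeds),
        seed_coords=seed_xy,
        regions=regions,
        assignment=assignment,
        tissue_polygon=tissue_polygon,
        slide_id=table.slide_id,
    )


def _nearest_seed_assignment(xy: np.ndarray, seed_xy: np.ndarray, seeds: list,
                             rtol: float = 1e-9) -> np.ndarray:
    """Nearest-seed labels with ties broken by the smaller seed cell_id."""
    n_seeds = len(seed_xy)
    tree = cKDTree(seed_xy)
    k = min(4, n_seeds)
    dist, idx = tree.query(xy, k=k)
    if k == 1:
        return np.asarray(idx).ravel()
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    assignment = idx[:, 0].copy()
    tied = dist[:, 1] <= dist[:, 0] * (1 + rtol)
    for i in np.flatnonzero(tied):
        d0 = dist[i, 0]
        cand = idx[i, dist[i] <= d0 * (1 + rtol)]
        assignment[i] = min(cand, key=lambda z: _id_key(seeds[z]))
    return assignment


def _id_key(cell_id):
    # order ids numerically when possible, lexically otherwise
    try:
        return (0, float(cell_id), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(cell_id))


def _clipped_voronoi_polygons(seed_xy: np.ndarray, tissue: Polygon) -> list:
    """Voronoi polygon per seed, clipped to the tissue polygon."""
    if len(seed_xy) == 1:
        return [Polygon(tissue.exterior)]
    envelope = tissue.buffer(2.0 * max(tissue.bounds[2] - tissue.bounds[0],
                                       tissue.bounds[3] - tissue.bounds[1],
                                       1.0)).envelope
    diagram = voronoi_diagram(MultiPoint(seed_xy), envelope=envelope)
    # voronoi_diagram does not preserve input order: match cells to seeds
    cells = list(diagram.geoms)
    tree = shapely.STRtree(cells)
    regions: list = [None] * len(seed_xy)
    for k, (x, y) in enumerate(seed_xy):
        pt = Point(x, y)
        hit = None
        for j in tree.query(pt):
            if cells[j].covers(pt):
                hit = cells[j]
                break
        if hit is None:  # pragma: no cover - numerical fallback
            j = int(tree.nearest(pt))
            hit = cells[j]
        clipped = hit.intersection(tissue)
        if clipped.is_empty or clipped.area <= 0:
            raise GeometryError(f"zone {k} degenerate after clipping")
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        regions[k] = clipped
    return regions


def neighbor_graph(zone_map: ZoneMap) -> WeightsGraph:
    """Queen-contiguity weights: w_ij = 1 iff zone polygons i and j touch.

    Contact through a single shared point counts.  Polygons coming from one
    Voronoi diagram share exact vertices, so the GEOS intersection predicate
    is reliable; interiors are disjoint by construction.
    """
    for k, poly in enumerate(zone_map.regions):
        if poly.is_empty or poly.area <= 0:
            raise GeometryError(f"zone {k} has a degenerate polygon")
    g = nx.Graph()
    g.add_nodes_from(range(zone_map.m))
    tree = shapely.STRtree(zone_map.regions)
    pairs = tree.query(zone_map.regions, predicate="intersects")
    for i, j in pairs.T:
        if i < j:
            g.add_edge(int(i), int(j))
    return WeightsGraph(g)
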