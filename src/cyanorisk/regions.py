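"""Areal units: county polygons, Queen contiguity, GeoJSON round-trip.

A :class:`CountyMap` is the package's in-memory representation of a set of
counties: polygon geometries with stable string identifiers, precomputed
areas/centroids, and a Queen-contiguity adjacency structure (two counties are
neighbors when their polygons share at least one boundary point — an edge or
a single vertex).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, shape, mapping

logger = logging.getLogger(__name__)

__all__ = ["CountyMap", "queen_adjacency"]


def queen_adjacency(polygons: list[Polygon]) -> list[list[int]]:
    """Queen-contiguity neighbor lists from polygon geometry.

    Polygons are adjacent when they intersect in at least one point
    (shared border or shared vertex).  Self-adjacency is excluded.
    """
    tree = shapely.STRtree(polygons)
    left, right = tree.query(np.array(polygons, dtype=object), predicate="intersects")
    neighbors: list[set[int]] = [set() for _ in polygons]
    for i, j in zip(left.tolist(), right.tolist()):
        if i != j:
            neighbors[i].add(j)
            neighbors[j].add(i)
    return [sorted(s) for s in neighbors]


@dataclass
class CountyMap:
    """Set of county polygons with Queen adjacency.

    Parameters
    ----------
    ids : list of str
        Unique county identifiers, aligned with ``polygons``.
    polygons : list of shapely.Polygon
    neighbors : list of list of int, optional
        Queen-contiguity neighbor lists by positional index; computed from
        the geometry when omitted.
    """

    ids: list[str]
    polygons: list[Polygon]
    neighbors: list[list[int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.polygons):
            raise ValueError("ids and polygons must be aligned")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("county ids must be unique")
        if self.neighbors is None:
            self.neighbors = queen_adjacency(self.polygons)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.polygons])

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of polygon centroid coordinates."""
        return np.array([[p.centroid.x, p.centroid.y] for p in self.polygons])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        b = np.array([p.bounds for p in self.polygons])
        return (b[:, 0].min(), b[:, 1].min(), b[:, 2].max(), b[:, 3].max())

    def index_of(self, county_id: str) -> int:
        try:
            return self.ids.index(county_id)
        except ValueError:
            raise KeyError(f"unknown county id {county_id!r}") from None

    def adjacency_graph(self):
        """Adjacency as a networkx Graph on positional indices."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self)))
        for i, nbrs in enumerate(self.neighbors):
            g.add_edges_from((i, j) for j in nbrs if j > i)
        return g

    def connected_components(self) -> list[np.ndarray]:
        import networkx as nx

        g = self.adjacency_graph()
        return [np.array(sorted(c)) for c in nx.connected_components(g)]

    # ---------------------------------------------------------------- I/O

    def to_geojson(self, path) -> None:
        """Write polygon features with a ``county_id`` property."""
        features = [
            {
                "type": "Feature",
                "properties": {"county_id": cid},
                "geometry": mapping(poly),
            }
            for cid, poly in zip(self.ids, self.polygons)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "CountyMap":
        with open(path) as fh:
            gj = json.load(fh)
        ids, polys = [], []
        for feat in gj["features"]:
            ids.append(str(feat["properties"]["county_id"]))
            polys.append(shape(feat["geometry"]))
        return cls(ids=ids, polygons=polys)
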