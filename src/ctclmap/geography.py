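"""Rook-contiguity adjacency structures over census tracts.

The spatial prior in the disease-mapping model is supported on a neighborhood
graph: two tracts are neighbors iff they share a boundary segment of positive
length ("rook's case"); tracts that touch only at a corner are not neighbors.
This module builds that graph from polygons, rectangular grids, or explicit
edge lists, and repairs zero-neighbor tracts (islands), for which an intrinsic
CAR prior is undefined.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

#: Minimum shared-boundary length (in coordinate units) that counts as a rook
#: contact; separates true shared edges from corner touches under
#: floating-point polygon arithmetic.
ROOK_LENGTH_TOL = 1e-9


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, loop-free neighborhood graph over tract identifiers.

    Parameters
    ----------
    node_ids
        Ordered tract identifiers. The order fixes the index used by the
        spatial field vector everywhere downstream.
    edges
        Unordered pairs of adjacent tract ids.
    """

    node_ids: tuple[Hashable, ...]
    edges: frozenset[frozenset]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        known = set(self.node_ids)
        if len(known) != len(self.node_ids):
            raise ValueError("duplicate tract ids in adjacency graph")
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not set(pair) <= known:
                raise ValueError(f"edge {set(e)} references unknown tract(s)")
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.node_ids)}
        )

    @classmethod
    def from_edges(
        cls, node_ids: Sequence[Hashable], edges: Iterable[tuple]
    ) -> "AdjacencyGraph":
        return cls(
            node_ids=tuple(node_ids),
            edges=frozenset(frozenset(e) for e in edges),
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, tract: Hashable) -> int:
        return self._index[tract]

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as two integer arrays (i, j) with i < j, sorted for determinism."""
        pairs = sorted(
            tuple(sorted((self._index[a], self._index[b])))
            for a, b in (tuple(e) for e in self.edges)
        )
        if not pairs:
            return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
        arr = np.asarray(pairs, dtype=np.intp)
        return arr[:, 0], arr[:, 1]

    def neighbor_counts(self) -> dict:
        counts = {t: 0 for t in self.node_ids}
        for e in self.edges:
            a, b = tuple(e)
            counts[a] += 1
            counts[b] += 1
        return counts

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.intp)
        i, j = self.edge_index_arrays()
        np.add.at(deg, i, 1)
        np.add.at(deg, j, 1)
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.to_networkx())

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - A in node order (ICAR precision / tau^2)."""
        n = self.n_nodes
        lap = np.zeros((n, n))
        i, j = self.edge_index_arrays()
        lap[i, j] = -1.0
        lap[j, i] = -1.0
        deg = self.degrees().astype(float)
        lap[np.diag_indices(n)] = deg
        return lap


def rook_adjacency(geometries: Mapping[Hashable, BaseGeometry]) -> AdjacencyGraph:
    """Build the rook-contiguity graph from tract polygons.

    Two tracts are adjacent iff the intersection of their boundaries has
    length greater than :data:`ROOK_LENGTH_TOL` — a shared segment, not a
    shared corner point.

    Parameters
    ----------
    geometries
        Mapping of tract id to (multi)polygon; iteration order fixes node order.
    """
    ids = list(geometries.keys())
    for tract, geom in geometries.items():
        if geom is None or geom.is_empty:
            raise ValueError(f"tract {tract!r} has empty geometry")
        if not geom.is_valid:
            raise ValueError(f"tract {tract!r} has invalid geometry")

    # STRtree-free O(n^2) with bounding-box prefilter: tract counts here are
    # a few thousand at most.
    edges = []
    bounds = {t: geometries[t].bounds for t in ids}
    for a_pos, a in enumerate(ids):
        ax0, ay0, ax1, ay1 = bounds[a]
        ga = geometries[a]
        for b in ids[a_pos + 1 :]:
            bx0, by0, bx1, by1 = bounds[b]
            if bx0 > ax1 or ax0 > bx1 or by0 > ay1 or ay0 > by1:
                continue
            inter = ga.boundary.intersection(geometries[b].boundary)
            if not inter.is_empty and inter.length > ROOK_LENGTH_TOL:
                edges.append((a, b))
    return AdjacencyGraph.from_edges(ids, edges)


def grid_adjacency(rows: int, cols: int) -> AdjacencyGraph:
    """Rook graph of a ``rows x cols`` lattice; node ids ``"r{r}c{c}"``, row-major."""
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    ids = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((f"r{r}c{c}", f"r{r}c{c + 1}"))
            if r + 1 < rows:
                edges.append((f"r{r}c{c}", f"r{r + 1}c{c}"))
    return AdjacencyGraph.from_edges(ids, edges)


def handle_islands(
    graph: AdjacencyGraph,
    policy: str = "connect-nearest",
    centroids: Mapping[Hashable, tuple[float, float]] | None = None,
) -> AdjacencyGraph:
    """Resolve zero-neighbor tracts so the ICAR prior is well defined.

    Policies: ``connect-nearest`` adds one edge from each island to the
    nearest-centroid non-island tract (requires ``centroids``); ``drop``
    removes islands; ``error`` raises, listing them. Connected graphs are
    returned unchanged under any policy.
    """
    counts = graph.neighbor_counts()
    islands = [t for t in graph.node_ids if counts[t] == 0]
    if not islands:
        return graph
    if policy == "error":
        raise ValueError(f"tracts with zero neighbors: {islands}")
    if policy == "drop":
        keep = [t for t in graph.node_ids if t not in set(islands)]
        logger.warning("dropping %d island tract(s): %s", len(islands), islands)
        return AdjacencyGraph(node_ids=tuple(keep), edges=graph.edges)
    if policy == "connect-nearest":
        if centroids is None:
            raise ValueError("connect-nearest policy requires tract centroids")
        mainland = [t for t in graph.node_ids if counts[t] > 0]
        if not mainland:
            raise ValueError("all tracts are islands; cannot connect-nearest")
        new_edges = set(graph.edges)
        for t in islands:
            cx, cy = centroids[t]
            nearest = min(
                mainland,
                key=lambda m: (centroids[m][0] - cx) ** 2
                + (centroids[m][1] - cy) ** 2,
            )
            warnings.warn(
                f"island tract {t!r} connected to nearest tract {nearest!r}",
                stacklevel=2,
            )
            new_edges.add(frozenset((t, nearest)))
        return AdjacencyGraph(node_ids=graph.node_ids, edges=frozenset(new_edges))
    raise ValueError(f"unknown island policy: {policy!r}")


def read_geojson(path) -> dict[Hashable, BaseGeometry]:
    """Read tract polygons from a GeoJSON FeatureCollection.

    The tract id is the feature's ``id`` or its ``tract_id`` property.
    """
    with open(path) as fh:
        gj = json.load(fh)
    geometries: dict[Hashable, BaseGeometry] = {}
    for feat in gj["features"]:
        tract = feat.get("id", feat.get("properties", {}).get("tract_id"))
        if tract is None:
            raise ValueError("GeoJSON feature without id or tract_id property")
        geometries[tract] = shapely_shape(feat["geometry"])
    return geometries


def read_edge_list(path, node_ids: Sequence[Hashable] | None = None) -> AdjacencyGraph:
    """Read a two-column whitespace/tab-delimited edge list.

    Node order is ``node_ids`` if given, else first-appearance order.
    """
    edges = []
    seen: list = []
    seen_set = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            edges.append((a, b))
            for t in (a, b):
                if t not in seen_set:
                    seen.append(t)
                    seen_set.add(t)
    return AdjacencyGraph.from_edges(list(node_ids) if node_ids is not None else seen, edges)


def write_edge_list(graph: AdjacencyGraph, path) -> None:
    i, j = graph.edge_index_arrays()
    with open(path, "w") as fh:
        fh.write("# tract_a\ttract_b\n")
        for a, b in zip(i, j):
            fh.write(f"{graph.node_ids[a]}\t{graph.node_ids[b]}\n")
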