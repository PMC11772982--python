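"""Sulcal pit/basin graph extraction from a triangulated cortical surface.

The sulcal pattern is represented as a graph whose nodes are sulcal
pits — the locally deepest points of sulcal catchment basins on a
per-vertex sulcal depth map (larger depth = deeper) — together with
their surrounding basins, and whose edges connect pits of basins that
meet on the surface.  Basins are delineated by watershed segmentation
of a smoothed depth map; shallow basins are merged into their deeper
neighbor by a relative ridge-height criterion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)

DEFAULT_SMOOTHING_ITERATIONS = 10
DEFAULT_MERGE_RIDGE_FRACTION = 0.3


@dataclass
class SurfaceMesh:
    """Triangulated surface patch with a per-vertex sulcal depth map."""

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) vertex indices
    depth: np.ndarray  # (n,) mm, larger = deeper
    region: str = "hemisphere"
    hemisphere: str = "L"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.depth = np.asarray(self.depth, dtype=float)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= n):
            raise ValueError("faces index invalid vertices")
        if len(self.depth) != n:
            raise ValueError("depth must have one value per vertex")
        if not np.all(np.isfinite(self.depth)) or np.any(self.depth < 0):
            raise ValueError("depth must be finite and >= 0")

    def vertex_neighbors(self) -> list[np.ndarray]:
        """1-ring neighbor indices per vertex."""
        neighbors: list[set[int]] = [set() for _ in self.vertices]
        for a, b, c in self.faces:
            neighbors[a].update((b, c))
            neighbors[b].update((a, c))
            neighbors[c].update((a, b))
        return [np.fromiter(sorted(s), dtype=int) for s in neighbors]

    def vertex_areas(self) -> np.ndarray:
        """One third of the incident face area, per vertex."""
        areas = np.zeros(len(self.vertices))
        v = self.vertices
        for a, b, c in self.faces:
            face_area = 0.5 * np.linalg.norm(
                np.cross(v[b] - v[a], v[c] - v[a]))
            share = face_area / 3.0
            areas[a] += share
            areas[b] += share
            areas[c] += share
        return areas


@dataclass
class SulcalNode:
    """One sulcal pit with its catchment-basin geometry and topology."""

    node_id: int
    position: np.ndarray  # (3,) mm, pit vertex coordinates
    depth: float  # mm, smoothed depth at the pit
    area: float  # mm^2, basin surface area
    degree: int = 0
    mean_path_length: float = 0.0

    @property
    def topology(self) -> np.ndarray:
        return np.array([float(self.degree), self.mean_path_length])


@dataclass
class SulcalGraph:
    nodes: list[SulcalNode]
    edges: list[tuple[int, int]]
    region: str = "hemisphere"
    hemisphere: str = "L"
    participant: str | None = None

    def __post_init__(self):
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loop edge")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError("duplicate edge")
            seen.add(key)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(n.node_id for n in self.nodes)
        g.add_edges_from(self.edges)
        return g

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes])

    def to_json_dict(self) -> dict:
        return {
            "region": self.region,
            "hemisphere": self.hemisphere,
            "participant": self.participant,
            "nodes": [
                {"id": n.node_id, "x": n.position[0], "y": n.position[1],
                 "z": n.position[2], "depth": n.depth, "area": n.area}
                for n in self.nodes
            ],
            "edges": [[a, b] for a, b in self.edges],
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "SulcalGraph":
        nodes = [
            SulcalNode(
                node_id=nd["id"],
                position=np.array([nd["x"], nd["y"], nd["z"]], dtype=float),
                depth=float(nd["depth"]),
                area=float(nd["area"]),
            )
            for nd in data["nodes"]
        ]
        graph = cls(
            nodes=nodes,
            edges=[tuple(e) for e in data["edges"]],
            region=data.get("region", "hemisphere"),
            hemisphere=data.get("hemisphere", "L"),
            participant=data.get("participant"),
        )
        compute_topology(graph)
        return graph

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SulcalGraph":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def compute_topology(graph: SulcalGraph) -> None:
    """Fill per-node degree and mean shortest-path length (hop count).

    Path lengths are averaged over the node's connected component; a
    singleton component has mean path length 0.
    """
    g = graph.to_networkx()
    paths = dict(nx.all_pairs_shortest_path_length(g))
    for node in graph.nodes:
        lengths = paths[node.node_id]
        others = [d for target, d in lengths.items()
                  if target != node.node_id]
        node.degree = g.degree[node.node_id]
        node.mean_path_length = float(np.mean(others)) if others else 0.0


def smooth_depth(
    mesh: SurfaceMesh,
    iterations: int = DEFAULT_SMOOTHING_ITERATIONS,
) -> np.ndarray:
    """Iterative umbrella smoothing of the depth map.

    Each vertex is replaced by the mean of itself and its 1-ring
    neighbors, ``iterations`` times.  Isolated vertices are left
    unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    depth = mesh.depth.astype(float).copy()
    neighbors = mesh.vertex_neighbors()
    isolated = [i for i, nb in enumerate(neighbors) if nb.size == 0]
    if isolated:
        log.warning("smooth_depth: %d isolated vertices left unchanged",
                    len(isolated))
    for _ in range(iterations):
        new = depth.copy()
        for i, nb in enumerate(neighbors):
            if nb.size:
                new[i] = (depth[i] + depth[nb].sum()) / (1 + nb.size)
        depth = new
    return depth


def detect_pits_watershed(
    mesh: SurfaceMesh,
    smoothed_depth: np.ndarray,
    merge_ridge_fraction: float = DEFAULT_MERGE_RIDGE_FRACTION,
) -> tuple[list[int], np.ndarray, list[tuple[int, int]]]:
    """Watershed segmentation of the smoothed depth map.

    Vertices are flooded in order of decreasing depth.  A vertex with
    no labeled neighbor founds a new basin (it is a pit: a local depth
    maximum); otherwise it joins the basin of its deepest labeled
    neighbor.  When two basins first meet at a ridge vertex they merge
    if ``deeper pit depth - ridge depth < merge_ridge_fraction * deeper
    pit depth``, else both persist and the meeting is recorded for edge
    construction.  Plateau ties are broken by vertex index (lowest
    first).

    Returns ``(pit vertices, per-vertex basin label, basin meetings)``
    where labels index into the pit list.
    """
    n = len(mesh.vertices)
    if n == 0:
        raise ValueError("empty mesh")
    if not 0.0 <= merge_ridge_fraction <= 1.0:
        raise ValueError("merge_ridge_fraction must lie in [0, 1]")
    depth = np.asarray(smoothed_depth, dtype=float)
    neighbors = mesh.vertex_neighbors()
    # decreasing depth; ties by lowest vertex index
    order = np.lexsort((np.arange(n), -depth))

    parent = list(range(n + 16))  # union-find over basin ids

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    labels = np.full(n, -1, dtype=int)
    pits: list[int] = []
    pit_depth: list[float] = []
    meetings: set[tuple[int, int]] = set()

    for v in order:
        labeled = [u for u in neighbors[v] if labels[u] >= 0]
        if not labeled:
            basin = len(pits)
            if basin >= len(parent):
                parent.extend(range(len(parent), basin + 16))
            pits.append(int(v))
            pit_depth.append(float(depth[v]))
            labels[v] = basin
            continue
        # deepest labeled neighbor, ties by lowest vertex index
        best = min(labeled, key=lambda u: (-depth[u], u))
        basins = {find(labels[u]) for u in labeled}
        home = find(labels[best])
        labels[v] = home
        for other in basins - {home}:
            a, b = find(home), find(other)
            if a == b:
                continue
            deeper = max(pit_depth[a], pit_depth[b])
            if deeper - depth[v] < merge_ridge_fraction * deeper:
                # merge the shallower basin into the deeper one
                keep, drop = (a, b) if pit_depth[a] >= pit_depth[b] else (b, a)
                parent[drop] = keep
                labels[v] = find(labels[v])
            else:
                meetings.add((min(a, b), max(a, b)))

    # resolve union-find and compact surviving basin labels
    final = np.array([find(l) for l in labels])
    survivors = sorted(set(final), key=lambda b: pits[b])
    remap = {b: i for i, b in enumerate(survivors)}
    compact = np.array([remap[b] for b in final])
    surviving_pits = [pits[b] for b in survivors]
    surviving_meetings = sorted(
        {(min(remap[find(a)], remap[find(b)]),
          max(remap[find(a)], remap[find(b)]))
         for a, b in meetings
         if find(a) != find(b)}
    )
    return surviving_pits, compact, surviving_meetings


def build_graph(
    mesh: SurfaceMesh,
    pits: list[int],
    basin_labels: np.ndarray,
    basin_meetings: list[tuple[int, int]],
    smoothed_depth: np.ndarray | None = None,
) -> SulcalGraph:
    """Assemble the sulcal graph from the watershed output.

    One node per surviving basin: position and depth from the pit
    vertex, area the sum of one-third incident face areas over the
    basin's vertices; edges from the recorded basin meetings.
    """
    depth = mesh.depth if smoothed_depth is None else smoothed_depth
    vertex_area = mesh.vertex_areas()
    nodes = []
    for basin, pit_vertex in enumerate(pits):
        area = float(vertex_area[basin_labels == basin].sum())
        if area <= 0:
            raise ValueError(f"basin {basin} has zero area")
        nodes.append(SulcalNode(
            node_id=basin,
            position=mesh.vertices[pit_vertex].copy(),
            depth=float(depth[pit_vertex]),
            area=area,
        ))
    graph = SulcalGraph(nodes=nodes, edges=list(basin_meetings),
                        region=mesh.region, hemisphere=mesh.hemisphere)
    compute_topology(graph)
    return graph


def extract_sulcal_graph(
    mesh: SurfaceMesh,
    smoothing_iterations: int = DEFAULT_SMOOTHING_ITERATIONS,
    merge_ridge_fraction: float = DEFAULT_MERGE_RIDGE_FRACTION,
) -> SulcalGraph:
    """Smooth, segment and build the graph in one call."""
    smoothed = smooth_depth(mesh, smoothing_iterations)
    pits, labels, meetings = detect_pits_watershed(
        mesh, smoothed, merge_ridge_fraction)
    return build_graph(mesh, pits, labels, meetings, smoothed)


def load_mesh(surface_path, depth_table_path,
              region: str = "hemisphere",
              hemisphere: str = "L") -> SurfaceMesh:
    """Load an ASCII OFF/PLY surface plus a TSV of per-vertex depth.

    The TSV needs a ``depth`` column, one row per vertex in surface
    order; an optional ``region`` column overrides the region label.
    """
    import pandas as pd
    import trimesh

    mesh = trimesh.load(surface_path, process=False)
    table = pd.read_csv(depth_table_path, sep="\t")
    if "depth" not in table.columns:
        raise ValueError("depth table must have a 'depth' column")
    if len(table) != len(mesh.vertices):
        raise ValueError("depth table row count != vertex count")
    if "region" in table.columns:
        uniq = table["region"].unique()
        if len(uniq) == 1:
            region = str(uniq[0])
    return SurfaceMesh(
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
        depth=table["depth"].to_numpy(dtype=float),
        region=region,
        hemisphere=hemisphere,
    )
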