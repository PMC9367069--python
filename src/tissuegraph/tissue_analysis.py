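"""Downstream neighborhood analyses on a tissue graph.

Covers the read-outs a tissue graph is usually built for: degree and
link-length statistics, spheroid layer peeling with per-layer profiles, and
extraction of same-type cell clusters (connected components of the subgraph
induced by one phenotype).

Two layer definitions are provided.  *Hull peeling* assigns layer 0 to the
cells on the convex hull of all centroids, removes them, and iterates —
suited to point-cloud or Delaunay inputs such as nuclei-only spheroid
segmentations.  *Background contact* assigns layer 0 to cells whose mask
touches background or the image border, and deeper layers by minimum hop
count in the contact graph — suited to full-mask images.  Neither is claimed
to be canonical; the method used is recorded in the assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .cell_features import CellTable
from .errors import ConfigError, ValidationError
from .image_io import LabeledImage

__all__ = [
    "DegreeStats",
    "LinkLengthStats",
    "LayerAssignment",
    "ClusterReport",
    "degree_distribution",
    "link_length_distribution",
    "assign_layers",
    "per_layer_profile",
    "find_type_clusters",
    "type_composition",
]


@dataclass
class DegreeStats:
    """Per-node degrees with their histogram and moments."""

    degrees: dict[int, int]
    histogram: dict[int, int]  # degree value -> node count
    mean: float | None
    std: float | None


@dataclass
class LinkLengthStats:
    """Per-edge centre-to-centre distances with histogram and moments."""

    lengths: dict[tuple[int, int], float]
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)
    mean: float | None
    std: float | None


@dataclass
class LayerAssignment:
    """Map cell label -> layer index (0 = outermost)."""

    layers: dict[int, int]
    method: str

    @property
    def n_layers(self) -> int:
        return max(self.layers.values()) + 1 if self.layers else 0

    def members(self, layer: int) -> list[int]:
        return [n for n, l in self.layers.items() if l == layer]


@dataclass
class ClusterReport:
    """Same-type clusters: connected components within each phenotype."""

    clusters: list[tuple[str, frozenset[int]]] = field(default_factory=list)

    def sizes_by_type(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for ctype, members in self.clusters:
            out.setdefault(ctype, []).append(len(members))
        return {t: sorted(s, reverse=True) for t, s in out.items()}

    def fraction_clustered(self, min_size: int = 2) -> dict[str, float]:
        """Per type: fraction of its cells in clusters of size >= ``min_size``."""
        out: dict[str, float] = {}
        for ctype, sizes in self.sizes_by_type().items():
            total = sum(sizes)
            out[ctype] = sum(s for s in sizes if s >= min_size) / total if total else 0.0
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (k, ctype, len(members), " ".join(map(str, sorted(members))))
            for k, (ctype, members) in enumerate(self.clusters)
        ]
        return pd.DataFrame(rows, columns=["cluster", "cell_type", "size", "members"])


def degree_distribution(graph: nx.Graph) -> DegreeStats:
    """Degrees per node, their histogram, and mean/SD over nodes.

    An empty graph has no mean (reported as None).
    """
    degrees = {int(n): int(d) for n, d in graph.degree()}
    if not degrees:
        return DegreeStats({}, {}, None, None)
    vals = np.fromiter(degrees.values(), dtype=int)
    counts = np.bincount(vals)
    hist = {int(k): int(c) for k, c in enumerate(counts) if c > 0}
    return DegreeStats(degrees, hist, float(vals.mean()), float(vals.std()))


def link_length_distribution(graph: nx.Graph) -> LinkLengthStats:
    """Statistics of the ``distance`` edge attribute."""
    lengths: dict[tuple[int, int], float] = {}
    for u, v, data in graph.edges(data=True):
        if "distance" not in data:
            raise ValidationError(f"edge ({u}, {v}) has no distance attribute")
        key = (u, v) if u < v else (v, u)
        lengths[key] = float(data["distance"])
    if not lengths:
        return LinkLengthStats({}, (np.array([]), np.array([])), None, None)
    vals = np.fromiter(lengths.values(), dtype=float)
    counts, edges = np.histogram(vals)
    return LinkLengthStats(lengths, (counts, edges), float(vals.mean()), float(vals.std()))


def _node_positions(graph: nx.Graph) -> tuple[list[int], np.ndarray, int]:
    nodes = list(graph.nodes)
    first = graph.nodes[nodes[0]]
    if "x" not in first or "y" not in first:
        raise ConfigError("hull peeling requires x/y(/z) centroid node attributes")
    dim = 3 if "z" in first else 2
    cols = ["x", "y", "z"][:dim]
    pos = np.array([[graph.nodes[n][c] for c in cols] for n in nodes], dtype=float)
    return nodes, pos, dim


def _hull_peel(nodes: list[int], pos: np.ndarray, dim: int) -> dict[int, int]:
    layers: dict[int, int] = {}
    remaining = np.arange(len(nodes))
    layer = 0
    while remaining.size >= dim + 1:
        try:
            hull = ConvexHull(pos[remaining])
        except QhullError:
            break  # degenerate leftovers: all get the terminal layer below
        on_hull = remaining[hull.vertices]
        for k in on_hull:
            layers[nodes[k]] = layer
        keep = np.ones(remaining.size, dtype=bool)
        keep[hull.vertices] = False
        remaining = remaining[keep]
        layer += 1
    for k in remaining:
        layers[nodes[k]] = layer
    return layers


def _background_layer0(image: LabeledImage) -> set[int]:
    """Labels whose mask touches background (face adjacency) or the border."""
    lab = image.labels
    touching: set[int] = set()
    nd = lab.ndim
    for ax in range(nd):
        sl_a = tuple(slice(None, -1) if k == ax else slice(None) for k in range(nd))
        sl_b = tuple(slice(1, None) if k == ax else slice(None) for k in range(nd))
        a, b = lab[sl_a], lab[sl_b]
        touching.update(int(x) for x in np.unique(a[(a > 0) & (b == 0)]))
        touching.update(int(x) for x in np.unique(b[(b > 0) & (a == 0)]))
        border_lo = lab[tuple(slice(0, 1) if k == ax else slice(None) for k in range(nd))]
        border_hi = lab[tuple(slice(-1, None) if k == ax else slice(None) for k in range(nd))]
        touching.update(int(x) for x in np.unique(border_lo[border_lo > 0]))
        touching.update(int(x) for x in np.unique(border_hi[border_hi > 0]))
    return touching


def assign_layers(
    graph: nx.Graph,
    method: str = "hull-peeling",
    image: LabeledImage | None = None,
) -> LayerAssignment:
    """Assign each cell a concentric layer index, 0 being the surface.

    ``hull-peeling`` iteratively strips the convex hull of the remaining
    centroids; when fewer than ``dim + 1`` points remain (or they are
    degenerate) they all receive the next index and peeling stops.
    ``background-contact`` takes layer 0 as the cells whose mask touches
    background or the image border, then indexes deeper cells by minimum hop
    count to layer 0 in ``graph`` (use a contact graph).  Cells unreachable
    from the surface get the next index after the deepest reachable layer.
    """
    if graph.number_of_nodes() == 0:
        return LayerAssignment({}, method)
    if method == "hull-peeling":
        nodes, pos, dim = _node_positions(graph)
        return LayerAssignment(_hull_peel(nodes, pos, dim), method)
    if method == "background-contact":
        if image is None:
            raise ConfigError("background-contact layering requires the source image")
        layer0 = _background_layer0(image) & set(graph.nodes)
        if not layer0:
            layer0 = set(graph.nodes)  # fully interior tiling: everything is surface
        dist = nx.multi_source_dijkstra_path_length(graph, layer0, weight=None)
        layers = {int(n): int(d) for n, d in dist.items()}
        deepest = max(layers.values(), default=0)
        for n in graph.nodes:
            if n not in layers:
                layers[int(n)] = deepest + 1
        return LayerAssignment(layers, method)
    raise ConfigError(f"unknown layer method {method!r}")


def per_layer_profile(
    graph: nx.Graph, layers: LayerAssignment, mode: str = "incident"
) -> pd.DataFrame:
    """Mean degree and mean link length per layer.

    ``mode='incident'`` (default) averages the distances of all edges
    incident to a layer's nodes, which is defined even for sparse inner
    layers; ``mode='intra'`` restricts to edges with both endpoints in the
    layer.  Returns a DataFrame indexed by layer with columns ``n_cells``,
    ``mean_degree``, ``mean_link_length``.
    """
    if mode not in ("incident", "intra"):
        raise ConfigError(f"unknown profile mode {mode!r}")
    uncovered = [n for n in graph.nodes if n not in layers.layers]
    if uncovered:
        raise ValidationError(f"nodes without a layer: {sorted(uncovered)}")
    rows = []
    for layer in range(layers.n_layers):
        members = set(layers.members(layer))
        degs = [graph.degree(n) for n in members]
        dists = []
        for u, v, data in graph.edges(members, data=True):
            if mode == "intra" and not (u in members and v in members):
                continue
            dists.append(float(data["distance"]))
        rows.append(
            {
                "layer": layer,
                "n_cells": len(members),
                "mean_degree": float(np.mean(degs)) if degs else math.nan,
                "mean_link_length": float(np.mean(dists)) if dists else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("layer")


def find_type_clusters(graph: nx.Graph, type_attribute: str = "cell_type") -> ClusterReport:
    """Connected components of each phenotype's induced subgraph.

    For every observed type, the subgraph induced by that type's cells is
    split into connected components; each component is one cluster.  Clusters
    of one type are disjoint and together cover all cells of the type.
    """
    missing = [n for n, d in graph.nodes(data=True) if type_attribute not in d]
    if missing:
        raise ValidationError(f"nodes missing {type_attribute!r}: {sorted(missing)}")
    by_type: dict[str, list[int]] = {}
    for n, d in graph.nodes(data=True):
        by_type.setdefault(str(d[type_attribute]), []).append(n)
    report = ClusterReport()
    for ctype in sorted(by_type):
        sub = graph.subgraph(by_type[ctype])
        for comp in nx.connected_components(sub):
            report.clusters.append((ctype, frozenset(int(n) for n in comp)))
    return report


def type_composition(table: CellTable, type_attribute: str = "cell_type") -> dict[str, float]:
    """Fraction of cells of each type; fractions sum to 1 over observed types."""
    if type_attribute not in table.df.columns or len(table) == 0:
        return {}
    counts = table.df[type_attribute].value_counts()
    total = counts.sum()
    return {str(t): float(c) / float(total) for t, c in counts.items()}
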