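"""Polyline reconstruction from detection boxes.

The reconstruction chain turns a set of vessel detection boxes into vessel
centerline polylines in three stages, followed by a decomposition step:

1. **Neighbor graph** — box centers become graph nodes; two nodes are joined
   when their center distance is at most ``radius_factor`` times the mean of
   the two box diagonals, so the rule is scale-free in box size. Edge weights
   are Euclidean center distances in pixels.
2. **False-connection filtering** — proximity alone suggests spurious links
   between parallel vessels. Each candidate edge is tested against the image:
   the straight segment between its endpoints is sampled at 1-px arc steps and
   the edge is kept only if at least ``min_support`` of the samples land on
   foreground (pixels above the ``support_quantile`` intensity quantile of the
   equalized image).
3. **Cycle removal** — proximity links that survive filtering can still close
   loops that no vessel forms. Per connected component, the minimum-weight
   spanning tree (Kruskal; ties broken by lexicographic node order) is kept,
   so the output is a forest whose component partition matches the input.

Finally each tree is decomposed into maximal simple paths split at branch
nodes (degree ≥ 3); every edge appears in exactly one polyline, so the summed
polyline length equals the summed forest edge weight exactly.

Detector-center jitter puts small kinks into the reconstructed chains; the
kinks lengthen some segments and shorten others and largely cancel in the
total, which is why length measurements tolerate modest detector noise.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.utils import UnionFind

from .annotation import Polyline
from .detection import DetectionSet
from .errors import ValidationError
from .imaging import Image2D, equalize_histogram

logger = logging.getLogger(__name__)

#: VesselGraph: an undirected networkx graph whose nodes carry ``pos=(x, y)``
#: (the detection-box center) and ``box`` attributes, and whose edges carry
#: ``weight`` equal to the Euclidean distance between endpoint centers.
VesselGraph = nx.Graph


@dataclass
class ReconstructionConfig:
    """Tunables of the box→polyline chain (all distances in pixels)."""

    radius_factor: float = 1.25
    min_confidence: float = 0.0
    support_quantile: float = 0.8
    min_support: float = 0.7

    def __post_init__(self) -> None:
        if not (self.radius_factor > 0):
            raise ValidationError("radius_factor must be > 0")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValidationError("min_confidence must be in [0, 1]")
        if not (0.0 < self.support_quantile < 1.0):
            raise ValidationError("support_quantile must be in (0, 1)")
        if not (0.0 < self.min_support <= 1.0):
            raise ValidationError("min_support must be in (0, 1]")


def build_neighbor_graph(
    detections: DetectionSet, radius_factor: float = 1.25, min_confidence: float = 0.0
) -> VesselGraph:
    """Connect vessel boxes whose centers are within the neighbor radius.

    Only boxes labelled ``vessel`` with confidence at least ``min_confidence``
    become nodes. Nodes u, v are joined iff their center distance is positive
    and at most ``radius_factor × (diag_u + diag_v) / 2``. Coincident centers
    (distance 0) are left unconnected: a zero-weight edge carries no length and
    the chain reconnects through the next box along the vessel.
    """
    G: VesselGraph = nx.Graph()
    eligible = [b for b in detections.boxes if b.label == "vessel" and b.confidence >= min_confidence]
    for i, b in enumerate(eligible):
        G.add_node(i, pos=(b.cx, b.cy), box=b)
    if len(eligible) < 2:
        return G
    pos = np.array([[b.cx, b.cy] for b in eligible])
    diag = np.array([b.diagonal for b in eligible])
    d = np.hypot(pos[:, 0:1] - pos[None, :, 0], pos[:, 1:2] - pos[None, :, 1])
    limit = radius_factor * (diag[:, None] + diag[None, :]) / 2.0
    iu, ju = np.nonzero(np.triu((d > 0) & (d <= limit), k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        G.add_edge(i, j, weight=float(d[i, j]))
    return G


def filter_false_connections(
    graph: VesselGraph,
    image: Image2D,
    support_quantile: float = 0.8,
    min_support: float = 0.7,
) -> VesselGraph:
    """Drop edges whose straight segment lacks image foreground support.

    The foreground mask is the set of pixels strictly above the
    ``support_quantile`` quantile of the equalized image. Each edge segment is
    sampled at 1-px arc steps (endpoints included, nearest-pixel lookup) and
    kept iff the on-foreground fraction is at least ``min_support``. Nodes are
    never removed and kept edges are a subset of the input edges.
    """
    if not (0.0 < support_quantile < 1.0):
        raise ValidationError("support_quantile must be in (0, 1)")
    if not (0.0 < min_support <= 1.0):
        raise ValidationError("min_support must be in (0, 1]")
    H: VesselGraph = nx.Graph()
    H.add_nodes_from(graph.nodes(data=True))
    if graph.number_of_edges() == 0:
        return H
    eq = equalize_histogram(image)
    thr = np.quantile(eq.pixels, support_quantile)
    mask = eq.pixels > thr
    h, w = mask.shape
    for u, v, data in graph.edges(data=True):
        x0, y0 = graph.nodes[u]["pos"]
        x1, y1 = graph.nodes[v]["pos"]
        n = max(2, int(math.ceil(math.hypot(x1 - x0, y1 - y0))) + 1)
        xs = np.clip(np.rint(np.linspace(x0, x1, n)).astype(int), 0, w - 1)
        ys = np.clip(np.rint(np.linspace(y0, y1, n)).astype(int), 0, h - 1)
        support = float(mask[ys, xs].mean())
        if support >= min_support:
            H.add_edge(u, v, **data)
    return H


def edge_support(graph: VesselGraph, image: Image2D, u, v, support_quantile: float = 0.8) -> float:
    """Foreground-support fraction of one candidate edge (diagnostic helper)."""
    eq = equalize_histogram(image)
    thr = np.quantile(eq.pixels, support_quantile)
    mask = eq.pixels > thr
    x0, y0 = graph.nodes[u]["pos"]
    x1, y1 = graph.nodes[v]["pos"]
    n = max(2, int(math.ceil(math.hypot(x1 - x0, y1 - y0))) + 1)
    xs = np.clip(np.rint(np.linspace(x0, x1, n)).astype(int), 0, mask.shape[1] - 1)
    ys = np.clip(np.rint(np.linspace(y0, y1, n)).astype(int), 0, mask.shape[0] - 1)
    return float(mask[ys, xs].mean())


def remove_cycles(graph: VesselGraph) -> VesselGraph:
    """Minimum spanning forest: per component, the minimum-weight spanning tree.

    Kruskal over edges sorted by ``(weight, u, v)`` — the lexicographic node
    order breaks weight ties deterministically. The node set and the connected
    component partition are preserved; the output is acyclic with
    ``E = N − C`` edges.
    """
    T: VesselGraph = nx.Graph()
    T.add_nodes_from(graph.nodes(data=True))
    edges = sorted(
        ((data.get("weight", 1.0), *sorted((u, v)), data) for u, v, data in graph.edges(data=True)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    uf = UnionFind(graph.nodes())
    for w, u, v, data in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            T.add_edge(u, v, **data)
    return T


def graph_to_polylines(forest: VesselGraph) -> list[Polyline]:
    """Decompose an acyclic vessel graph into maximal simple-path polylines.

    Paths are split at branch nodes (degree ≥ 3); every edge lands in exactly
    one polyline, so total polyline length equals total forest edge weight.
    Isolated nodes (a single box has no extent) yield no polyline.
    """
    if forest.number_of_nodes() == 0:
        return []
    if forest.number_of_edges() > 0 and not nx.is_forest(forest):
        raise ValidationError("input graph contains cycles; run remove_cycles first")
    visited: set[tuple] = set()
    polylines: list[Polyline] = []
    terminals = sorted(n for n in forest.nodes if forest.degree(n) != 2)
    for t in terminals:
        for nb in sorted(forest.neighbors(t)):
            edge = tuple(sorted((t, nb)))
            if edge in visited:
                continue
            visited.add(edge)
            chain = [t, nb]
            prev, cur = t, nb
            while forest.degree(cur) == 2:
                nxt = next(n for n in forest.neighbors(cur) if n != prev)
                visited.add(tuple(sorted((cur, nxt))))
                chain.append(nxt)
                prev, cur = cur, nxt
            points = [tuple(map(float, forest.nodes[n]["pos"])) for n in chain]
            deduped = [points[0]]
            for pt in points[1:]:
                if pt != deduped[-1]:
                    deduped.append(pt)
            if len(deduped) >= 2:
                polylines.append(Polyline(tuple(deduped), "vessel"))
    return polylines


def reconstruct(
    detections: DetectionSet, image: Image2D, config: ReconstructionConfig | None = None
) -> list[Polyline]:
    """Full box→polyline chain: neighbor graph → support filter → MSF → paths."""
    cfg = config or ReconstructionConfig()
    if detections.image_id and image.id and detections.image_id != image.id:
        raise ValidationError(
            f"detections are for image {detections.image_id!r} but image is {image.id!r}"
        )
    G = build_neighbor_graph(detections, cfg.radius_factor, cfg.min_confidence)
    G = filter_false_connections(G, image, cfg.support_quantile, cfg.min_support)
    F = remove_cycles(G)
    return graph_to_polylines(F)
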