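import numpy as np
import pytest

import vesselkit as vk


@pytest.fixture(scope="session")
def two_bar_scene():
    """Two bright horizontal bars with a dark gap, plus boxes along each bar.

    The classic false-connection construction: proximity suggests links across
    the gap, but the image supports only the intra-bar links.
    """
    img = np.zeros((120, 200))
    img[38:43, 10:190] = 1.0
    img[78:83, 10:190] = 1.0
    image = vk.Image2D(img, 1.0, "fluorescent", "bars")
    top = vk.boxes_from_polyline(vk.Polyline(((20, 40), (180, 40))), 32, 16).boxes
    bottom = vk.boxes_from_polyline(vk.Polyline(((20, 80), (180, 80))), 32, 16).boxes
    detections = vk.DetectionSet("bars", top + bottom)
    return image, detections


@pytest.fixture(scope="session")
def single_vessel_scene():
    """One unbranched synthetic vessel; ground truth known by construction."""
    params = vk.SceneParams(
        n_seeds=1, branch_prob=0.0, n_debris=0, n_out_of_plane=0, seed=21
    )
    return vk.make_scene(params)


def brute_force_mst_weight(G) -> float:
    """Exhaustive minimum over all spanning trees, per connected component.

    Only feasible for small graphs; the edge count is capped by the generator
    below so enumeration stays in the thousands of combinations.
    """
    import itertools

    import networkx as nx

    total = 0.0
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        n = sub.number_of_nodes()
        if n == 1:
            continue
        best = np.inf
        edges = list(sub.edges(data="weight"))
        for combo in itertools.combinations(edges, n - 1):
            T = nx.Graph()
            T.add_nodes_from(sub.nodes())
            T.add_weighted_edges_from(combo)
            if nx.is_connected(T):
                best = min(best, sum(w for *_, w in combo))
        total += best
    return total


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 8):
    """Random connected geometric graph with at most 5 non-tree edges."""
    import networkx as nx

    n = int(rng.integers(3, max_nodes + 1))
    pos = rng.uniform(0, 100, size=(n, 2))
    G = nx.Graph()
    for i in range(n):
        G.add_node(i, pos=tuple(pos[i]))
    order = rng.permutation(n)
    for a, b in zip(order, order[1:]):
        G.add_edge(int(a), int(b), weight=float(np.hypot(*(pos[a] - pos[b]))))
    candidates = [(i, j) for i in range(n) for j in range(i + 1, n) if not G.has_edge(i, j)]
    rng.shuffle(candidates)
    for i, j in candidates[:5]:
        G.add_edge(i, j, weight=float(np.hypot(*(pos[i] - pos[j]))))
    return G


def random_forest_graph(rng: np.random.Generator, n_trees: int = 3, max_nodes: int = 8):
    """Random geometric forest with edge weights equal to node distances."""
    import networkx as nx

    F = nx.Graph()
    offset = 0
    for _ in range(n_trees):
        n = int(rng.integers(2, max_nodes + 1))
        tree = nx.random_labeled_tree(n, seed=int(rng.integers(0, 2**31)))
        pos = rng.uniform(0, 500, size=(n, 2))
        for i in range(n):
            F.add_node(offset + i, pos=(float(pos[i, 0]), float(pos[i, 1])))
        for u, v in tree.edges():
            w = float(np.hypot(*(pos[u] - pos[v])))
            F.add_edge(offset + u, offset + v, weight=max(w, 1e-6))
        offset += n
    return F
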