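"""Visibility graphs, connected components, MST skeletons and attributes,
each checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from cavigraph.graphs import (
    CavityGraph,
    build_components,
    build_mst,
    compute_attributes,
    segment_visible,
    to_networkx,
)
from cavigraph.sampling import CavitySample
from cavigraph.surface import SurfaceField, SurfaceModel
from conftest import make_frame, make_parallel_plates

SAS = SurfaceModel("sas", 1.4)


def _sample(p):
    p = np.asarray(p, float)
    return CavitySample(p, 0, p, p, 0.5)


def _open_field():
    """A field whose molecule is far away: all test points have f < 0, so
    visibility reduces to pure geometry."""
    return SurfaceField(SAS, make_frame([(500.0, 500.0, 500.0)]))


# ------------------------------------------------------------- visibility

def test_segment_visible_degenerate_and_blocked(lone_atom_field):
    p = np.array([5.0, 0, 0])
    assert segment_visible(p, p, lone_atom_field)
    # through the atom: blocked
    assert not segment_visible([5.0, 0, 0], [-5.0, 0, 0], lone_atom_field)
    # chord well clear of the atom: visible
    assert segment_visible([5.0, 5.0, 0], [-5.0, 5.0, 0], lone_atom_field)


def test_segment_visible_agrees_with_fine_sampling_oracle():
    """Random pairs around the slit fixture: the production step delta
    agrees with a delta/10 oracle in >= 99% of pairs."""
    frame = make_parallel_plates()
    field = SurfaceField(SAS, frame)
    rng = np.random.default_rng(17)
    pts = rng.uniform([-10, -10, -2], [10, 10, 14], size=(160, 3))
    pts = pts[field.evaluate_many(pts) < 0]
    pairs = [
        (pts[i], pts[j])
        for i, j in itertools.combinations(range(min(len(pts), 30)), 2)
    ]
    agree = sum(
        segment_visible(p, q, field, delta=0.7)
        == segment_visible(p, q, field, delta=0.07)
        for p, q in pairs
    )
    assert agree / len(pairs) >= 0.99


# ------------------------------------------------------------- components

def test_two_visible_samples_form_one_component():
    field = _open_field()
    samples = [_sample([0, 0, 0]), _sample([1.0, 0, 0])]
    graphs = build_components(samples, field, n_min=2)
    assert len(graphs) == 1 and graphs[0].node_count == 2


def test_component_partition_matches_transitive_closure_oracle():
    """Union-find components equal the O(n^3) boolean transitive closure of
    the visibility relation for n <= 50 random samples."""
    field = _open_field()
    rng = np.random.default_rng(23)
    pts = rng.uniform(0, 25, size=(50, 3))
    d_vis = 4.0
    graphs = build_components(
        [_sample(p) for p in pts], field, d_vis=d_vis, n_min=1
    )

    n = len(pts)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            adj[i, j] = (i == j) or (
                np.linalg.norm(pts[i] - pts[j]) <= d_vis
            )
    closure = adj.copy()
    for k in range(n):  # Floyd-Warshall style boolean closure
        closure |= np.outer(closure[:, k], closure[k, :])

    def canon(partition):
        return sorted(tuple(sorted(c)) for c in partition)

    oracle = {}
    for i in range(n):
        oracle.setdefault(frozenset(np.nonzero(closure[i])[0]), set()).add(i)
    got = []
    for g in graphs:
        members = {
            int(np.nonzero(np.all(np.isclose(pts, node.position), axis=1))[0][0])
            for node in g.nodes
        }
        got.append(members)
    assert canon(got) == canon(oracle.values())


def test_small_components_are_discarded():
    field = _open_field()
    pts = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [40, 0, 0], [41, 0, 0]]
    graphs = build_components([_sample(p) for p in pts], field, d_vis=2.0, n_min=3)
    assert len(graphs) == 1 and graphs[0].node_count == 3


def test_slab_two_sided_pockets_are_separate_components():
    from cavigraph import fixtures as fx
    from cavigraph.pipeline import Config, detect_frame

    frame, gt = fx.make_slab_pocket(two_sided=True)
    graphs = detect_frame(frame, Config())
    assert len(graphs) == gt["n_cavities"] == 2
    for g in graphs:
        pos = g.positions()
        dists = [
            np.linalg.norm(pos - np.array(c), axis=1).max()
            for c in gt["pocket_centers"]
        ]
        # confined to exactly one pocket
        assert sum(d < gt["node_radius_bound"] for d in dists) == 1
        assert g.residues <= set(gt["lining_residues"])


# -------------------------------------------------------------------- MST

def test_mst_three_collinear_nodes():
    edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 2.0)]
    mst = build_mst(3, edges)
    assert sorted((u, v) for u, v, _ in mst) == [(0, 1), (1, 2)]
    assert sum(w for _, _, w in mst) == pytest.approx(2.0)


def test_mst_unit_square_weight_and_tie_break():
    pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    edges = [
        (i, j, float(np.linalg.norm(pts[i] - pts[j])))
        for i, j in itertools.combinations(range(4), 2)
    ]
    mst = build_mst(4, edges)
    assert sum(w for _, _, w in mst) == pytest.approx(3.0)
    # deterministic (length, min id, max id) tie-break: lexicographically
    # first three unit sides
    assert [(u, v) for u, v, _ in mst] == [(0, 1), (0, 3), (1, 2)]


def test_mst_weight_matches_exhaustive_enumeration():
    """n <= 7 complete graphs: Kruskal's weight equals the minimum over all
    spanning trees enumerated by brute force."""
    rng = np.random.default_rng(31)
    for n in (4, 5, 6, 7):
        pts = rng.uniform(0, 10, size=(n, 3))
        edges = [
            (i, j, float(np.linalg.norm(pts[i] - pts[j])))
            for i, j in itertools.combinations(range(n), 2)
        ]
        mst_weight = sum(w for _, _, w in build_mst(n, edges))

        best = np.inf
        for subset in itertools.combinations(edges, n - 1):
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            ok = True
            for u, v, _ in subset:
                ru, rv = find(u), find(v)
                if ru == rv:
                    ok = False
                    break
                parent[ru] = rv
            if ok:
                best = min(best, sum(w for _, _, w in subset))
        assert mst_weight == pytest.approx(best)


def test_mst_disconnected_input_raises():
    with pytest.raises(ValueError, match="not connected"):
        build_mst(4, [(0, 1, 1.0), (2, 3, 1.0)])


def test_mst_beats_random_spanning_trees_and_deleting_an_edge_splits():
    rng = np.random.default_rng(5)
    n = 9
    pts = rng.uniform(0, 6, size=(n, 3))
    edges = [
        (i, j, float(np.linalg.norm(pts[i] - pts[j])))
        for i, j in itertools.combinations(range(n), 2)
    ]
    mst = build_mst(n, edges)
    w_mst = sum(w for _, _, w in mst)
    for _ in range(100):  # random spanning trees via shuffled Kruskal
        shuffled = list(edges)
        rng.shuffle(shuffled)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        w = 0.0
        picked = 0
        for u, v, weight in shuffled:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
                w += weight
                picked += 1
        assert picked == n - 1
        assert w_mst <= w + 1e-12

    # removing any MST edge splits the tree into exactly two parts
    import networkx as nx

    for drop in range(len(mst)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(
            (u, v) for k, (u, v, _) in enumerate(mst) if k != drop
        )
        assert nx.number_connected_components(g) == 2


# ------------------------------------------------------------- attributes

def _graph_from_edges(n, edges):
    g = CavityGraph(0, 0, [_sample([float(i), 0, 0]) for i in range(n)],
                    [(u, v, float(w)) for u, v, w in edges])
    if n > 1:
        g.mst_edges = build_mst(n, g.edges)
    return g


def test_attributes_path_graph_closed_form():
    g = _graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
    avg_p, diameter, avg_degree = compute_attributes(g)
    assert avg_p == pytest.approx(4.0 / 3.0)
    assert diameter == pytest.approx(2.0)
    assert avg_degree == pytest.approx(4.0 / 3.0)


def test_attributes_singleton_all_zero():
    g = CavityGraph(0, 0, [_sample([0, 0, 0])], [])
    assert compute_attributes(g) == (0.0, 0.0, 0.0)


def test_attributes_match_floyd_warshall_oracle():
    """Random connected graphs (n <= 30): avgP and diameter equal the dense
    all-pairs shortest-path matrix from scipy."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import floyd_warshall

    rng = np.random.default_rng(41)
    for n in (5, 12, 30):
        edge_map = {(i, i + 1): float(rng.uniform(0.5, 2)) for i in range(n - 1)}
        for a, b in rng.integers(0, n, size=(2 * n, 2)):
            if a < b:
                edge_map.setdefault((int(a), int(b)), float(rng.uniform(0.5, 3)))
        edges = [(u, v, w) for (u, v), w in sorted(edge_map.items())]
        g = _graph_from_edges(n, edges)
        avg_p, diameter, avg_degree = compute_attributes(g)

        m = np.zeros((n, n))
        for u, v, w in edges:
            if m[u, v] == 0 or w < m[u, v]:
                m[u, v] = m[v, u] = w
        dist = floyd_warshall(csr_matrix(m), directed=False)
        iu = np.triu_indices(n, 1)
        assert avg_p == pytest.approx(dist[iu].mean(), abs=1e-9)
        assert diameter == pytest.approx(dist[iu].max(), abs=1e-9)
        assert avg_degree == pytest.approx(2 * len(edges) / n)


def test_to_networkx_carries_geometry_and_mst_flags():
    g = _graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 2.0)])
    nxg = to_networkx(g)
    assert nxg.number_of_nodes() == 3 and nxg.number_of_edges() == 3
    assert nxg.nodes[1]["x"] == pytest.approx(1.0)
    assert nxg.edges[0, 1]["mst"] and not nxg.edges[0, 2]["mst"]
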