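import numpy as np
import pytest

from modgain import BinaryGraph, ModulePartition, ROITimeSeries


def make_graph(n, edges, density=0.1, node_ids=None):
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(
        adjacency=adj, density=density,
        node_ids=node_ids or [f"n{i}" for i in range(n)],
    )


def make_partition(labels, group_of=None, node_ids=None):
    node_ids = node_ids or [f"n{i}" for i in range(len(labels))]
    return ModulePartition.from_labels(node_ids, labels, group_of)


def random_graph_and_partition(rng, max_nodes=8):
    """Random connected-ish graph with at least one edge plus a random partition."""
    while True:
        n = rng.integers(3, max_nodes + 1)
        adj = (rng.random((n, n)) < rng.uniform(0.2, 0.8)).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        if adj.sum() > 0:
            break
    g = BinaryGraph(adjacency=adj, density=0.5,
                    node_ids=[f"n{i}" for i in range(n)])
    labels = rng.integers(0, rng.integers(1, n + 1), size=n)
    # every module label present in partition must be non-empty by construction
    p = make_partition([f"m{k}" for k in labels], node_ids=g.node_ids)
    return g, p


def brute_force_modularity(g: BinaryGraph, p: ModulePartition):
    """Edge-by-edge count of e_ii and a_i straight from the definition."""
    edges = g.edge_list()
    L = len(edges)
    mods = p.modules
    e = {m: 0.0 for m in mods}
    ends = {m: 0.0 for m in mods}
    for a, b in edges:
        ma, mb = p.assignment[a], p.assignment[b]
        if ma == mb:
            e[ma] += 1.0
        ends[ma] += 1.0
        ends[mb] += 1.0
    Q = sum(e[m] / L - (ends[m] / (2 * L)) ** 2 for m in mods)
    return Q, {m: e[m] / L for m in mods}, {m: ends[m] / (2 * L) for m in mods}


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def two_triangles_bridge():
    """Two triangles {0,1,2} and {3,4,5} joined by the bridge 2-3."""
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    g = make_graph(6, edges)
    p = make_partition(["a", "a", "a", "b", "b", "b"])
    return g, p


def ts_from_array(data, subject_id="s1", node_ids=None):
    data = np.asarray(data, dtype=float)
    return ROITimeSeries(subject_id=subject_id, data=data,
                         node_ids=node_ids or [f"n{i}" for i in range(len(data))])
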