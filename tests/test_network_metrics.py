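import itertools

import numpy as np
import pytest

from modgain import (
    ConnectivityMatrix,
    aggregate_over_densities,
    modularity_fixed_partition,
    module_segregation,
    spectral_partition,
    subnetwork_modularity,
)

from conftest import (
    brute_force_modularity,
    make_graph,
    make_partition,
    random_graph_and_partition,
)


class TestFixedPartitionModularity:
    def test_two_triangles_with_bridge(self, two_triangles_bridge):
        g, p = two_triangles_bridge
        prof = modularity_fixed_partition(g, p)
        assert prof.per_module["a"].e_ii == pytest.approx(3 / 7)
        assert prof.per_module["a"].a_i == pytest.approx(1 / 2)
        assert prof.Q == pytest.approx(5 / 14, abs=1e-14)

    def test_two_isolated_modules(self):
        g = make_graph(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
        p = make_partition(["a"] * 3 + ["b"] * 3)
        assert modularity_fixed_partition(g, p).Q == pytest.approx(0.5)

    def test_single_module_zero(self):
        g = make_graph(4, [(0, 1), (2, 3), (1, 2)])
        p = make_partition(["a"] * 4)
        assert modularity_fixed_partition(g, p).Q == pytest.approx(0.0, abs=1e-15)

    def test_edgeless_graph_error(self):
        g = make_graph(3, [])
        with pytest.raises(ValueError, match="edgeless"):
            modularity_fixed_partition(g, make_partition(["a", "a", "b"]))

    def test_node_missing_from_partition_error(self):
        g = make_graph(3, [(0, 1)])
        p = make_partition(["a", "a"], node_ids=["n0", "n1"])
        with pytest.raises(KeyError, match="n2"):
            modularity_fixed_partition(g, p)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(100):
            g, p = random_graph_and_partition(rng)
            prof = modularity_fixed_partition(g, p)
            Q_ref, e_ref, a_ref = brute_force_modularity(g, p)
            assert prof.Q == pytest.approx(Q_ref, abs=1e-12)
            for m in p.modules:
                assert prof.per_module[m].e_ii == pytest.approx(e_ref[m], abs=1e-12)
                assert prof.per_module[m].a_i == pytest.approx(a_ref[m], abs=1e-12)

    def test_matches_networkx_modularity(self, rng):
        nx = pytest.importorskip("networkx")
        from networkx.algorithms.community import modularity as nx_modularity

        for _ in range(25):
            g, p = random_graph_and_partition(rng)
            G = nx.Graph(
                [(g.node_ids[i], g.node_ids[j])
                 for i, j in zip(*np.nonzero(np.triu(g.adjacency)))]
            )
            G.add_nodes_from(g.node_ids)
            comms = [
                {n for n, m in p.assignment.items() if m == mod}
                for mod in p.modules
            ]
            assert modularity_fixed_partition(g, p).Q == pytest.approx(
                nx_modularity(G, comms), abs=1e-12
            )

    def test_edge_end_fractions_sum_to_one(self, rng):
        for _ in range(30):
            g, p = random_graph_and_partition(rng)
            prof = modularity_fixed_partition(g, p)
            a = [st.a_i for st in prof.per_module.values()]
            e = [st.e_ii for st in prof.per_module.values()]
            assert sum(a) == pytest.approx(1.0, abs=1e-12)
            assert sum(e) <= 1.0 + 1e-12
            assert prof.Q == pytest.approx(
                sum(st.q_i for st in prof.per_module.values()), abs=1e-14
            )
            assert -1.0 <= prof.Q <= 1.0 - 1.0 / p.m + 1e-12


def all_partitions(n):
    """Every set partition of range(n) as a label vector (Bell-number many)."""
    if n == 0:
        yield []
        return
    for rest in all_partitions(n - 1):
        k = max(rest, default=-1) + 1
        for lab in range(k + 1):
            yield rest + [lab]


class TestSpectralPartition:
    def test_recovers_two_cliques(self):
        edges = list(itertools.combinations(range(5), 2))
        edges += [(i + 5, j + 5) for i, j in itertools.combinations(range(5), 2)]
        edges += [(4, 5)]
        g = make_graph(10, edges)
        part, Q = spectral_partition(g)
        labels = [part.assignment[n] for n in g.node_ids]
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        assert Q == pytest.approx(modularity_fixed_partition(g, part).Q)
        # and no other partition of these 10 nodes does better than the cliques
        clique_Q = modularity_fixed_partition(
            g, make_partition(["a"] * 5 + ["b"] * 5, node_ids=g.node_ids)
        ).Q
        assert Q == pytest.approx(clique_Q, abs=1e-12)

    def test_complete_graph_single_module(self):
        g = make_graph(6, list(itertools.combinations(range(6), 2)))
        part, Q = spectral_partition(g)
        assert part.m == 1
        assert Q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_error(self):
        with pytest.raises(ValueError):
            spectral_partition(make_graph(3, []))

    def test_deterministic(self, rng):
        g, _ = random_graph_and_partition(rng)
        p1, q1 = spectral_partition(g)
        p2, q2 = spectral_partition(g)
        assert p1.assignment == p2.assignment and q1 == q2

    def test_never_below_exhaustive_optimum_by_much(self, rng):
        """Spectral Q is a heuristic lower bound on, never above, the true max Q."""
        for _ in range(10):
            g, _ = random_graph_and_partition(rng, max_nodes=7)
            _, Q = spectral_partition(g)
            best = max(
                modularity_fixed_partition(
                    g, make_partition([f"m{k}" for k in labs], node_ids=g.node_ids)
                ).Q
                for labs in all_partitions(g.n_nodes)
            )
            assert Q <= best + 1e-12

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, k = 18, 3
            truth = np.repeat(np.arange(k), n // k)
            prob = np.where(truth[:, None] == truth[None, :], 0.9, 0.05)
            adj = np.triu((rng.random((n, n)) < prob), 1).astype(int)
            g = make_graph(n, list(zip(*np.nonzero(adj))))
            part, Q = spectral_partition(g)
            labels = [part.assignment[nid] for nid in g.node_ids]
            if adjusted_rand_score(truth, labels) == 1.0:
                hits += 1
            planted_Q = modularity_fixed_partition(
                g, make_partition([f"m{t}" for t in truth], node_ids=g.node_ids)
            ).Q
            assert Q >= planted_Q - 1e-9
        assert hits >= 19

    def test_fine_tuning_never_hurts(self, rng):
        for _ in range(20):
            g, _ = random_graph_and_partition(rng)
            _, q_plain = spectral_partition(g)
            _, q_kl = spectral_partition(g, fine_tune=True)
            assert q_kl >= q_plain - 1e-12


class TestSubnetworkModularity:
    def test_group_means(self, two_triangles_bridge):
        g, _ = two_triangles_bridge
        p = make_partition(
            ["a", "a", "a", "b", "b", "b"],
            group_of={"a": "sensory-motor", "b": "association"},
        )
        prof = modularity_fixed_partition(g, p)
        assert subnetwork_modularity(prof, p, "sensory-motor") == pytest.approx(
            prof.per_module["a"].q_i
        )

    def test_mean_of_three(self):
        g = make_graph(9, [(0, 1), (1, 2), (3, 4), (4, 5), (6, 7), (7, 8), (2, 3)])
        p = make_partition(
            ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            group_of={m: "association" for m in "abc"},
        )
        prof = modularity_fixed_partition(g, p)
        q = [prof.per_module[m].q_i for m in "abc"]
        assert subnetwork_modularity(prof, p, "association") == pytest.approx(
            np.mean(q)
        )

    def test_unknown_group_error(self, two_triangles_bridge):
        g, p = two_triangles_bridge
        prof = modularity_fixed_partition(g, p)
        with pytest.raises(ValueError, match="no modules"):
            subnetwork_modularity(prof, p, "cerebellar")


def block_cm(zw, zb, sizes=(3, 3)):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    z = np.where(labels[:, None] == labels[None, :], zw, zb).astype(float)
    np.fill_diagonal(z, np.nan)
    cm = ConnectivityMatrix(z=z, node_ids=[f"n{i}" for i in range(n)])
    p = make_partition([f"m{k}" for k in labels], node_ids=cm.node_ids)
    return cm, p


class TestModuleSegregation:
    @pytest.mark.parametrize(
        "zw,zb,expected", [(0.6, 0.0, 1.0), (0.5, 0.5, 0.0), (0.6, 0.3, 0.5)]
    )
    def test_closed_forms(self, zw, zb, expected):
        cm, p = block_cm(zw, zb)
        seg = module_segregation(cm, p)
        for m in p.modules:
            assert seg.per_module[m][2] == pytest.approx(expected, abs=1e-14)
        assert seg.whole_brain == pytest.approx(expected, abs=1e-14)

    def test_absolute_equals_all_on_nonnegative(self, rng):
        z = np.abs(rng.standard_normal((8, 8)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        cm = ConnectivityMatrix(z=z, node_ids=[f"n{i}" for i in range(8)])
        p = make_partition(["a"] * 4 + ["b"] * 4, node_ids=cm.node_ids)
        s_all = module_segregation(cm, p, "all")
        s_abs = module_segregation(cm, p, "absolute")
        assert s_all.per_module == s_abs.per_module

    def test_positive_only_drops_negatives(self):
        cm, p = block_cm(0.6, -0.2)
        seg = module_segregation(cm, p, variant="positive")
        # all between-module z negative -> Zb = 0 -> S = 1
        for m in p.modules:
            assert seg.per_module[m] == (pytest.approx(0.6), 0.0, pytest.approx(1.0))

    def test_group_means_follow_grouping(self):
        cm, _ = block_cm(0.6, 0.3, sizes=(3, 3, 3))
        p = make_partition(
            ["sm"] * 3 + ["as1"] * 3 + ["as2"] * 3,
            group_of={"sm": "sensory-motor", "as1": "association",
                      "as2": "association"},
            node_ids=cm.node_ids,
        )
        seg = module_segregation(cm, p)
        assert set(seg.group_means) == {"sensory-motor", "association"}
        assert seg.group_means["association"] == pytest.approx(
            np.mean([seg.per_module["as1"][2], seg.per_module["as2"][2]])
        )

    def test_zero_within_error(self):
        cm, p = block_cm(0.0, 0.2)
        with pytest.raises(ValueError, match="Zw = 0"):
            module_segregation(cm, p)

    def test_singleton_module_error(self):
        cm, _ = block_cm(0.5, 0.1, sizes=(5, 1))
        p = make_partition(["a"] * 5 + ["b"], node_ids=cm.node_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            module_segregation(cm, p)

    def test_raising_within_z_raises_segregation_and_Q(self, rng):
        from modgain import threshold_by_density, modularity_fixed_partition

        cm, p = block_cm(0.5, 0.2, sizes=(4, 4))
        cm2, _ = block_cm(0.6, 0.2, sizes=(4, 4))
        s1 = module_segregation(cm, p).whole_brain
        s2 = module_segregation(cm2, p).whole_brain
        assert s2 > s1


class TestAggregateOverDensities:
    def test_constant_function(self):
        vals = {d: 0.4 for d in (0.02, 0.06, 0.10)}
        assert aggregate_over_densities(vals, "mean") == pytest.approx(0.4)
        assert aggregate_over_densities(vals, "integrate") == pytest.approx(
            0.4 * 0.08
        )

    def test_two_point_trapezoid(self):
        vals = {0.02: 0.2, 0.04: 0.4}
        assert aggregate_over_densities(vals, "mean") == pytest.approx(0.3)
        assert aggregate_over_densities(vals, "integrate") == pytest.approx(0.006)

    def test_five_point_mean(self):
        vals = dict(zip((0.02, 0.04, 0.06, 0.08, 0.10), (1.0, 2.0, 3.0, 4.0, 5.0)))
        assert aggregate_over_densities(vals, "mean") == pytest.approx(3.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="no values"):
            aggregate_over_densities({}, "mean")
        with pytest.raises(ValueError, match="at least 2"):
            aggregate_over_densities({0.1: 1.0}, "integrate")
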