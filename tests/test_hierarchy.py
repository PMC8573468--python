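import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from netreg.hierarchy import (
    ModuleTree,
    ResolutionParams,
    build_module_tree,
    hamiltonian_cpm,
    lev_bisect,
    lev_split,
    level_energy_profile,
    modularity,
)
from netreg.synthetic_data import SyntheticNetworkSpec, generate_network

from oracles import (
    best_bipartition,
    cpm_oracle,
    modularity_oracle,
    random_graph,
    random_partition,
)


def membership(partition, nodes):
    lookup = {v: i for i, part in enumerate(partition) for v in part}
    return [lookup[v] for v in nodes]


class TestModularity:
    def test_single_community_is_zero(self, two_cliques_bridge):
        assert modularity(
            two_cliques_bridge, [list(two_cliques_bridge.nodes)]
        ) == pytest.approx(0.0)

    def test_two_disjoint_cliques_half(self):
        G = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        assert modularity(G, [[0, 1, 2], [3, 4, 5]]) == pytest.approx(0.5)

    def test_matches_pairwise_sum_oracle(self, rng):
        for _ in range(40):
            nodes, edges = random_graph(rng, int(rng.integers(4, 9)), 0.5)
            G = nx.Graph()
            G.add_nodes_from(nodes)
            G.add_edges_from(edges)
            parts = random_partition(rng, nodes, int(rng.integers(1, 4)))
            assert modularity(G, parts) == pytest.approx(
                modularity_oracle(nodes, edges, parts), abs=1e-9
            )

    def test_matches_networkx_reference(self, rng):
        for _ in range(10):
            G = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1 << 30)))
            parts = random_partition(rng, list(G.nodes), 3)
            expected = nx.algorithms.community.modularity(
                G, [set(p) for p in parts]
            )
            assert modularity(G, parts) == pytest.approx(expected, abs=1e-12)

    def test_missing_node_named_in_error(self, two_cliques_bridge):
        partition = [list(two_cliques_bridge.nodes)[:-1]]
        with pytest.raises(ValueError, match="g9"):
            modularity(two_cliques_bridge, partition)


class TestHamiltonianCPM:
    def test_triangle_closed_form(self):
        G = nx.complete_graph(3)
        assert hamiltonian_cpm(G, [[0, 1, 2]], gamma=0.5) == pytest.approx(-1.5)

    def test_singleton_partition_is_zero(self, two_cliques_bridge):
        singletons = [[v] for v in two_cliques_bridge.nodes]
        assert hamiltonian_cpm(two_cliques_bridge, singletons, 0.7) == pytest.approx(
            0.0
        )

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(40):
            nodes, edges = random_graph(rng, int(rng.integers(4, 10)), 0.4)
            G = nx.Graph()
            G.add_nodes_from(nodes)
            G.add_edges_from(edges)
            parts = random_partition(rng, nodes, int(rng.integers(1, 4)))
            gamma = float(rng.uniform(0.1, 1.0))
            assert hamiltonian_cpm(G, parts, gamma) == pytest.approx(
                cpm_oracle(nodes, edges, parts, gamma), abs=1e-9
            )

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            hamiltonian_cpm(nx.complete_graph(3), [[0, 1, 2]], gamma=0.0)


class TestLevSplit:
    def test_two_bridged_cliques_match_exhaustive_optimum(self, two_cliques_bridge):
        parts = lev_split(two_cliques_bridge)
        assert parts is not None and len(parts) == 2
        nodes = list(two_cliques_bridge.nodes)
        edges = list(two_cliques_bridge.edges)
        _, best = best_bipartition(nodes, edges)
        assert {frozenset(p) for p in parts} == {frozenset(p) for p in best}

    def test_complete_graph_indivisible(self):
        assert lev_split(nx.complete_graph(6)) is None
        assert lev_bisect(nx.complete_graph(6)) is None

    def test_split_never_lowers_modularity(self, rng):
        for _ in range(15):
            G = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(G):
                G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
            parts = lev_split(G)
            if parts is not None:
                assert modularity(G, parts) > 0.0  # unsplit graph scores exactly 0

    def test_disconnected_input_rejected(self):
        G = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        with pytest.raises(ValueError, match="connected"):
            lev_split(G)

    def test_agrees_with_igraph_reference_on_planted_blocks(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(42)
        labels = np.array([0] * 50 + [1] * 50)
        P = np.where(labels[:, None] == labels[None, :], 0.3, 0.02)
        A = np.triu(rng.random((100, 100)) < P, 1)
        A = (A | A.T).astype(float)
        G = nx.from_numpy_array(A)
        mine = lev_split(G)
        ref = igraph.Graph.Adjacency(A.tolist(), mode="undirected")
        ref_member = ref.community_leading_eigenvector().membership
        ari = adjusted_rand_score(membership(mine, list(G.nodes)), ref_member)
        assert ari > 0.95


class TestModuleTree:
    def test_two_disjoint_cliques_split_once(self):
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        tree = build_module_tree(G)
        assert tree.max_depth == 1
        leaves = [n for n in tree.nodes() if n.is_leaf]
        assert sorted(len(l.members) for l in leaves) == [4, 4]

    def test_complete_graph_root_is_leaf(self):
        tree = build_module_tree(nx.complete_graph(6))
        assert tree.max_depth == 0 and tree.root.is_leaf

    def test_partitions_proper_at_every_level(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=64, levels=2, branching=2,
            p_within_leaf=0.6, p_between=(0.01, 0.08), seed=3,
        )
        G, _ = generate_network(spec)
        tree = build_module_tree(G)
        all_nodes = set(G.nodes)
        for level in range(tree.max_depth + 1):
            parts = tree.level_partition(level)
            flat = [v for p in parts for v in p]
            assert len(flat) == len(set(flat)) == len(all_nodes)
            assert set(flat) == all_nodes

    def test_recovers_planted_two_level_hierarchy(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=128, levels=2, branching=2,
            p_within_leaf=0.5, p_between=(0.005, 0.05), seed=0,
        )
        G, truth = generate_network(spec)
        tree = build_module_tree(G)
        nodes = sorted(G.nodes)
        for level, expected_count in ((1, 2), (2, 4)):
            parts = tree.level_partition(level)
            assert len(parts) == expected_count
            planted = [truth.block_labels[level][v] for v in nodes]
            assert adjusted_rand_score(planted, membership(parts, nodes)) >= 0.9

    def test_min_module_size_caps_splitting(self):
        G = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        tree = build_module_tree(G, ResolutionParams(min_module_size=6))
        assert tree.max_depth == 0

    def test_girvan_newman_alternative_on_bridged_cliques(self, two_cliques_bridge):
        tree = build_module_tree(two_cliques_bridge, method="girvan_newman")
        parts = tree.level_partition(1)
        assert {frozenset(p) for p in parts} == {
            frozenset(f"g{i}" for i in range(5)),
            frozenset(f"g{i}" for i in range(5, 10)),
        }


class TestLevelEnergyProfile:
    def test_unsplittable_graph_has_single_zero_level(self):
        G = nx.complete_graph(5)
        tree = build_module_tree(G)
        profile = level_energy_profile(tree, G)
        assert len(profile) == 1
        assert profile.loc[0, "q_level"] == pytest.approx(0.0)

    def test_root_energy_matches_closed_form(self, two_cliques_bridge):
        G = two_cliques_bridge
        tree = build_module_tree(G)
        profile = level_energy_profile(tree, G).set_index("level")
        n, m = G.number_of_nodes(), G.number_of_edges()
        gamma = tree.params.gamma
        assert profile.loc[0, "he_level"] == pytest.approx(
            -(m - gamma * n * (n - 1) / 2)
        )

    def test_energy_and_split_quality_decline_on_nested_blocks(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=128, levels=2, branching=2,
            p_within_leaf=0.5, p_between=(0.005, 0.05), seed=1,
        )
        G, _ = generate_network(spec)
        params = ResolutionParams(gamma=0.5, max_depth=3)
        tree = build_module_tree(G, params)
        profile = level_energy_profile(tree, G, params)
        he = profile["he_level"].to_numpy()
        assert (np.diff(he) < 0).all()
        split_q = profile["mean_q_of_split"].dropna().to_numpy()
        assert (np.diff(split_q) < 0).all()
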