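import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netreg.synthetic_data import (
    NetworkTruth,
    SyntheticExpressionSpec,
    SyntheticNetworkSpec,
    generate_expression,
    generate_network,
    write_expression_tsv,
    write_labels_tsv,
    write_network_tsv,
)
from netreg.diff_expression import read_expression


class TestExpressionGenerator:
    def test_zero_noise_planted_effect_is_exact(self):
        spec = SyntheticExpressionSpec(
            n_genes=10, n_up=2, n_down=1, effect_log2fc=2.0, noise_sd=0.0, seed=3
        )
        matrix, truth = generate_expression(spec)
        case = matrix.values[matrix.samples_in("case")].mean(axis=1)
        ctrl = matrix.values[matrix.samples_in("control")].mean(axis=1)
        diff = case - ctrl
        up = truth.index[truth == "up"]
        down = truth.index[truth == "down"]
        null = truth.index[truth == "null"]
        assert np.allclose(diff[up], 2.0)
        assert np.allclose(diff[down], -2.0)
        assert np.allclose(diff[null], 0.0)

    def test_no_planted_genes_means_identical_groups(self):
        spec = SyntheticExpressionSpec(n_genes=6, noise_sd=0.0, seed=1)
        matrix, truth = generate_expression(spec)
        assert (truth == "null").all()
        values = matrix.values.to_numpy()
        assert np.allclose(values, values[:, :1])  # each gene constant across samples

    def test_same_seed_bit_identical(self):
        spec = SyntheticExpressionSpec(n_genes=50, n_up=5, n_down=5, seed=7)
        m1, t1 = generate_expression(spec)
        m2, t2 = generate_expression(spec)
        assert m1.values.equals(m2.values)
        assert t1.equals(t2)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_genes": 0}, "n_genes"),
            ({"n_genes": 5, "n_up": 4, "n_down": 3}, "n_up + n_down"),
            ({"n_genes": 5, "effect_log2fc": -1.0}, "effect_log2fc"),
            ({"n_genes": 5, "noise_sd": -0.1}, "noise_sd"),
            ({"n_genes": 5, "n_per_group": 0}, "n_per_group"),
        ],
    )
    def test_invalid_spec_names_offending_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field.split()[0]):
            generate_expression(SyntheticExpressionSpec(**kwargs))

    def test_tsv_round_trip(self, tmp_path):
        matrix, _ = generate_expression(
            SyntheticExpressionSpec(n_genes=8, n_up=1, seed=2)
        )
        write_expression_tsv(matrix, tmp_path / "m.tsv")
        write_labels_tsv(matrix, tmp_path / "l.tsv")
        back = read_expression(tmp_path / "m.tsv", tmp_path / "l.tsv")
        assert np.allclose(back.values.to_numpy(), matrix.values.to_numpy())
        assert list(back.groups) == list(matrix.groups)


class TestNetworkGenerator:
    def test_single_level_extreme_probabilities_give_two_cliques(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=8, levels=1, branching=2,
            p_within_leaf=1.0, p_between=0.0, seed=0,
        )
        G, truth = generate_network(spec)
        comps = sorted(nx.connected_components(G), key=len)
        assert [len(c) for c in comps] == [4, 4]
        for comp in comps:
            sub = G.subgraph(comp)
            assert sub.number_of_edges() == 6  # K4
        # components coincide with the planted top-level blocks
        blocks = truth.block_labels[1]
        for comp in comps:
            assert len({blocks[v] for v in comp}) == 1

    def test_graph_is_simple_and_deterministic(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=64, levels=2, branching=2,
            p_within_leaf=0.6, p_between=(0.01, 0.08),
            n_planted_hubs=2, n_decoy_hubs=1, seed=11,
        )
        G1, _ = generate_network(spec)
        G2, _ = generate_network(spec)
        assert set(G1.edges) == set(G2.edges)
        assert not any(u == v for u, v in G1.edges)

    def test_preferential_attachment_has_heavy_tail(self):
        spec = SyntheticNetworkSpec(
            kind="preferential_attachment", n_nodes=5000, m_attach=2, seed=0
        )
        G, _ = generate_network(spec)
        degrees = np.array([d for _, d in G.degree()])
        assert degrees.max() > 10 * np.median(degrees)

    def test_planted_hubs_take_top_degrees(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=128, levels=2, branching=2,
            p_within_leaf=0.5, p_between=(0.005, 0.05),
            n_planted_hubs=2, seed=5,
        )
        G, truth = generate_network(spec)
        top2 = sorted(dict(G.degree()), key=lambda v: -G.degree(v))[:2]
        assert set(top2) == set(truth.hubs)

    def test_flat_between_structure_rejected(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=16, levels=1, branching=2,
            p_within_leaf=0.1, p_between=0.1,
        )
        with pytest.raises(ValueError, match="p_within_leaf"):
            generate_network(spec)

    def test_hierarchical_cliques_deterministic_size(self):
        spec = SyntheticNetworkSpec(
            kind="hierarchical_cliques", n_nodes=125, levels=3, branching=5
        )
        G, _ = generate_network(spec)
        assert G.number_of_nodes() == 125
        with pytest.raises(ValueError, match="branching"):
            generate_network(
                SyntheticNetworkSpec(
                    kind="hierarchical_cliques", n_nodes=100, levels=3, branching=5
                )
            )

    def test_decoys_are_pendant_star_hubs(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=64, levels=1, branching=2,
            p_within_leaf=0.3, p_between=0.01,
            n_decoy_hubs=2, decoy_pendant=20, decoy_attach=3, seed=2,
        )
        G, truth = generate_network(spec)
        for decoy in truth.decoys:
            assert G.degree(decoy) == 23
            pendants = [v for v in G[decoy] if v.startswith(decoy + "_P")]
            assert len(pendants) == 20
            assert all(G.degree(p) == 1 for p in pendants)

    def test_network_tsv_writer_format(self, tmp_path):
        G = nx.Graph()
        G.add_edge("A", "B", score=0.9)
        write_network_tsv(G, tmp_path / "net.tsv")
        lines = (tmp_path / "net.tsv").read_text().splitlines()
        assert lines[0] == "gene1\tgene2\tscore"
        assert lines[1] == "A\tB\t0.9"
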