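import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netreg.hierarchy import ResolutionParams, build_module_tree
from netreg.key_regulators import (
    annotate_tf,
    call_hubs,
    call_key_regulators,
    read_tf_table,
    report_to_frame,
    trace_gene,
)
from netreg.synthetic_data import SyntheticNetworkSpec, generate_network
from netreg.topology import centralities


class TestCallHubs:
    def test_star_centre_is_the_hub(self):
        cents = centralities(nx.star_graph(6))
        assert call_hubs(cents, 1) == [0]

    def test_degree_ties_break_by_betweenness_then_symbol(self):
        G = nx.cycle_graph(6)  # all degree 2, all betweenness equal
        G = nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})
        assert call_hubs(centralities(G), 2) == ["n0", "n1"]

    def test_too_many_hubs_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            call_hubs(centralities(nx.path_graph(3)), 4)

    def test_planted_hubs_recovered(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=128, levels=2, branching=2,
            p_within_leaf=0.5, p_between=(0.005, 0.05),
            n_planted_hubs=2, seed=8,
        )
        G, truth = generate_network(spec)
        assert set(call_hubs(centralities(G), 2)) == set(truth.hubs)


class TestTraceGene:
    def test_every_gene_starts_at_the_root(self, two_cliques_bridge):
        tree = build_module_tree(two_cliques_bridge)
        for gene in two_cliques_bridge.nodes:
            assert trace_gene(tree, gene)[0] == "0"

    def test_leaf_level_recorded_by_path_length(self):
        # clique pair: every gene's module chain ends at level 1
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        tree = build_module_tree(G)
        for gene in G.nodes:
            path = trace_gene(tree, gene)
            assert len(path) == 2 and path[1].startswith("0.")

    def test_unknown_gene_rejected(self, two_cliques_bridge):
        tree = build_module_tree(two_cliques_bridge)
        with pytest.raises(KeyError, match="nope"):
            trace_gene(tree, "nope")


class TestCallKeyRegulators:
    def test_deep_hubs_called_decoys_rejected(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=256, levels=2, branching=2,
            p_within_leaf=0.5, p_between=(0.005, 0.05),
            n_planted_hubs=3, n_decoy_hubs=3, decoy_pendant=64, seed=0,
        )
        G, truth = generate_network(spec)
        tree = build_module_tree(G, ResolutionParams(max_depth=5))
        report = call_key_regulators(tree, centralities(G), n_hubs=6)
        fundamental = {r.gene for r in report if r.present_at_all_levels}
        assert fundamental == set(truth.hubs)

    def test_depth_zero_tree_flags_everything_with_warning(self, caplog):
        G = nx.complete_graph(5)
        tree = build_module_tree(G)
        with caplog.at_level("WARNING"):
            report = call_key_regulators(tree, centralities(G), n_hubs=3)
        assert all(r.present_at_all_levels for r in report)
        assert any("depth 0" in r.message for r in caplog.records)

    def test_hub_absent_from_deg_table_gets_unknown_direction(
        self, two_cliques_bridge
    ):
        tree = build_module_tree(two_cliques_bridge)
        degs = pd.DataFrame(
            {"gene": ["g0"], "log2fc": [2.0], "p_value": [0.01],
             "adj_p": [0.01], "direction": ["up"]}
        )
        report = call_key_regulators(
            tree, centralities(two_cliques_bridge), degs, n_hubs=3
        )
        directions = {r.gene: r.direction for r in report}
        assert directions["g0"] == "up"
        assert all(d == "unknown" for g, d in directions.items() if g != "g0")

    def test_key_regulators_subset_of_hubs_subset_of_nodes(self):
        spec = SyntheticNetworkSpec(
            kind="nested_blocks", n_nodes=64, levels=2, branching=2,
            p_within_leaf=0.6, p_between=(0.01, 0.08),
            n_planted_hubs=1, seed=4,
        )
        G, _ = generate_network(spec)
        tree = build_module_tree(G)
        cents = centralities(G)
        report = call_key_regulators(tree, cents, n_hubs=5)
        hubs = {r.gene for r in report}
        fkr = {r.gene for r in report if r.present_at_all_levels}
        assert fkr <= hubs <= set(G.nodes)
        frame = report_to_frame(report)
        assert list(frame["degree"]) == sorted(frame["degree"], reverse=True)


class TestTFAnnotation:
    def make_record(self, gene):
        from netreg.key_regulators import KeyRegulatorRecord

        return KeyRegulatorRecord(
            gene=gene, degree=10, is_hub=True, deepest_level=2,
            present_at_all_levels=True, direction="down",
        )

    def test_known_regulator_target_relation_attached(self, tf_fixture_table):
        table = read_tf_table(tf_fixture_table)
        report = annotate_tf([self.make_record("POSTN")], table)
        assert ("CDX1", "target", "activation") in report[0].tf_roles

    def test_empty_table_leaves_roles_empty(self):
        report = annotate_tf(
            [self.make_record("POSTN")],
            pd.DataFrame(columns=["tf", "target", "mode"]),
        )
        assert report[0].tf_roles == []

    def test_gene_on_both_sides_gets_both_roles(self, tf_fixture_table):
        table = read_tf_table(tf_fixture_table)
        report = annotate_tf([self.make_record("CDX1")], table)
        roles = set(report[0].tf_roles)
        assert ("POSTN", "regulator", "activation") in roles
        assert ("YY1", "target", "unknown") in roles  # unknown-mapped mode

    def test_join_row_count_matches_table(self, tf_fixture_table):
        table = read_tf_table(tf_fixture_table)
        genes = sorted(set(table["tf"]) | set(table["target"]))
        report = annotate_tf([self.make_record(g) for g in genes], table)
        total_roles = sum(len(r.tf_roles) for r in report)
        assert total_roles == 2 * len(table)  # each row seen from both ends

    def test_malformed_table_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("tf\ttarget\tmode\nA\tB\tactivation\nC\n")
        with pytest.raises(ValueError, match="line 3"):
            read_tf_table(path)
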