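#!/usr/bin/env python
"""Simulate the benchmark inputs: expression matrix + planted networks.

Generates (i) a two-group log2 expression matrix with planted up/down
fold changes, (ii) a nested-block interaction network with planted deep
hubs and pendant-star decoys, and (iii) the scale-free / hierarchical
reference graphs, then writes everything as TSV/JSON under results/data/.
"""

import json
from pathlib import Path

from netreg.synthetic_data import (
    SyntheticExpressionSpec,
    SyntheticNetworkSpec,
    generate_expression,
    generate_network,
    write_expression_tsv,
    write_labels_tsv,
    write_network_tsv,
    write_truth_json,
)

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    expr_spec = SyntheticExpressionSpec(
        n_genes=2000, n_up=50, n_down=50, n_per_group=10,
        effect_log2fc=2.0, noise_sd=0.25, seed=SEED,
    )
    matrix, truth = generate_expression(expr_spec)
    write_expression_tsv(matrix, OUT / "expression.tsv")
    write_labels_tsv(matrix, OUT / "labels.tsv")
    write_truth_json(truth, OUT / "expression_truth.json")
    print(f"expression: {expr_spec.n_genes} genes x {2 * expr_spec.n_per_group} "
          f"samples, {expr_spec.n_up} up / {expr_spec.n_down} down planted "
          f"at |log2FC| = {expr_spec.effect_log2fc}, noise sd {expr_spec.noise_sd}")

    net_spec = SyntheticNetworkSpec(
        kind="nested_blocks", n_nodes=256, levels=2, branching=2,
        p_within_leaf=0.5, p_between=(0.005, 0.05),
        n_planted_hubs=4, n_decoy_hubs=4, decoy_pendant=64, seed=SEED,
    )
    G, net_truth = generate_network(net_spec)
    write_network_tsv(G, OUT / "network.tsv")
    write_truth_json(net_truth, OUT / "network_truth.json")
    print(f"nested network: {G.number_of_nodes()} nodes, "
          f"{G.number_of_edges()} edges, deep hubs {net_truth.hubs}, "
          f"decoys {net_truth.decoys}")

    pa, _ = generate_network(SyntheticNetworkSpec(
        kind="preferential_attachment", n_nodes=5000, m_attach=2, seed=SEED,
    ))
    write_network_tsv(pa, OUT / "scale_free.tsv")
    rb, _ = generate_network(SyntheticNetworkSpec(
        kind="hierarchical_cliques", n_nodes=125, levels=3, branching=5,
    ))
    write_network_tsv(rb, OUT / "hierarchical_cliques.tsv")
    print(f"reference graphs: preferential attachment ({pa.number_of_nodes()} "
          f"nodes), hierarchical cliques ({rb.number_of_nodes()} nodes)")

    (OUT / "simulation_params.json").write_text(json.dumps(
        {"seed": SEED, "expression": expr_spec.__dict__,
         "network": {k: v if not isinstance(v, tuple) else list(v)
                     for k, v in net_spec.__dict__.items()}},
        indent=1,
    ))


if __name__ == "__main__":
    main()
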