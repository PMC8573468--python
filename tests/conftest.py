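import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def two_cliques_bridge():
    """Two 5-cliques joined by a single edge — textbook two-community graph."""
    G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    G.add_edge(0, 5)
    return nx.relabel_nodes(G, {i: f"g{i}" for i in G.nodes})


@pytest.fixture()
def tf_fixture_table(tmp_path):
    """Small TF-target table covering known regulator/target relations."""
    rows = [
        ("CDX1", "POSTN", "activation"),
        ("TWIST2", "POSTN", "activation"),
        ("YY1", "POSTN", "unknown"),
        ("TCF4", "WNT4", "repression"),
        ("EGR1", "WNT4", "repression"),
        ("RUNX3", "WNT4", "repression"),
        ("GATA6", "CAV1", "repression"),
        ("SREBF1", "CAV1", "activation"),
        ("TP53", "CAV1", "unknown"),
        ("SP1", "CAV1", "unknown"),
        ("TFDP1", "CAV1", "unknown"),
        ("PPARG", "CAV1", "repression"),
        ("SNIP1", "CCND1", "activation"),
        ("SNIP1", "MYC", "activation"),
        ("EBF1", "ATF5", "activation"),
        ("MEIS2", "CRBN", "repression"),
        ("YY1", "CDX1", "oddmode"),
    ]
    path = tmp_path / "tf_table.tsv"
    with open(path, "w") as fh:
        fh.write("tf\ttarget\tmode\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path
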