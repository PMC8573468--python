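#!/usr/bin/env python
"""Build the cleaned gene interaction network from the simulated edge list.

Reads the STRING-style edge list, applies the confidence threshold and the
cleaning rules (no self-loops, duplicates collapsed to the max score),
reduces to the largest connected component, and writes the cleaned network
plus a summary.
"""

import json
from pathlib import Path

from netreg.network_build import largest_component, network_summary, read_edge_list
from netreg.synthetic_data import write_network_tsv

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    net = read_edge_list(DATA / "network.tsv", score_threshold=0.4)
    print(f"raw network: {network_summary(net)}")
    net = largest_component(net)
    summary = network_summary(net)
    print(f"largest component: {summary}")
    write_network_tsv(net, OUT / "network_clean.tsv")
    (OUT / "network_summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
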