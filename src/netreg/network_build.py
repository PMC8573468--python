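"""Build simple undirected gene networks from confidence-scored edge lists.

Consumes STRING-style exports (three columns: gene1, gene2, combined score);
integer scores on the 0-1000 convention are rescaled to [0, 1]. Cleaning
rules: drop self-loops, collapse duplicate pairs in either orientation
keeping the maximum score, and keep an edge only when its score reaches the
confidence threshold (default 0.4, STRING's documented "medium confidence").
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "network_from_edges",
    "read_edge_list",
    "graph_union",
    "largest_component",
    "subset_to_genes",
    "network_summary",
]


def network_from_edges(
    rows: Iterable[Tuple[str, str, float]], score_threshold: float = 0.0
) -> nx.Graph:
    """Clean a (gene1, gene2, score) row stream into a simple scored graph."""
    G = nx.Graph()
    for u, v, score in rows:
        if u == v:
            continue
        if score < score_threshold:
            continue
        if G.has_edge(u, v):
            G[u][v]["score"] = max(G[u][v]["score"], score)
        else:
            G.add_edge(u, v, score=score)
    return G


def read_edge_list(
    path: Union[str, Path], score_threshold: float = 0.4
) -> nx.Graph:
    """Read a STRING-style edge-list TSV into a cleaned gene network.

    Tab- or space-delimited; a header line is tolerated (detected by a
    non-numeric third field on the first line). Scores above 1 are assumed
    to be on STRING's 0-1000 integer scale and divided by 1000. Malformed
    rows raise with their line number; an empty post-filter network is
    returned with a warning.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    rows: List[Tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 columns, got {len(fields)}"
                )
            try:
                score = float(fields[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: score {fields[2]!r} is not numeric"
                ) from None
            if score > 1.0:
                score /= 1000.0
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{path}: line {lineno}: score {fields[2]!r} outside [0, 1] "
                    "after rescaling"
                )
            rows.append((fields[0], fields[1], score))
    G = network_from_edges(rows, score_threshold=score_threshold)
    if G.number_of_edges() == 0:
        logger.warning(
            "%s: no edges at score threshold %.3f", path, score_threshold
        )
    return G


def graph_union(networks: Sequence[nx.Graph]) -> nx.Graph:
    """Union of node and edge sets; duplicate edges keep the max score."""
    if not networks:
        raise ValueError("graph_union needs at least one network")
    out = nx.Graph()
    for G in networks:
        out.add_nodes_from(G.nodes)
        for u, v, data in G.edges(data=True):
            if u == v:
                continue
            score = data.get("score", 1.0)
            if out.has_edge(u, v):
                out[u][v]["score"] = max(out[u][v].get("score", 1.0), score)
            else:
                out.add_edge(u, v, score=score)
    return out


def largest_component(G: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected node set.

    Size ties go to the component containing the lexicographically smallest
    member, so the choice is deterministic.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("largest_component of an empty network")
    comps = sorted(
        nx.connected_components(G), key=lambda c: (-len(c), min(str(v) for v in c))
    )
    return G.subgraph(comps[0]).copy()


def subset_to_genes(G: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Induced subgraph on a gene list (e.g. the up- or down-regulated set)."""
    keep = set(genes) & set(G.nodes)
    return G.subgraph(keep).copy()


def network_summary(G: nx.Graph) -> dict:
    return {
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
        "mean_clustering": (
            float(nx.average_clustering(G)) if G.number_of_nodes() else 0.0
        ),
        "n_components": nx.number_connected_components(G) if G.number_of_nodes() else 0,
    }
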