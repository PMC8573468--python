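"""Synthetic expression matrices and gene networks with planted ground truth.

Every downstream stage of the pipeline (differential expression, network
topology, module hierarchies, key-regulator tracing) is exercised against
generators whose truth is known by construction: planted up/down fold
changes on a log2 expression scale, nested community structure, heavy-tailed
degree sequences, and "deep hub" genes wired into every block at every
nesting level so that they persist through the whole module hierarchy.

All generators are deterministic under a fixed integer seed: a single
``numpy.random.default_rng(seed)`` stream is created per call and no global
RNG state is touched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .diff_expression import ExpressionMatrix

__all__ = [
    "SyntheticExpressionSpec",
    "SyntheticNetworkSpec",
    "NetworkTruth",
    "generate_expression",
    "generate_network",
    "write_expression_tsv",
    "write_labels_tsv",
    "write_network_tsv",
    "write_truth_json",
]

NETWORK_KINDS = ("nested_blocks", "preferential_attachment", "hierarchical_cliques")


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Planted two-group expression experiment on the log2 scale.

    Expression values are generated directly as log2 intensities (the real
    pipelines this emulates quantile-normalize and log2-transform upstream,
    so normalization is skipped entirely). Each gene gets a baseline drawn
    once from N(baseline_mean, baseline_sd); planted genes have
    ``effect_log2fc`` added to (up) or subtracted from (down) the case-group
    columns; i.i.d. Gaussian noise of sd ``noise_sd`` is added everywhere.
    """

    n_genes: int
    n_up: int = 0
    n_down: int = 0
    n_per_group: int = 10
    effect_log2fc: float = 2.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        for name in ("n_up", "n_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError(
                f"n_up + n_down = {self.n_up + self.n_down} exceeds n_genes = {self.n_genes}"
            )
        if self.n_per_group < 1:
            raise ValueError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.effect_log2fc < 0:
            raise ValueError(f"effect_log2fc must be >= 0, got {self.effect_log2fc}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_expression(
    spec: SyntheticExpressionSpec,
) -> Tuple[ExpressionMatrix, pd.Series]:
    """Generate a genes x samples log2 matrix plus per-gene truth labels.

    Returns ``(matrix, truth)`` where truth maps each gene symbol to one of
    ``{"up", "down", "null"}``. The first ``n_up`` genes are planted up, the
    next ``n_down`` planted down; before noise, their case-group means differ
    from control by exactly +/- ``effect_log2fc`` log2 units.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    controls = [f"ctrl_{j + 1:02d}" for j in range(spec.n_per_group)]
    cases = [f"case_{j + 1:02d}" for j in range(spec.n_per_group)]
    samples = controls + cases

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    effect = np.zeros(spec.n_genes)
    effect[: spec.n_up] = spec.effect_log2fc
    effect[spec.n_up : spec.n_up + spec.n_down] = -spec.effect_log2fc

    values = np.tile(baseline[:, None], (1, 2 * spec.n_per_group))
    values[:, spec.n_per_group :] += effect[:, None]
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    frame = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(
        ["control"] * spec.n_per_group + ["case"] * spec.n_per_group,
        index=samples,
        name="group",
    )
    labels = ["up"] * spec.n_up + ["down"] * spec.n_down
    labels += ["null"] * (spec.n_genes - spec.n_up - spec.n_down)
    truth = pd.Series(labels, index=genes, name="direction")
    return ExpressionMatrix(values=frame, groups=groups), truth


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Planted-structure network generator settings.

    kind
        ``nested_blocks`` — balanced hierarchy of blocks, ``levels`` deep with
        ``branching`` children per block; edge probability depends on the
        deepest block two nodes share (``p_within_leaf`` inside a leaf block,
        ``p_between[l]`` when the deepest common block sits at level ``l``,
        level 0 being the root).
        ``preferential_attachment`` — Barabási–Albert graph with ``m_attach``
        edges per arriving node (heavy-tailed degrees, P(k) ~ k^-3).
        ``hierarchical_cliques`` — deterministic Ravasz–Barabási hierarchical
        modular graph: a ``branching``-clique replicated ``levels - 1`` times
        with peripheral nodes wired back to the central hub; its C(k) decays
        with k, the hierarchical-network signature.
    n_planted_hubs
        Deep hubs, one per distinct leaf block: each receives
        ``ceil(p_hub * |block|)`` extra edges into every block at every level,
        so the hub stays embedded in a dense module at each partition depth.
    n_decoy_hubs
        Shallow high-degree decoys: each is the centre of a pendant star of
        ``decoy_pendant`` leaves, tied to a single leaf block by
        ``decoy_attach`` edges. A star is indivisible under spectral
        modularity splitting, so a decoy's module chain terminates levels
        above the deep hubs' chains despite its comparable degree.
    """

    kind: str
    n_nodes: int
    levels: int = 1
    branching: int = 2
    p_within_leaf: float = 0.5
    p_between: Union[float, Sequence[float]] = 0.01
    n_planted_hubs: int = 0
    n_decoy_hubs: int = 0
    p_hub: float = 0.5
    decoy_pendant: Optional[int] = None
    decoy_attach: int = 6
    m_attach: int = 2
    seed: int = 0

    def betweens(self) -> List[float]:
        """Per-level between-block probabilities, index = level of deepest
        common block (0 = root ... levels-1)."""
        if np.isscalar(self.p_between):
            return [float(self.p_between)] * self.levels
        ps = [float(p) for p in self.p_between]
        if len(ps) != self.levels:
            raise ValueError(
                f"p_between must have one entry per level ({self.levels}), got {len(ps)}"
            )
        return ps

    def validate(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise ValueError(f"kind must be one of {NETWORK_KINDS}, got {self.kind!r}")
        if self.n_nodes <= 0:
            raise ValueError(f"n_nodes must be positive, got {self.n_nodes}")
        if self.kind == "nested_blocks":
            if self.levels < 1:
                raise ValueError(f"levels must be >= 1, got {self.levels}")
            if self.branching < 2:
                raise ValueError(f"branching must be >= 2, got {self.branching}")
            probs = [self.p_within_leaf] + self.betweens()
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"edge probability {p} outside [0, 1]")
            if self.p_within_leaf <= max(self.betweens()):
                raise ValueError(
                    "p_within_leaf must exceed every p_between "
                    "(no detectable block structure otherwise)"
                )
            n_leaf = self.branching**self.levels
            if self.n_nodes < n_leaf:
                raise ValueError(
                    f"n_nodes = {self.n_nodes} smaller than the {n_leaf} leaf blocks"
                )
            if self.n_planted_hubs > n_leaf:
                raise ValueError(
                    f"n_planted_hubs = {self.n_planted_hubs} exceeds the "
                    f"{n_leaf} leaf blocks (one deep hub per block)"
                )
            if not 0.0 < self.p_hub <= 1.0:
                raise ValueError(f"p_hub must be in (0, 1], got {self.p_hub}")
        elif self.kind == "preferential_attachment":
            if self.m_attach < 1 or self.m_attach >= self.n_nodes:
                raise ValueError(
                    f"m_attach must satisfy 1 <= m_attach < n_nodes, got {self.m_attach}"
                )
        elif self.kind == "hierarchical_cliques":
            if self.branching < 3:
                raise ValueError(
                    f"hierarchical_cliques needs branching >= 3, got {self.branching}"
                )
            if self.n_nodes != self.branching**self.levels:
                raise ValueError(
                    f"hierarchical_cliques requires n_nodes == branching ** levels "
                    f"({self.branching}**{self.levels} = {self.branching ** self.levels}), "
                    f"got {self.n_nodes}"
                )


@dataclass
class NetworkTruth:
    """Ground truth accompanying a generated network.

    block_labels maps level (1-based, down to ``levels``) to a dict
    node -> block id at that level; hub and decoy node lists are the planted
    high-degree genes. Pendant star leaves and decoy centres carry no block
    label (they sit outside the planted hierarchy).
    """

    block_labels: Dict[int, Dict[str, int]] = field(default_factory=dict)
    hubs: List[str] = field(default_factory=list)
    decoys: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "block_labels": {str(k): v for k, v in self.block_labels.items()},
                "hubs": self.hubs,
                "decoys": self.decoys,
            },
            indent=1,
        )


def _gene_name(i: int, width: int = 5) -> str:
    return f"G{i + 1:0{width}d}"


def _nested_blocks(spec: SyntheticNetworkSpec, rng: np.random.Generator):
    n = spec.n_nodes
    n_leaf = spec.branching**spec.levels
    leaf = np.minimum((np.arange(n) * n_leaf) // n, n_leaf - 1)
    # block index at level l (1-based): leaf id with the deepest levels peeled off
    blocks = {
        l: leaf // spec.branching ** (spec.levels - l) for l in range(1, spec.levels + 1)
    }
    betweens = spec.betweens()

    # depth of deepest common block for every pair, vectorized per level
    common = np.zeros((n, n), dtype=int)
    for l in range(1, spec.levels + 1):
        same = blocks[l][:, None] == blocks[l][None, :]
        common[same] = l
    prob = np.empty((n, n))
    for l in range(spec.levels):
        prob[common == l] = betweens[l]
    prob[common == spec.levels] = spec.p_within_leaf

    upper = np.triu(rng.random((n, n)) < prob, 1)
    edges = {(int(i), int(j)) for i, j in zip(*np.nonzero(upper))}

    # deep hubs: one per leaf block, extra edges into every block at every level
    hubs: List[int] = []
    for b in range(spec.n_planted_hubs):
        members = np.nonzero(leaf == b)[0]
        hubs.append(int(rng.choice(members)))
    for h in hubs:
        for l in range(1, spec.levels + 1):
            for blk in np.unique(blocks[l]):
                members = np.nonzero((blocks[l] == blk) & (np.arange(n) != h))[0]
                k = min(math.ceil(spec.p_hub * len(members)), len(members))
                for t in rng.choice(members, size=k, replace=False):
                    edges.add((min(h, int(t)), max(h, int(t))))

    names = {i: _gene_name(i) for i in range(n)}
    G = nx.Graph()
    G.add_nodes_from(names.values())
    G.add_edges_from((names[u], names[v]) for u, v in edges)

    truth = NetworkTruth(
        block_labels={
            l: {names[i]: int(blocks[l][i]) for i in range(n)}
            for l in range(1, spec.levels + 1)
        },
        hubs=[names[h] for h in hubs],
    )

    # shallow decoys: pendant stars tied to one leaf block each
    pendant = spec.decoy_pendant or max(1, math.ceil(n / 4))
    for d in range(spec.n_decoy_hubs):
        centre = f"D{d + 1:02d}"
        truth.decoys.append(centre)
        G.add_node(centre)
        for p in range(pendant):
            G.add_edge(centre, f"{centre}_P{p + 1:03d}")
        blk = d % n_leaf
        members = np.nonzero(leaf == blk)[0]
        k = min(spec.decoy_attach, len(members))
        for t in rng.choice(members, size=k, replace=False):
            G.add_edge(centre, names[int(t)])
    return G, truth


def _hierarchical_cliques(spec: SyntheticNetworkSpec) -> nx.Graph:
    """Deterministic Ravasz–Barabási hierarchical modular graph."""
    b = spec.branching
    G = nx.complete_graph(b)
    periphery = list(range(1, b))  # non-central nodes of the base clique
    for _ in range(spec.levels - 1):
        n0 = G.number_of_nodes()
        base_edges = list(G.edges())
        new_periphery = []
        for r in range(1, b):
            off = r * n0
            G.add_edges_from((u + off, v + off) for u, v in base_edges)
            new_periphery.extend(p + off for p in periphery)
        G.add_edges_from((p, 0) for p in new_periphery)
        periphery = new_periphery
    return G


def generate_network(spec: SyntheticNetworkSpec) -> Tuple[nx.Graph, NetworkTruth]:
    """Generate a simple undirected gene network plus its ground truth.

    Node names are gene-symbol-like strings; edges carry a unit ``score``
    attribute so the graph round-trips through the edge-list TSV format.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "nested_blocks":
        G, truth = _nested_blocks(spec, rng)
    elif spec.kind == "preferential_attachment":
        raw = nx.barabasi_albert_graph(spec.n_nodes, spec.m_attach, seed=int(spec.seed))
        G = nx.relabel_nodes(raw, {i: _gene_name(i) for i in raw.nodes})
        truth = NetworkTruth()
    else:  # hierarchical_cliques
        raw = _hierarchical_cliques(spec)
        G = nx.relabel_nodes(raw, {i: _gene_name(i) for i in raw.nodes})
        truth = NetworkTruth()

    nx.set_edge_attributes(G, 1.0, "score")
    assert not any(u == v for u, v in G.edges), "self-loop in generated network"
    return G, truth


# ---------------------------------------------------------------------------
# plain-text writers (TSV edge lists and matrices, JSON truth)

def write_expression_tsv(matrix: ExpressionMatrix, path: Union[str, Path]) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def write_labels_tsv(matrix: ExpressionMatrix, path: Union[str, Path]) -> None:
    matrix.groups.rename_axis("sample").to_frame().to_csv(path, sep="\t")


def write_network_tsv(G: nx.Graph, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tscore\n")
        for u, v, data in G.edges(data=True):
            fh.write(f"{u}\t{v}\t{data.get('score', 1.0):g}\n")


def write_truth_json(truth, path: Union[str, Path]) -> None:
    path = Path(path)
    if isinstance(truth, NetworkTruth):
        path.write_text(truth.to_json())
    elif isinstance(truth, pd.Series):
        path.write_text(json.dumps(truth.to_dict(), indent=1))
    else:
        path.write_text(json.dumps(truth, indent=1))
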