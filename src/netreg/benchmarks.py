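"""Planted-truth benchmark experiments for every pipeline stage.

Each function generates synthetic data under the package's reference study
conditions, runs the corresponding stage, and scores the result against the
planted ground truth. The same experiments back the recovery tests, the
analysis drivers, and the acceptance report, so the numbers they print are
always recomputed from scratch.

Reference conditions (see docs/methods.md for rationale):

* DEG calling — 2000 genes, 50 up + 50 down planted at |log2FC| = 2.0,
  noise sd 0.25, 10 samples per group.
* Flat community detection — two-block planted partition, n = 100,
  p_in = 0.3, p_out = 0.02.
* Hierarchy recovery — nested blocks, n = 128, 2 levels, branching 2,
  p = 0.5 / 0.05 / 0.005 by nesting depth.
* Energy profile — same nested networks; the module tree is capped at
  depth 3 (the planted two levels plus one refinement step) because the
  generator plants no structure below its leaf blocks.
* Key regulators — nested blocks with 4 planted deep hubs and 4 pendant-star
  decoys, n = 256, depth cap 5 (typical bottom-module size about twice the
  motif floor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .diff_expression import compute_deg_table, split_by_direction
from .hierarchy import ResolutionParams, build_module_tree, lev_split, level_energy_profile
from .key_regulators import call_key_regulators
from .synthetic_data import (
    SyntheticExpressionSpec,
    SyntheticNetworkSpec,
    generate_expression,
    generate_network,
)
from .topology import centralities, degree_distribution, fit_power_law, topology_profile

__all__ = [
    "deg_benchmark",
    "lev_sbm_benchmark",
    "hierarchy_recovery_benchmark",
    "energy_decline_benchmark",
    "key_regulator_benchmark",
    "scale_free_benchmark",
]


def _seeds(base_seed: int, n: int) -> List[int]:
    # spread sub-experiment seeds deterministically, keep below 2**31
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def deg_benchmark(n_seeds: int = 20, base_seed: int = 0) -> Dict[str, float]:
    """Sensitivity and false-discovery proportion of DEG calling.

    Per seed: 2000 genes with 50 up and 50 down planted at effect 2.0 under
    noise sd 0.25, 10 samples per group; cutoffs |log2FC| >= 1.5 and
    BH-adjusted p < 0.05.
    """
    sens, fdp = [], []
    for seed in _seeds(base_seed, n_seeds):
        spec = SyntheticExpressionSpec(
            n_genes=2000, n_up=50, n_down=50, n_per_group=10,
            effect_log2fc=2.0, noise_sd=0.25, seed=seed,
        )
        matrix, truth = generate_expression(spec)
        degs = compute_deg_table(matrix)
        up, down = split_by_direction(degs)
        called = {(g, "up") for g in up} | {(g, "down") for g in down}
        planted = {
            (g, d) for g, d in truth.items() if d != "null"
        }
        tp = len(called & planted)
        sens.append(tp / len(planted))
        fdp.append((len(called) - tp) / len(called) if called else 0.0)
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "n_seeds": n_seeds,
    }


def _two_block_network(seed: int, n: int = 100, p_in: float = 0.3,
                       p_out: float = 0.02):
    spec = SyntheticNetworkSpec(
        kind="nested_blocks", n_nodes=n, levels=1, branching=2,
        p_within_leaf=p_in, p_between=p_out, seed=seed,
    )
    return generate_network(spec)


def lev_sbm_benchmark(n_seeds: int = 50, base_seed: int = 0) -> Dict[str, float]:
    """Flat LEV recovery of a planted two-block partition.

    Scores the fraction of seeds with ARI >= 0.9 against the planted labels
    (n = 100, p_in = 0.3, p_out = 0.02); disconnected graphs contribute
    their largest component.
    """
    import networkx as nx

    hits, aris = 0, []
    for seed in _seeds(base_seed, n_seeds):
        G, truth = _two_block_network(seed)
        if not nx.is_connected(G):
            G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
        parts = lev_split(G) or [list(G.nodes)]
        lookup = {v: i for i, p in enumerate(parts) for v in p}
        nodes = sorted(G.nodes)
        ari = adjusted_rand_score(
            [truth.block_labels[1][v] for v in nodes], [lookup[v] for v in nodes]
        )
        aris.append(ari)
        hits += ari >= 0.9
    return {
        "success_rate": hits / n_seeds,
        "mean_ari": float(np.mean(aris)),
        "n_seeds": n_seeds,
    }


def _nested_spec(seed: int, **overrides) -> SyntheticNetworkSpec:
    kwargs = dict(
        kind="nested_blocks", n_nodes=128, levels=2, branching=2,
        p_within_leaf=0.5, p_between=(0.005, 0.05), seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticNetworkSpec(**kwargs)


def hierarchy_recovery_benchmark(
    n_seeds: int = 20, base_seed: int = 0
) -> Dict[str, float]:
    """Mean ARI of the module tree against both planted nesting levels."""
    ari_by_level = {1: [], 2: []}
    for seed in _seeds(base_seed, n_seeds):
        G, truth = generate_network(_nested_spec(seed))
        tree = build_module_tree(G)
        nodes = sorted(G.nodes)
        for level in (1, 2):
            parts = tree.level_partition(level)
            lookup = {v: i for i, p in enumerate(parts) for v in p}
            ari_by_level[level].append(
                adjusted_rand_score(
                    [truth.block_labels[level][v] for v in nodes],
                    [lookup[v] for v in nodes],
                )
            )
    return {
        "mean_ari_level1": float(np.mean(ari_by_level[1])),
        "mean_ari_level2": float(np.mean(ari_by_level[2])),
        "n_seeds": n_seeds,
    }


def energy_decline_benchmark(
    n_seeds: int = 10, base_seed: int = 0
) -> Dict[str, float]:
    """Fraction of nested-block instances whose CPM energy and mean split
    modularity decline strictly from the top level to the motif level
    (tree capped at the planted depth plus one refinement step)."""
    he_ok, q_ok = 0, 0
    for seed in _seeds(base_seed, n_seeds):
        G, _ = generate_network(_nested_spec(seed))
        params = ResolutionParams(gamma=0.5, max_depth=3)
        tree = build_module_tree(G, params)
        profile = level_energy_profile(tree, G, params)
        he = profile["he_level"].to_numpy()
        he_ok += bool((np.diff(he) < 0).all())
        qs = profile["mean_q_of_split"].dropna().to_numpy()
        q_ok += bool((np.diff(qs) < 0).all())
    return {
        "he_decline_fraction": he_ok / n_seeds,
        "split_q_decline_fraction": q_ok / n_seeds,
        "n_seeds": n_seeds,
    }


def key_regulator_benchmark(
    n_seeds: int = 20, base_seed: int = 0
) -> Dict[str, float]:
    """Precision and recall of fundamental-key-regulator calling.

    Per seed: 256 block nodes with 4 planted deep hubs and 4 pendant-star
    decoys; hubs are called as the top-8 degrees and traced down a tree
    capped at depth 5.
    """
    precisions, recalls = [], []
    for seed in _seeds(base_seed, n_seeds):
        spec = _nested_spec(
            seed, n_nodes=256, n_planted_hubs=4, n_decoy_hubs=4, decoy_pendant=64
        )
        G, truth = generate_network(spec)
        tree = build_module_tree(G, ResolutionParams(max_depth=5))
        report = call_key_regulators(tree, centralities(G), n_hubs=8)
        called = {r.gene for r in report if r.present_at_all_levels}
        planted = set(truth.hubs)
        tp = len(called & planted)
        precisions.append(tp / len(called) if called else 0.0)
        recalls.append(tp / len(planted))
    return {
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "n_seeds": n_seeds,
    }


def scale_free_benchmark(base_seed: int = 0) -> Dict[str, float]:
    """Scale-free and hierarchical signatures of the network generators.

    Fits the log-binned degree distribution of a preferential-attachment
    graph (n = 5000, m = 2) and the C(k)-vs-k Spearman correlation of the
    deterministic hierarchical-clique graph (125 nodes).
    """
    G, _ = generate_network(
        SyntheticNetworkSpec(
            kind="preferential_attachment", n_nodes=5000, m_attach=2,
            seed=base_seed,
        )
    )
    fit = fit_power_law(degree_distribution(G))
    H, _ = generate_network(
        SyntheticNetworkSpec(
            kind="hierarchical_cliques", n_nodes=125, levels=3, branching=5
        )
    )
    profile = topology_profile(H, centralities(H))
    usable = profile[profile["C"] > 0]
    rho = stats.spearmanr(usable.index.to_numpy(), usable["C"].to_numpy())
    return {
        "pk_exponent": fit.exponent,
        "pk_r_squared": fit.r_squared,
        "ck_spearman": float(rho.statistic),
    }
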