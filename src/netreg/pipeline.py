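"""End-to-end orchestration: expression -> DEGs -> networks -> hierarchy -> FKR.

One config drives the five stages in order (differential expression, network
building, topology, module hierarchy, key regulators) on either user-supplied
TSV inputs or a synthetic benchmark block, writes every stage artifact under
an output directory, and records a manifest with parameters, per-stage
summary numbers, and SHA-256 checksums of every artifact so a rerun with the
same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import networkx as nx

from . import diff_expression as de
from . import key_regulators as kr
from . import network_build as nb
from . import synthetic_data as sd
from . import topology as topo
from .hierarchy import ResolutionParams, build_module_tree, level_energy_profile

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Exactly one input source: either the real-input paths (matrix_path,
    labels_path, edges_path) or ``synthetic=True`` (a planted benchmark
    generated from ``seed``). Defaults mirror the pipeline's printed
    thresholds: |log2FC| >= 1.5, adjusted p < 0.05, edge confidence >= 0.4,
    CPM gamma 0.5, motif size 3, 10 hubs.
    """

    out_dir: Union[str, Path] = "netreg_run"
    matrix_path: Optional[str] = None
    labels_path: Optional[str] = None
    edges_path: Optional[str] = None
    tf_table_path: Optional[str] = None
    synthetic: bool = False
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05
    score_threshold: float = 0.4
    gamma: float = 0.5
    min_module_size: int = 3
    max_depth: Optional[int] = None
    n_hubs: int = 10
    seed: int = 0
    use_largest_component: bool = True

    def validate(self) -> None:
        real = [self.matrix_path, self.labels_path, self.edges_path]
        if self.synthetic and any(p is not None for p in real):
            raise ValueError("config mixes synthetic and real inputs; choose one")
        if not self.synthetic and not all(p is not None for p in real):
            raise ValueError(
                "config needs matrix_path, labels_path and edges_path "
                "(or synthetic=True)"
            )
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError(f"score_threshold outside [0, 1]: {self.score_threshold}")
        if self.fc_cutoff < 0 or not 0 < self.p_cutoff <= 1:
            raise ValueError("fc_cutoff must be >= 0 and p_cutoff in (0, 1]")
        ResolutionParams(
            gamma=self.gamma,
            min_module_size=self.min_module_size,
            max_depth=self.max_depth,
        )
        if self.n_hubs < 1:
            raise ValueError(f"n_hubs must be >= 1, got {self.n_hubs}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synthetic_inputs(cfg: RunConfig, out: Path) -> Dict[str, Path]:
    """Generate the demo benchmark: planted DEGs + a nested hub network."""
    expr_spec = sd.SyntheticExpressionSpec(
        n_genes=400, n_up=40, n_down=24, n_per_group=10, seed=cfg.seed
    )
    matrix, truth = sd.generate_expression(expr_spec)
    net_spec = sd.SyntheticNetworkSpec(
        kind="nested_blocks",
        n_nodes=128,
        levels=2,
        branching=2,
        p_within_leaf=0.5,
        p_between=(0.005, 0.05),
        n_planted_hubs=2,
        seed=cfg.seed,
    )
    G, net_truth = sd.generate_network(net_spec)
    # graft the network onto DEG symbols so the stages share a gene universe
    deg_symbols = list(truth.index[truth != "null"])
    extra = [g for g in truth.index if g not in deg_symbols]
    pool = deg_symbols + extra
    ordered = net_truth.hubs + [
        v for v in sorted(G.nodes, key=str) if v not in set(net_truth.hubs)
    ]
    mapping = {node: (pool[i] if i < len(pool) else node)
               for i, node in enumerate(ordered)}
    G = nx.relabel_nodes(G, mapping)
    paths = {
        "matrix": out / "matrix.tsv",
        "labels": out / "labels.tsv",
        "edges": out / "edges.tsv",
        "truth": out / "truth.json",
    }
    sd.write_expression_tsv(matrix, paths["matrix"])
    sd.write_labels_tsv(matrix, paths["labels"])
    sd.write_network_tsv(G, paths["edges"])
    sd.write_truth_json(
        {
            "expression": truth.to_dict(),
            "hubs": [mapping[h] for h in net_truth.hubs],
        },
        paths["truth"],
    )
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written as JSON).

    Any stage failure aborts with the stage name in the exception; artifacts
    written so far stay on disk next to a FAILED marker naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: str(v) if isinstance(v, Path) else v
                       for k, v in asdict(config).items()},
        "stages": {},
        "checksums": {},
    }
    stage = "inputs"
    try:
        if config.synthetic:
            paths = _synthetic_inputs(config, out)
            matrix_path, labels_path, edges_path = (
                paths["matrix"], paths["labels"], paths["edges"],
            )
        else:
            matrix_path = Path(config.matrix_path)
            labels_path = Path(config.labels_path)
            edges_path = Path(config.edges_path)

        stage = "diff_expression"
        matrix = de.read_expression(matrix_path, labels_path)
        degs = de.compute_deg_table(matrix, config.fc_cutoff, config.p_cutoff)
        up, down = de.split_by_direction(degs)
        de.write_deg_table(degs, out / "degs.tsv")
        manifest["stages"][stage] = {
            "n_genes": len(degs), "n_up": len(up), "n_down": len(down),
            "output": "degs.tsv",
        }
        logger.info("diff_expression: %d genes -> %d up, %d down",
                    len(degs), len(up), len(down))

        stage = "network_build"
        full_net = nb.read_edge_list(edges_path, config.score_threshold)
        net = nb.subset_to_genes(full_net, up + down)
        if net.number_of_nodes() == 0:
            net = full_net  # fall back to the full network when no DEG overlaps
        if config.use_largest_component and net.number_of_nodes() > 0:
            net = nb.largest_component(net)
        sd.write_network_tsv(net, out / "network.tsv")
        manifest["stages"][stage] = {
            **nb.network_summary(net), "output": "network.tsv",
        }
        logger.info("network_build: %d nodes, %d edges",
                    net.number_of_nodes(), net.number_of_edges())

        stage = "topology"
        cents = topo.centralities(net)
        profile = topo.topology_profile(net, cents)
        cents.to_csv(out / "centralities.tsv", sep="\t", index=False)
        profile.to_csv(out / "topology_profile.tsv", sep="\t")
        fits = {}
        try:
            fits["P_k"] = asdict(topo.fit_power_law(topo.degree_distribution(net)))
        except ValueError:
            pass
        (out / "power_law_fits.json").write_text(json.dumps(fits, indent=1))
        manifest["stages"][stage] = {
            "mean_clustering": topo.whole_network_clustering(net),
            "outputs": ["centralities.tsv", "topology_profile.tsv",
                        "power_law_fits.json"],
        }

        stage = "hierarchy"
        params = ResolutionParams(
            gamma=config.gamma,
            min_module_size=config.min_module_size,
            max_depth=config.max_depth,
        )
        tree = build_module_tree(net, params)
        energy = level_energy_profile(tree, net, params)
        (out / "module_tree.json").write_text(json.dumps(tree.to_json_dict(), indent=1))
        energy.to_csv(out / "level_profile.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "max_depth": tree.max_depth,
            "n_modules_bottom": len(tree.level_partition(tree.max_depth)),
            "outputs": ["module_tree.json", "level_profile.tsv"],
        }
        logger.info("hierarchy: depth %d", tree.max_depth)

        stage = "key_regulators"
        n_hubs = min(config.n_hubs, net.number_of_nodes())
        report = kr.call_key_regulators(tree, cents, degs, n_hubs=n_hubs)
        if config.tf_table_path:
            kr.annotate_tf(report, kr.read_tf_table(config.tf_table_path))
        frame = kr.report_to_frame(report)
        frame.to_csv(out / "key_regulators.tsv", sep="\t", index=False)
        (out / "key_regulators.json").write_text(json.dumps(
            [
                {
                    "gene": r.gene, "degree": r.degree,
                    "deepest_level": r.deepest_level,
                    "fundamental": r.present_at_all_levels,
                    "direction": r.direction,
                    "module_path": r.module_path,
                    "tf_roles": r.tf_roles,
                }
                for r in report
            ],
            indent=1,
        ))
        fkr = [r.gene for r in report if r.present_at_all_levels]
        manifest["stages"][stage] = {
            "n_hubs": n_hubs,
            "n_key_regulators": len(fkr),
            "key_regulators": fkr,
            "outputs": ["key_regulators.tsv", "key_regulators.json"],
        }
        logger.info("key_regulators: %d/%d hubs are fundamental", len(fkr), n_hubs)
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    for artifact in sorted(out.iterdir()):
        if artifact.name not in ("manifest.json", "FAILED") and artifact.is_file():
            manifest["checksums"][artifact.name] = _sha256(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
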