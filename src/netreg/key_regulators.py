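"""Hub calling, gene tracing, and fundamental key regulator identification.

A hub is one of the top-N degree nodes of the network. Tracing follows a
gene's containing module from the whole network (level 0) down the module
hierarchy until its module becomes a leaf; a gene whose chain reaches the
tree's maximum depth is "present at every hierarchical level". Fundamental
key regulators (FKR) are exactly the hubs with that property: high-degree
genes deep-rooted in the modular organization rather than riding a module
that dissolves early. Each key regulator is annotated with its differential-
expression direction and, from a user-supplied TF-target table, the
regulatory relations in which it appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .hierarchy import ModuleTree

logger = logging.getLogger(__name__)

__all__ = [
    "call_hubs",
    "trace_gene",
    "KeyRegulatorRecord",
    "call_key_regulators",
    "read_tf_table",
    "annotate_tf",
    "report_to_frame",
]

TF_MODES = ("activation", "repression", "unknown")


def call_hubs(cents: pd.DataFrame, n_hubs: int) -> List[str]:
    """Top-``n_hubs`` nodes by degree.

    Ties break by higher betweenness, then lexicographically smaller symbol,
    so the hub list is deterministic.
    """
    if n_hubs < 1:
        raise ValueError(f"n_hubs must be >= 1, got {n_hubs}")
    if n_hubs > len(cents):
        raise ValueError(
            f"n_hubs = {n_hubs} exceeds the {len(cents)} nodes in the network"
        )
    ranked = cents.sort_values(
        by=["degree", "betweenness", "node"], ascending=[False, False, True]
    )
    return ranked["node"].head(n_hubs).tolist()


def trace_gene(tree: ModuleTree, gene: str) -> List[str]:
    """Module ids containing a gene from the root down to its leaf.

    The chain's length minus one is the level at which the gene's module
    became a leaf; a chain of length ``tree.max_depth + 1`` means the gene
    persists to the deepest hierarchy level.
    """
    try:
        chain = tree.find(gene)
    except KeyError:
        raise KeyError(f"gene {gene!r} not present in the module tree") from None
    return [node.id for node in chain]


@dataclass
class KeyRegulatorRecord:
    gene: str
    degree: int
    is_hub: bool
    deepest_level: int
    present_at_all_levels: bool
    direction: str  # up / down / none / unknown
    module_path: List[str] = field(default_factory=list)
    tf_roles: List[Tuple[str, str, str]] = field(default_factory=list)


def call_key_regulators(
    tree: ModuleTree,
    cents: pd.DataFrame,
    degs: Optional[pd.DataFrame] = None,
    n_hubs: int = 10,
) -> List[KeyRegulatorRecord]:
    """Hubs whose module chain reaches the hierarchy's maximum depth.

    Returns one record per hub, sorted by degree descending, with
    ``present_at_all_levels`` marking the fundamental key regulators.
    Hubs absent from the DEG table get direction "unknown". A depth-0 tree
    (nothing ever split) makes every hub trivially deep-rooted; that
    degenerate case is flagged with a warning.
    """
    max_depth = tree.max_depth
    if max_depth == 0:
        logger.warning(
            "module tree has depth 0; every hub is trivially present at all levels"
        )
    directions: Dict[str, str] = {}
    if degs is not None:
        directions = dict(zip(degs["gene"], degs["direction"]))
    degree_of = dict(zip(cents["node"], cents["degree"]))

    records = []
    for gene in call_hubs(cents, n_hubs):
        path = trace_gene(tree, gene)
        deepest = len(path) - 1
        records.append(
            KeyRegulatorRecord(
                gene=gene,
                degree=int(degree_of[gene]),
                is_hub=True,
                deepest_level=deepest,
                present_at_all_levels=deepest == max_depth,
                direction=directions.get(gene, "unknown"),
                module_path=path,
            )
        )
    records.sort(key=lambda r: (-r.degree, r.gene))
    return records


def read_tf_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a 3-column (tf, target, mode) regulatory table TSV.

    A header line is tolerated; modes outside {activation, repression,
    unknown} map to "unknown"; malformed rows raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 columns (tf, target, mode), "
                    f"got {len(fields)}"
                )
            if lineno == 1 and fields[0].lower() in ("tf", "regulator"):
                continue
            mode = fields[2].lower()
            if mode not in TF_MODES:
                mode = "unknown"
            rows.append((fields[0], fields[1], mode))
    return pd.DataFrame(rows, columns=["tf", "target", "mode"])


def annotate_tf(
    report: Sequence[KeyRegulatorRecord], tf_table: pd.DataFrame
) -> List[KeyRegulatorRecord]:
    """Attach TF-target relations to each record (pure table join, in place).

    A gene appearing as ``tf`` gains (target, "regulator", mode); appearing
    as ``target`` it gains (tf, "target", mode). Both roles attach when a
    gene occurs on both sides of the table.
    """
    for rec in report:
        roles: List[Tuple[str, str, str]] = []
        as_tf = tf_table[tf_table["tf"] == rec.gene]
        roles.extend(
            (row.target, "regulator", row.mode) for row in as_tf.itertuples()
        )
        as_target = tf_table[tf_table["target"] == rec.gene]
        roles.extend((row.tf, "target", row.mode) for row in as_target.itertuples())
        rec.tf_roles = roles
    return list(report)


def report_to_frame(report: Sequence[KeyRegulatorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in report],
            "degree": [r.degree for r in report],
            "is_hub": [r.is_hub for r in report],
            "deepest_level": [r.deepest_level for r in report],
            "present_at_all_levels": [r.present_at_all_levels for r in report],
            "direction": [r.direction for r in report],
            "n_tf_roles": [len(r.tf_roles) for r in report],
        }
    )
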