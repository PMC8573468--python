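"""Two-group differential expression with fold-change and FDR cutoffs.

Genes are called up/down from a log2 expression matrix by a Welch two-sample
t-test per gene, Benjamini–Hochberg adjustment across genes, and the classic
microarray cutoffs |log2FC| >= 1.5 and adjusted p < 0.05. The moderated
linear models real platforms use upstream are out of scope here; only the
printed cutoff semantics are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "compute_deg_table",
    "split_by_direction",
    "union_deg_symbols",
    "write_deg_table",
]

DEG_COLUMNS = ["gene", "log2fc", "p_value", "adj_p", "direction"]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities with a two-group sample labelling.

    ``values`` is a DataFrame indexed by unique gene symbols with sample-ID
    columns; ``groups`` maps every sample to ``"control"`` or ``"case"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        levels = set(self.groups.unique())
        if levels != {"control", "case"}:
            raise ValueError(
                f"groups must be exactly {{'control', 'case'}}, got {sorted(levels)}"
            )
        bad = ~np.isfinite(self.values.to_numpy())
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    def samples_in(self, group: str) -> List[str]:
        return list(self.groups.index[self.groups == group])


def read_expression(
    matrix_path: Union[str, Path], labels_path: Union[str, Path]
) -> ExpressionMatrix:
    """Read the TSV pair written by the synthetic generator (or equivalent)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, groups=labels.iloc[:, 0])


def compute_deg_table(
    matrix: ExpressionMatrix, fc_cutoff: float = 1.5, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """Per-gene log2 fold change, Welch p, BH-adjusted p and up/down call.

    log2fc is case mean minus control mean. Genes with zero variance in both
    groups (possible on noiseless synthetic data) get p = 0 when the means
    differ and p = 1 when they coincide, with a logged warning. Returns a
    DataFrame with columns gene, log2fc, p_value, adj_p, direction in the
    input gene order.
    """
    if fc_cutoff < 0:
        raise ValueError(f"fc_cutoff must be >= 0, got {fc_cutoff}")
    ctrl = matrix.values[matrix.samples_in("control")].to_numpy()
    case = matrix.values[matrix.samples_in("case")].to_numpy()
    for name, arr in (("control", ctrl), ("case", case)):
        if arr.shape[1] < 2:
            raise ValueError(
                f"group {name!r} has {arr.shape[1]} sample(s); need >= 2 for the test"
            )

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)

    degenerate = (ctrl.std(axis=1) == 0) & (case.std(axis=1) == 0)
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero variance in both groups; p set to 0/1 by mean equality",
            int(degenerate.sum()),
        )
        p[degenerate] = np.where(np.abs(log2fc[degenerate]) > 1e-12, 0.0, 1.0)
    p = np.nan_to_num(p, nan=1.0)

    adj_p = multipletests(p, method="fdr_bh")[1]
    direction = np.full(len(p), "none", dtype=object)
    significant = adj_p < p_cutoff
    direction[significant & (log2fc >= fc_cutoff)] = "up"
    direction[significant & (log2fc <= -fc_cutoff)] = "down"

    return pd.DataFrame(
        {
            "gene": matrix.values.index,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj_p,
            "direction": direction,
        }
    ).reset_index(drop=True)


def split_by_direction(degs: pd.DataFrame) -> Tuple[List[str], List[str]]:
    """Partition called genes into (up, down) symbol lists, order preserved."""
    up = degs.loc[degs["direction"] == "up", "gene"].tolist()
    down = degs.loc[degs["direction"] == "down", "gene"].tolist()
    return up, down


def union_deg_symbols(symbol_lists: Iterable[Sequence[str]]) -> List[str]:
    """Set union of DEG symbol lists from multiple datasets, first-seen order.

    Cross-platform integration is modelled as a union of the per-dataset
    calls (the graph-union of the per-dataset networks downstream operates on
    the same merged universe).
    """
    seen = {}
    for symbols in symbol_lists:
        for s in symbols:
            seen.setdefault(s, None)
    return list(seen)


def write_deg_table(degs: pd.DataFrame, path: Union[str, Path]) -> None:
    degs[DEG_COLUMNS].to_csv(path, sep="\t", index=False)
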