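"""Centralities, degree-indexed topology curves, and power-law fits.

The four centralities characterizing protein-interaction networks: degree,
closeness (within-component, classical (n-1)/sum-of-distances form),
betweenness (unnormalized Freeman definition, endpoints excluded), and
eigenvector centrality (principal eigenvector of the adjacency operator,
computed per connected component). On top of these, the degree-indexed
curves P(k), C(k), CN(k), CB(k), CC(k) and their log-log power-law fits
diagnose scale-free and hierarchical organization: a heavy-tailed P(k) with
C(k) decaying in k is the signature of modules nested within modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "centralities",
    "whole_network_clustering",
    "topology_profile",
    "degree_distribution",
    "PowerLawFit",
    "fit_power_law",
    "power_law_mle",
]


def _component_eigenvector(G: nx.Graph, nodes: Sequence) -> Dict:
    """Principal adjacency eigenvector of one component, nonnegative, unit L2.

    Edgeless components (singletons) have a degenerate spectrum and get 0.
    """
    sub = G.subgraph(nodes)
    if sub.number_of_edges() == 0:
        return {v: 0.0 for v in nodes}
    order = sorted(sub.nodes, key=str)
    A = nx.to_numpy_array(sub, nodelist=order)
    if len(order) <= 600:
        w, V = np.linalg.eigh(A)
        vec = V[:, -1]
    else:
        from scipy.sparse import csr_array
        from scipy.sparse.linalg import eigsh

        v0 = np.ones(len(order))
        w, V = eigsh(csr_array(A), k=1, which="LA", v0=v0, tol=0)
        vec = V[:, 0]
    vec = np.abs(vec)  # Perron-Frobenius: principal eigenvector is sign-constant
    vec /= np.linalg.norm(vec)
    return dict(zip(order, vec))


def centralities(G: nx.Graph) -> pd.DataFrame:
    """Degree, closeness, betweenness and eigenvector centrality per node.

    Closeness and eigenvector centrality are computed within each connected
    component; betweenness is the raw Freeman sum of shortest-path shares
    over unordered pairs.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("centralities of an empty network")
    deg = dict(G.degree())
    clo = nx.closeness_centrality(G, wf_improved=False)
    bet = nx.betweenness_centrality(G, normalized=False)
    eig: Dict = {}
    for comp in nx.connected_components(G):
        eig.update(_component_eigenvector(G, comp))
    nodes = sorted(G.nodes, key=str)
    return pd.DataFrame(
        {
            "node": nodes,
            "degree": [deg[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "betweenness": [bet[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
        }
    )


def whole_network_clustering(G: nx.Graph, count_low_degree: bool = True) -> float:
    """Mean clustering coefficient of the network.

    ``count_low_degree`` keeps degree-<2 nodes in the mean as zeros (the
    default convention); False averages over nodes with degree >= 2 only.
    """
    if count_low_degree:
        return float(nx.average_clustering(G))
    nodes = [v for v, d in G.degree() if d >= 2]
    if not nodes:
        return 0.0
    return float(np.mean(list(nx.clustering(G, nodes).values())))


def topology_profile(G: nx.Graph, cents: pd.DataFrame) -> pd.DataFrame:
    """Per-degree averages: P(k), C(k), CN(k), CB(k), CC(k).

    One row per observed degree k; P sums to 1 over rows.
    """
    clustering = nx.clustering(G)
    neigh_deg = nx.average_neighbor_degree(G)
    table = cents.assign(
        clustering=[clustering[v] for v in cents["node"]],
        neighbor_degree=[neigh_deg[v] for v in cents["node"]],
    )
    grouped = table.groupby("degree")
    n = len(table)
    profile = pd.DataFrame(
        {
            "P": grouped.size() / n,
            "C": grouped["clustering"].mean(),
            "CN": grouped["neighbor_degree"].mean(),
            "CB": grouped["betweenness"].mean(),
            "CC": grouped["closeness"].mean(),
        }
    )
    profile.index.name = "k"
    return profile


def degree_distribution(
    G: nx.Graph, log_binned: bool = True, n_bins: int = 15
) -> Dict[float, float]:
    """P(k) of the network, optionally averaged over logarithmic bins.

    Raw degree histograms of heavy-tailed networks have a one-count tail
    that flattens least-squares slope estimates; logarithmic binning (bin
    densities normalized by bin width, geometric-mean bin centres) is the
    standard correction and is the default here. Degree-0 nodes are excluded
    (log undefined).
    """
    deg = np.array([d for _, d in G.degree() if d > 0])
    if deg.size == 0:
        return {}
    if not log_binned:
        ks, counts = np.unique(deg, return_counts=True)
        return {float(k): float(c) / deg.size for k, c in zip(ks, counts)}
    edges = np.unique(
        np.round(
            np.logspace(np.log10(deg.min()), np.log10(deg.max() + 1), n_bins + 1)
        ).astype(int)
    )
    curve: Dict[float, float] = {}
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (deg >= a) & (deg < b)
        if not mask.any():
            continue
        centre = float(np.exp(np.mean(np.log(np.arange(a, b)))))
        curve[centre] = float(mask.sum()) / deg.size / (b - a)
    return curve


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line on (log10 k, log10 value)."""

    exponent: float
    intercept: float
    r_squared: float
    k_range: Tuple[float, float]


def fit_power_law(curve: Mapping[float, float]) -> PowerLawFit:
    """Fit value ~ k^exponent by least squares on the log-log scale.

    Only strictly positive (k, value) points enter the fit; fewer than three
    such points is an error. A constant curve fits slope 0 exactly.
    """
    pts = [(k, v) for k, v in curve.items() if k > 0 and v > 0]
    if len(pts) < 3:
        raise ValueError(f"insufficient points for a power-law fit ({len(pts)} < 3)")
    ks, vs = map(np.asarray, zip(*sorted(pts)))
    res = stats.linregress(np.log10(ks), np.log10(vs))
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return PowerLawFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        k_range=(float(ks[0]), float(ks[-1])),
    )


def power_law_mle(degrees: Sequence[int], k_min: Optional[int] = None) -> float:
    """Continuous-approximation MLE of the tail exponent, as a cross-check.

    alpha = 1 + n / sum(ln(k / (k_min - 1/2))) over degrees >= k_min.
    Returned negated so its sign convention matches the least-squares slope.
    """
    deg = np.array([d for d in degrees if d > 0], dtype=float)
    if k_min is None:
        k_min = int(deg.min())
    tail = deg[deg >= k_min]
    if tail.size < 3:
        raise ValueError("insufficient tail for MLE")
    alpha = 1.0 + tail.size / np.sum(np.log(tail / (k_min - 0.5)))
    return -float(alpha)
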