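"""Independent brute-force oracles used to validate the library.

Everything here is written from the definitions, by exhaustive enumeration
or direct summation, deliberately avoiding the code paths (and wherever
possible the libraries) the implementation uses: shortest paths are
enumerated explicitly, eigenvectors come from plain power iteration, and
partition scores are pairwise sums over the adjacency matrix.
"""

from __future__ import annotations

import itertools
from collections import deque
from typing import Dict, Hashable, Iterable, List, Sequence, Tuple

import numpy as np


Edge = Tuple[Hashable, Hashable]


def adjacency(nodes: Sequence, edges: Iterable[Edge]) -> Dict[Hashable, set]:
    adj = {v: set() for v in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def bfs_distances(adj: Dict, source) -> Dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def components(adj: Dict) -> List[set]:
    seen, comps = set(), []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def enumerate_shortest_paths(adj: Dict, s, t) -> List[List]:
    """All shortest s-t paths, by DFS constrained to a BFS distance field."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths, stack = [], [[s]]
    while stack:
        path = stack.pop()
        u = path[-1]
        if u == t:
            paths.append(path)
            continue
        for w in adj[u]:
            if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                stack.append(path + [w])
    return [p for p in paths if len(p) - 1 == dist[t]]


def betweenness_oracle(nodes: Sequence, edges: Iterable[Edge]) -> Dict:
    """Freeman betweenness: sum over unordered pairs of path shares through v."""
    adj = adjacency(nodes, edges)
    bet = {v: 0.0 for v in nodes}
    node_list = list(nodes)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1 :]:
            paths = enumerate_shortest_paths(adj, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bet[v] += 1.0 / sigma
    return bet


def closeness_oracle(nodes: Sequence, edges: Iterable[Edge]) -> Dict:
    """(n_comp - 1) / sum of within-component distances; 0 for isolates."""
    adj = adjacency(nodes, edges)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def eigenvector_oracle(
    nodes: Sequence, edges: Iterable[Edge], tol: float = 1e-12
) -> Dict:
    """Per-component principal eigenvector by power iteration on A + I.

    The +I shift guarantees convergence on bipartite components (where the
    adjacency spectrum is symmetric) without changing the eigenvector.
    Edgeless components get 0 by convention.
    """
    adj = adjacency(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for comp in components(adj):
        comp = sorted(comp, key=str)
        if not any(adj[v] for v in comp):
            continue
        index = {v: i for i, v in enumerate(comp)}
        A = np.zeros((len(comp), len(comp)))
        for v in comp:
            for w in adj[v]:
                A[index[v], index[w]] = 1.0
        M = A + np.eye(len(comp))
        x = np.ones(len(comp)) / np.sqrt(len(comp))
        for _ in range(100_000):
            y = M @ x
            y /= np.linalg.norm(y)
            if np.linalg.norm(y - x) < tol:
                x = y
                break
            x = y
        x = np.abs(x)
        x /= np.linalg.norm(x)
        for v in comp:
            out[v] = float(x[index[v]])
    return out


def modularity_oracle(
    nodes: Sequence, edges: Iterable[Edge], partition: Sequence[Iterable]
) -> float:
    """Q as the pairwise sum (1/2m) sum_ij (A_ij - k_i k_j / 2m) d(c_i, c_j)."""
    node_list = list(nodes)
    index = {v: i for i, v in enumerate(node_list)}
    n = len(node_list)
    A = np.zeros((n, n))
    for u, v in edges:
        if u != v:
            A[index[u], index[v]] = A[index[v], index[u]] = 1.0
    k = A.sum(axis=1)
    m = k.sum() / 2.0
    if m == 0:
        return 0.0
    comm = {}
    for c, part in enumerate(partition):
        for v in part:
            comm[index[v]] = c
    q = 0.0
    for i in range(n):
        for j in range(n):
            if comm[i] == comm[j]:
                q += A[i, j] - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def cpm_oracle(
    nodes: Sequence, edges: Iterable[Edge], partition: Sequence[Iterable],
    gamma: float,
) -> float:
    """H = -sum over same-community pairs i<j of (A_ij - gamma)."""
    edge_set = {frozenset(e) for e in edges if e[0] != e[1]}
    h = 0.0
    for part in partition:
        part = list(part)
        for i, u in enumerate(part):
            for v in part[i + 1 :]:
                a = 1.0 if frozenset((u, v)) in edge_set else 0.0
                h -= a - gamma
    return h


def best_bipartition(nodes: Sequence, edges: Iterable[Edge]):
    """Exhaustive max-modularity bipartition (feasible to n ~ 12)."""
    node_list = list(nodes)
    edges = list(edges)
    best_q, best = -np.inf, None
    n = len(node_list)
    for mask in range(1, 2 ** (n - 1)):  # fix node 0 on one side
        left = [node_list[i] for i in range(n) if mask & (1 << i) == 0]
        right = [node_list[i] for i in range(n) if mask & (1 << i)]
        q = modularity_oracle(node_list, edges, [left, right])
        if q > best_q + 1e-12:
            best_q, best = q, (left, right)
    return best_q, best


def random_graph(rng: np.random.Generator, n: int, p: float):
    """Plain Bernoulli random graph as (nodes, edges) with string labels."""
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges


def random_partition(rng: np.random.Generator, nodes: Sequence, k: int):
    labels = rng.integers(0, k, size=len(nodes))
    return [
        [v for v, c in zip(nodes, labels) if c == lab]
        for lab in range(k)
        if (labels == lab).any()
    ]
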