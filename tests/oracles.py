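"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: graph measures are
computed by direct enumeration/summation, TFNBS scores by per-threshold
component labeling with networkx, and permutation p-values by exhaustive
enumeration with scipy's t-test.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats


def strength_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(w[i, j] for j in range(n)) for i in range(n)])


def clustering_oracle(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by direct triple summation."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    what = w / wmax
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and w[j, h] > 0:
                    s += (what[i, j] * what[j, h] * what[h, i]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def assortativity_oracle(w: np.ndarray) -> float:
    """Pearson correlation of endpoint strengths over the expanded edge list."""
    n = w.shape[0]
    s = strength_oracle(w)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                xs.append(s[i])
                ys.append(s[j])
    if len(xs) < 2:
        return float("nan")
    xs, ys = np.array(xs), np.array(ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    sx = xs - xs.mean()
    sy = ys - ys.mean()
    return float((sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum()))


def betweenness_oracle(w: np.ndarray) -> np.ndarray:
    """Exhaustive simple-path enumeration betweenness on lengths 1/w.

    Use dyadic weights (e.g. 0.5, 1, 2, 4) so that tied path lengths are
    exact in floating point and tie handling is unambiguous.
    """
    n = w.shape[0]
    lengths = {(i, j): 1.0 / w[i, j] for i in range(n) for j in range(n) if w[i, j] > 0}
    bc = np.zeros(n)

    def all_paths(s, t):
        paths = []
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, dist = stack.pop()
            if node == t:
                paths.append((dist, path))
                continue
            for j in range(n):
                if (node, j) in lengths and j not in path:
                    stack.append((j, path + [j], dist + lengths[(node, j)]))
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_paths(s, t)
            if not paths:
                continue
            dmin = min(d for d, _ in paths)
            shortest = [p for d, p in paths if d == dmin]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm


def tfnbs_oracle(t_matrix: np.ndarray, heights: np.ndarray, dh: float,
                 E: float, H: float) -> np.ndarray:
    """Per-threshold connected-component labeling with networkx."""
    n = t_matrix.shape[0]
    ref = np.zeros((n, n))
    for h in heights:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if t_matrix[i, j] > h:
                    g.add_edge(i, j)
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            extent = sub.number_of_edges()
            for (i, j) in sub.edges():
                ref[i, j] += extent ** E * h ** H * dh
                ref[j, i] = ref[i, j]
    return ref


def exhaustive_fwe_oracle(x: np.ndarray, n_pd: int, heights: np.ndarray,
                          dh: float, E: float, H: float,
                          observed_pd_idx: tuple[int, ...]) -> np.ndarray:
    """Exact permutation FWE p per edge for hypothesis PD > HC.

    Enumerates every assignment of ``n_pd`` subjects to the PD group,
    computes Welch t per edge with scipy, scores with the networkx TFNBS
    oracle, and compares max scores against the observed labeling.
    Returns a p-value per edge (flat upper-triangle order).
    """
    n_sub, n_edges = x.shape
    n = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    iu = np.triu_indices(n, 1)

    def scores_for(idx):
        mask = np.zeros(n_sub, dtype=bool)
        mask[list(idx)] = True
        tvals = np.array([
            stats.ttest_ind(x[mask, e], x[~mask, e], equal_var=False).statistic
            for e in range(n_edges)
        ])
        tm = np.zeros((n, n))
        tm[iu] = tvals
        tm += tm.T
        return tfnbs_oracle(tm, heights, dh, E, H)[iu]

    obs = scores_for(observed_pd_idx)
    count = np.zeros(n_edges)
    total = 0
    for idx in combinations(range(n_sub), n_pd):
        total += 1
        count += scores_for(idx).max() >= obs
    return count / total
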