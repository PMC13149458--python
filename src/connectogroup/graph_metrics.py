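"""Weighted-graph measures per subject connectome.

Node level: strength (sum of incident edge weights), betweenness centrality
(weighted shortest paths on edge lengths 1/w, normalized to [0, 1]), and the
Onnela weighted clustering coefficient.  Whole-brain level: the node
averages of those three measures plus strength assortativity (the Pearson
correlation of endpoint node strengths over the edge list).

No thresholding is applied anywhere: the dense weighted graphs are analyzed
as-is.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .core import Cohort, Connectome

logger = logging.getLogger(__name__)

NODE_MEASURES = ("strength", "betweenness", "clustering")
GLOBAL_MEASURES = ("mean_strength", "mean_betweenness", "mean_clustering", "assortativity")


def _graph(weights: np.ndarray) -> nx.Graph:
    """Undirected graph with 'weight' and 'length' (=1/weight) edge attrs;
    zero-weight edges are absent."""
    g = nx.from_numpy_array(weights)
    zero = [(u, v) for u, v, w in g.edges(data="weight") if w <= 0]
    g.remove_edges_from(zero)
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    return g


def node_strength(c: Connectome) -> np.ndarray:
    """s_i = sum_j w_ij."""
    return c.weights.sum(axis=1)


def betweenness_centrality(c: Connectome) -> np.ndarray:
    """Fraction of all-pairs weighted shortest paths through each node.

    Strong edges are short: path lengths use l = 1/w.  Multiple shortest
    paths share credit fractionally; normalization by (N-1)(N-2)/2 puts
    values in [0, 1]; pairs in different components contribute nothing, and
    isolated nodes get 0.
    """
    g = _graph(c.weights)
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    return np.array([bc[i] for i in range(c.n_regions)])


def clustering_coefficient(c: Connectome) -> np.ndarray:
    """Onnela weighted clustering: geometric-mean triangle intensity with
    weights normalized by the graph maximum; nodes with < 2 neighbors get 0."""
    if not c.weights.any():
        return np.zeros(c.n_regions)
    g = _graph(c.weights)
    cc = nx.clustering(g, weight="weight")
    return np.array([cc[i] for i in range(c.n_regions)])


def assortativity(c: Connectome) -> float:
    """Pearson correlation of endpoint node strengths over all edges.

    Each undirected edge contributes both orientations.  Returns NaN when
    the endpoint strengths have zero variance (e.g. regular graphs) or when
    there are fewer than 2 edges — reported as missing, not an error.
    """
    w = c.weights
    s = w.sum(axis=1)
    ii, jj = np.nonzero(np.triu(w, k=1))
    if ii.size < 2:
        return float("nan")
    x = np.concatenate([s[ii], s[jj]])
    y = np.concatenate([s[jj], s[ii]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


_NODE_FUNCS = {
    "strength": node_strength,
    "betweenness": betweenness_centrality,
    "clustering": clustering_coefficient,
}


def node_measure_matrix(cohort: Cohort, metric: str, filtering: str,
                        measure: str) -> np.ndarray:
    """(n_subjects, n_regions) matrix of one node measure, manifest order."""
    func = _NODE_FUNCS[measure]
    return np.stack([
        func(cohort.get(sid, metric, filtering))
        for sid in cohort.manifest.subject_ids
    ])


def compute_cohort_metrics(cohort: Cohort, metric: str, filtering: str,
                           measures: tuple[str, ...] = NODE_MEASURES,
                           include_assortativity: bool = True
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All graph measures for all subjects of one (metric, filtering) cell.

    Returns ``(node_table, global_table)`` in long format.  The global table
    holds the node averages of each measure plus assortativity; subjects
    whose assortativity is undefined appear with NaN and are excluded
    pairwise from group tests downstream.
    """
    node_rows, global_rows = [], []
    names = cohort.labels.names
    for sid in cohort.manifest.subject_ids:
        c = cohort.get(sid, metric, filtering)
        for measure in measures:
            vals = _NODE_FUNCS[measure](c)
            node_rows.extend(
                {"subject_id": sid, "metric": metric, "filtering": filtering,
                 "measure": measure, "node": i, "region": names[i], "value": v}
                for i, v in enumerate(vals))
            global_rows.append(
                {"subject_id": sid, "metric": metric, "filtering": filtering,
                 "measure": f"mean_{measure}", "value": float(vals.mean())})
        if include_assortativity:
            a = assortativity(c)
            if np.isnan(a):
                logger.info("assortativity undefined for subject %s", sid)
            global_rows.append(
                {"subject_id": sid, "metric": metric, "filtering": filtering,
                 "measure": "assortativity", "value": a})
    return pd.DataFrame(node_rows), pd.DataFrame(global_rows)
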