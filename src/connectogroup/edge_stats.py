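"""Edge-level group inference: mass-univariate t-statistics and
threshold-free network-based statistics (TFNBS) with permutation FWE.

TFNBS replaces the single, arbitrary edge threshold of the classical
network-based statistic with a ladder of thresholds: at each height h the
t-statistic matrix is binarized at t > h, connected components of the
suprathreshold graph are found, and every suprathreshold edge accumulates

    extent(component)^E * h^H * dh,

where extent is the number of edges in its component.  Significance of the
accumulated scores is assessed against the permutation distribution of the
maximum score over edges (family-wise error control).  Both one-sided
hypotheses are tested: t1 (PD > HC) and t2 (HC > PD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .atlas import RegionAtlasLabels
from .core import Cohort

logger = logging.getLogger(__name__)

HYPOTHESES = ("t1_PD_gt_HC", "t2_HC_gt_PD")


@dataclass(frozen=True)
class TFNBSConfig:
    """TFNBS parameters.

    ``E`` and ``H`` are the extent and height exponents; the threshold
    ladder has ``n_steps`` evenly spaced levels over ``threshold_range``
    (``h_max=None`` means data-driven: the maximum observed t).
    """

    E: float = 0.5
    H: float = 3.0
    n_steps: int = 100
    h_min: float = 0.0
    h_max: float | None = None          # None => max observed t
    n_permutations: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.h_min < 0:
            raise ValueError("h_min must be >= 0")
        if self.E < 0 or self.H < 0:
            raise ValueError("exponents must be nonnegative")

    def ladder(self, t_max: float) -> tuple[np.ndarray, float]:
        """Threshold heights (exclusive of h_min) and the spacing dh."""
        h_max = self.h_max if self.h_max is not None else t_max
        if h_max <= self.h_min:
            return np.empty(0), 0.0
        dh = (h_max - self.h_min) / self.n_steps
        heights = self.h_min + dh * np.arange(1, self.n_steps + 1)
        return heights, dh


@dataclass
class EdgeInferenceResult:
    """Per-edge inference output for both hypotheses on one
    (metric, filtering) cell."""

    metric: str
    filtering: str
    t: np.ndarray                               # symmetric (n, n), sign: PD - HC
    p_uncorrected: dict[str, np.ndarray]        # hypothesis -> (n, n)
    scores: dict[str, np.ndarray]               # hypothesis -> (n, n) TFNBS scores
    p_fwe: dict[str, np.ndarray]                # hypothesis -> (n, n)
    config: TFNBSConfig
    n_permutations_used: int = 0
    exhaustive: bool = False
    labels: RegionAtlasLabels | None = None


def welch_t(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch two-sample t over columns: t of group1 minus group2,
    and the Welch-Satterthwaite degrees of freedom.

    Columns with zero variance in both groups get t = 0 and df = 1 (flagged
    as undefined by the zero t; their one-sided p is 0.5).
    """
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1, v2 = x1.var(axis=0, ddof=1), x2.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1)) + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    zero = se2 == 0
    t = np.where(zero, 0.0, t)
    df = np.where(zero | ~np.isfinite(df), 1.0, df)
    return t, df


def _edge_design(cohort: Cohort, metric: str, filtering: str):
    cohort.manifest.require_two_groups()
    x = cohort.edge_matrix(metric, filtering)
    pd_mask = cohort.manifest.group_mask("PD")
    return x, pd_mask


def _to_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    out[iu] = vec
    out.T[iu] = vec
    return out


def edge_t_statistics(cohort: Cohort, metric: str, filtering: str
                      ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Welch t per edge (sign: PD minus HC) and one-sided p for t1 and t2.

    Returns ``(t_matrix, {hypothesis: p_matrix})`` with symmetric matrices.
    """
    x, pd_mask = _edge_design(cohort, metric, filtering)
    t, df = welch_t(x[pd_mask], x[~pd_mask])
    p1 = stats.t.sf(t, df)          # PD > HC
    p2 = stats.t.cdf(t, df)         # HC > PD
    n = len(cohort.labels)
    return _to_matrix(t, n), {"t1_PD_gt_HC": _to_matrix(p1, n),
                              "t2_HC_gt_PD": _to_matrix(p2, n)}


def tfnbs_scores(t_matrix: np.ndarray, cfg: TFNBSConfig,
                 hypothesis: str = "t1_PD_gt_HC") -> np.ndarray:
    """Accumulated TFNBS scores for one hypothesis.

    The t matrix is oriented so that positive t favors PD > HC; for
    hypothesis t2 the sign is flipped before thresholding.
    """
    t = np.asarray(t_matrix, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("t matrix must be square")
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if hypothesis == "t2_HC_gt_PD":
        t = -t
    n = t.shape[0]
    iu = np.triu_indices(n, 1)
    tv = t[iu]
    scores = np.zeros(tv.size)
    t_max = float(tv.max(initial=0.0))
    heights, dh = cfg.ladder(t_max)
    if heights.size == 0:
        if cfg.h_max is not None and cfg.h_max <= cfg.h_min:
            raise ValueError("empty threshold ladder: h_max must exceed h_min")
        return np.zeros_like(t)
    _accumulate_scores(tv, iu, n, heights, dh, cfg.E, cfg.H, scores)
    return _to_matrix(scores, n)


@njit(cache=True)
def _accumulate_kernel(tv, rows, cols, n, heights, dh, E, H, scores):
    """Add extent^E * h^H * dh to suprathreshold edges, one ladder level at
    a time; connected components by union-find with path compression."""
    parent = np.empty(n, dtype=np.int64)
    extent = np.empty(n, dtype=np.int64)
    for h in heights:
        for v in range(n):
            parent[v] = v
            extent[v] = 0
        any_above = False
        for e in range(tv.size):
            if tv[e] > h:
                any_above = True
                # find roots with path compression
                r = rows[e]
                while parent[r] != r:
                    parent[r] = parent[parent[r]]
                    r = parent[r]
                c = cols[e]
                while parent[c] != c:
                    parent[c] = parent[parent[c]]
                    c = parent[c]
                if r != c:
                    parent[c] = r
        if not any_above:
            break                     # heights ascend; nothing survives later
        for e in range(tv.size):
            if tv[e] > h:
                r = rows[e]
                while parent[r] != r:
                    r = parent[r]
                extent[r] += 1
        inc = h ** H * dh
        for e in range(tv.size):
            if tv[e] > h:
                r = rows[e]
                while parent[r] != r:
                    r = parent[r]
                scores[e] += extent[r] ** E * inc


def _accumulate_scores(tv: np.ndarray, iu, n: int, heights: np.ndarray, dh: float,
                       E: float, H: float, scores: np.ndarray) -> None:
    _accumulate_kernel(np.ascontiguousarray(tv), iu[0].astype(np.int64),
                       iu[1].astype(np.int64), n, np.ascontiguousarray(heights),
                       dh, E, H, scores)


def tfnbs_fwe(cohort: Cohort, metric: str, filtering: str,
              cfg: TFNBSConfig) -> EdgeInferenceResult:
    """Permutation max-score FWE correction of TFNBS scores.

    Group labels are permuted ``cfg.n_permutations`` times (or exhaustively
    when fewer distinct assignments exist); the same permutations serve both
    hypotheses.  The threshold ladder is fixed from the observed t maximum
    over both hypotheses so that scores are comparable across permutations.
    p_fwe(edge) = (1 + #{perm max >= observed score}) / (1 + n_perm) for
    sampled permutations; with exhaustive enumeration the identity labeling
    is a member of the enumeration and is not counted twice.
    """
    x, pd_mask = _edge_design(cohort, metric, filtering)
    n = len(cohort.labels)
    iu = np.triu_indices(n, 1)
    n_sub = x.shape[0]
    n_pd = int(pd_mask.sum())

    t_obs, df = welch_t(x[pd_mask], x[~pd_mask])
    p_unc = {"t1_PD_gt_HC": stats.t.sf(t_obs, df), "t2_HC_gt_PD": stats.t.cdf(t_obs, df)}

    # fixed ladder for observed and permuted data alike
    t_max = float(np.abs(t_obs).max(initial=0.0))
    run_cfg = cfg if cfg.h_max is not None else TFNBSConfig(
        E=cfg.E, H=cfg.H, n_steps=cfg.n_steps, h_min=cfg.h_min, h_max=t_max,
        n_permutations=cfg.n_permutations, seed=cfg.seed)

    def score_vec(tv: np.ndarray, sign: float) -> np.ndarray:
        s = np.zeros(tv.size)
        heights, dh = run_cfg.ladder(t_max)
        if heights.size:
            _accumulate_scores(sign * tv, iu, n, heights, dh, run_cfg.E, run_cfg.H, s)
        return s

    obs_scores = {"t1_PD_gt_HC": score_vec(t_obs, +1.0),
                  "t2_HC_gt_PD": score_vec(t_obs, -1.0)}

    n_distinct = comb(n_sub, n_pd)
    exhaustive = n_distinct <= cfg.n_permutations
    if exhaustive:
        logger.info("exhaustive enumeration of %d group assignments", n_distinct)
        perm_iter = (np.isin(np.arange(n_sub), idx)
                     for idx in combinations(range(n_sub), n_pd))
        n_perm = n_distinct
    else:
        rng = np.random.default_rng(cfg.seed)

        def _sampled():
            for _ in range(cfg.n_permutations):
                yield rng.permutation(pd_mask)

        perm_iter = _sampled()
        n_perm = cfg.n_permutations

    exceed = {h: np.zeros(iu[0].size) for h in HYPOTHESES}
    for mask in perm_iter:
        t_p, _ = welch_t(x[mask], x[~mask])
        for hyp, sign in (("t1_PD_gt_HC", +1.0), ("t2_HC_gt_PD", -1.0)):
            max_score = score_vec(t_p, sign).max(initial=0.0)
            exceed[hyp] += max_score >= obs_scores[hyp]

    p_fwe = {}
    for hyp in HYPOTHESES:
        if exhaustive:
            p = exceed[hyp] / n_perm            # identity is in the enumeration
        else:
            p = (1.0 + exceed[hyp]) / (1.0 + n_perm)
        p_fwe[hyp] = np.minimum(p, 1.0)

    return EdgeInferenceResult(
        metric=metric, filtering=filtering,
        t=_to_matrix(t_obs, n),
        p_uncorrected={h: _to_matrix(p_unc[h], n) for h in HYPOTHESES},
        scores={h: _to_matrix(obs_scores[h], n) for h in HYPOTHESES},
        p_fwe={h: _to_matrix(p_fwe[h], n) for h in HYPOTHESES},
        config=run_cfg, n_permutations_used=n_perm, exhaustive=exhaustive,
        labels=cohort.labels)


def top_connections_table(result: EdgeInferenceResult, k: int,
                          labels: RegionAtlasLabels | None = None,
                          hypothesis: str = "t1_PD_gt_HC") -> pd.DataFrame:
    """The k most significant connections, in the printed-report layout:
    region pair, uncorrected p, FWE p, t.

    Sorted by uncorrected p ascending; ties broken by larger absolute t.
    """
    labels = labels or result.labels
    if labels is None:
        raise ValueError("region labels required")
    n = len(labels)
    iu = np.triu_indices(n, 1)
    n_edges = iu[0].size
    if k > n_edges:
        logger.warning("k=%d exceeds %d edges; clamping", k, n_edges)
        k = n_edges
    p = result.p_uncorrected[hypothesis][iu]
    t = result.t[iu]
    fwe = result.p_fwe[hypothesis][iu]
    order = np.lexsort((-np.abs(t), p))[:k]
    pretty = lambda i: labels.names[i].replace("_", " ")
    return pd.DataFrame({
        "connection": [f"{pretty(iu[0][e])}↔{pretty(iu[1][e])}" for e in order],
        "uncor_p": p[order],
        "fwe_p": fwe[order],
        "t": t[order],
        "hypothesis": hypothesis,
    })
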