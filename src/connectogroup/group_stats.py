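"""Node-level and whole-brain group comparisons.

Per node (or per global measure): a two-sided Welch t-test of PD vs HC,
Benjamini-Yekutieli (BY) adjustment across the 90 nodes within each
(metric, filtering, measure) family, a direction letter (P: PD mean higher,
H: HC mean higher), pre-correction significance stars, and Cohen's d with a
pooled standard deviation.  Whole-brain comparisons add a 95% normal-
approximation confidence interval for d and the change in effect size under
filtering (delta_d = d_filtered - d_unfiltered).

The filtering-impact taxonomy compares pre-correction significance patterns
between filtering states: the same difference in both states (null effect
of filtering), only before filtering (removal), only after (emergence), or
in neither (never significant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CohortManifest

IMPACT_CATEGORIES = ("null_effect", "removal", "emergence", "never_significant")


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _welch_rows(values: pd.DataFrame, manifest: CohortManifest, by_cols: list[str],
                test: str = "welch") -> pd.DataFrame:
    """Shared machinery: one Welch (or Mann-Whitney) comparison per group of
    ``by_cols``, expecting a 'value' column and subject_id."""
    manifest.require_two_groups()
    groups = manifest.table.set_index("subject_id")["group"]
    rows = []
    for key, sub in values.groupby(by_cols, sort=False):
        sub = sub.set_index("subject_id")["value"]
        g = groups.loc[sub.index]
        x_pd = sub[g == "PD"].to_numpy(dtype=float)
        x_hc = sub[g == "HC"].to_numpy(dtype=float)
        ok_pd, ok_hc = ~np.isnan(x_pd), ~np.isnan(x_hc)
        x_pd, x_hc = x_pd[ok_pd], x_hc[ok_hc]
        n1, n2 = x_pd.size, x_hc.size
        row = dict(zip(by_cols, key if isinstance(key, tuple) else (key,)))
        row.update(n_pd=n1, n_hc=n2, n_excluded=int((~ok_pd).sum() + (~ok_hc).sum()))
        if n1 < 2 or n2 < 2 or (x_pd.var(ddof=1) == 0 and x_hc.var(ddof=1) == 0):
            row.update(t=np.nan, p_uncorrected=np.nan, d=np.nan,
                       direction="", testable=False)
        else:
            if test == "welch":
                t, p = stats.ttest_ind(x_pd, x_hc, equal_var=False)
            elif test == "mannwhitney":
                u, p = stats.mannwhitneyu(x_pd, x_hc, alternative="two-sided")
                t = u - n1 * n2 / 2.0       # centered U plays the role of t
            else:
                raise ValueError(f"unknown test {test!r}")
            sp = np.sqrt(((n1 - 1) * x_pd.var(ddof=1) + (n2 - 1) * x_hc.var(ddof=1))
                         / (n1 + n2 - 2))
            d = (x_pd.mean() - x_hc.mean()) / sp if sp > 0 else np.nan
            row.update(t=float(t), p_uncorrected=float(p), d=float(d),
                       direction="P" if x_pd.mean() > x_hc.mean() else "H",
                       testable=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["stars"] = out["p_uncorrected"].map(_stars)
    return out


def by_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values (valid under arbitrary
    dependence); NaNs pass through and do not count toward the family size."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_by")[1]
    return out


def node_group_tests(node_table: pd.DataFrame, manifest: CohortManifest,
                     test: str = "welch") -> pd.DataFrame:
    """Per-node group comparison with BY correction.

    The BY family is the set of nodes within one (metric, filtering,
    measure) combination — matching correction "across all 90 nodes", never
    pooled across metrics or measures.
    """
    res = _welch_rows(node_table, manifest,
                      ["metric", "filtering", "measure", "node"], test=test)
    if "region" in node_table.columns:
        key = node_table.drop_duplicates("node").set_index("node")["region"]
        res.insert(4, "region", res["node"].map(key))
    res["p_by"] = np.nan
    for _, idx in res.groupby(["metric", "filtering", "measure"]).groups.items():
        res.loc[idx, "p_by"] = by_adjust(res.loc[idx, "p_uncorrected"].to_numpy())
    return res


def _d_ci(d: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for Cohen's d."""
    if not np.isfinite(d):
        return (np.nan, np.nan)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2)))
    z = stats.norm.ppf(0.5 + level / 2)
    return (d - z * se, d + z * se)


def global_group_tests(global_table: pd.DataFrame, manifest: CohortManifest,
                       test: str = "welch") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Whole-brain comparisons plus the effect-size summary.

    Returns ``(comparison_rows, effect_size_summary)``.  The summary pairs
    the filtering states per (metric, measure): d with 95% CI in each state
    and delta_d = d_filtered - d_unfiltered.
    """
    comp = _welch_rows(global_table, manifest, ["metric", "filtering", "measure"],
                       test=test)
    comp["p_by"] = np.nan
    for _, idx in comp.groupby(["metric", "filtering"]).groups.items():
        comp.loc[idx, "p_by"] = by_adjust(comp.loc[idx, "p_uncorrected"].to_numpy())
    ci = comp.apply(lambda r: _d_ci(r["d"], r["n_pd"], r["n_hc"]), axis=1)
    comp["d_ci_low"] = [c[0] for c in ci]
    comp["d_ci_high"] = [c[1] for c in ci]

    wide = comp.pivot_table(index=["metric", "measure"], columns="filtering",
                            values="d", aggfunc="first")
    summary_rows = []
    for (metric, measure), r in wide.iterrows():
        d_u = r.get("unfiltered", np.nan)
        d_f = r.get("filtered", np.nan)
        sub = comp[(comp["metric"] == metric) & (comp["measure"] == measure)]
        n1 = int(sub["n_pd"].iloc[0])
        n2 = int(sub["n_hc"].iloc[0])
        summary_rows.append({
            "metric": metric, "measure": measure, "scope": "global",
            "d_unfiltered": d_u, "d_filtered": d_f, "delta_d": d_f - d_u,
            "d_unfiltered_ci_low": _d_ci(d_u, n1, n2)[0],
            "d_unfiltered_ci_high": _d_ci(d_u, n1, n2)[1],
            "d_filtered_ci_low": _d_ci(d_f, n1, n2)[0],
            "d_filtered_ci_high": _d_ci(d_f, n1, n2)[1],
        })
    return comp, pd.DataFrame(summary_rows)


def filtering_impact(unfiltered: pd.DataFrame, filtered: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Classify each (metric, measure, node) cell by its pre-correction
    significance in the two filtering states.

    significant in both -> null_effect; only unfiltered -> removal; only
    filtered -> emergence; neither -> never_significant.
    """
    keys = ["metric", "measure", "node"]
    u = unfiltered[keys + ["p_uncorrected", "direction"]].rename(
        columns={"p_uncorrected": "p_unfiltered", "direction": "direction_unfiltered"})
    f = filtered[keys + ["p_uncorrected", "direction"]].rename(
        columns={"p_uncorrected": "p_filtered", "direction": "direction_filtered"})
    merged = u.merge(f, on=keys, how="outer", indicator=True)
    missing = merged[merged["_merge"] != "both"]
    if len(missing):
        cells = missing[keys].to_dict("records")
        raise ValueError(f"filtering states cover different grids; missing cells: {cells[:10]}")
    merged = merged.drop(columns="_merge")
    sig_u = merged["p_unfiltered"] < alpha
    sig_f = merged["p_filtered"] < alpha
    merged["category"] = np.select(
        [sig_u & sig_f, sig_u & ~sig_f, ~sig_u & sig_f],
        ["null_effect", "removal", "emergence"], default="never_significant")
    return merged


def significance_report(comparisons: pd.DataFrame, measure: str,
                        only_significant: bool = True) -> pd.DataFrame:
    """Wide significance table for one graph measure.

    One row per node, one column per (metric, filtering) pair in the
    canonical order, cells like ``P**`` / ``H*`` / ``-`` (direction letter
    plus pre-correction stars).  Rows are sorted by each node's best
    uncorrected p.  With ``only_significant`` (the printed-report
    convention) nodes with no starred cell are dropped.
    """
    sub = comparisons[comparisons["measure"] == measure].copy()
    if sub.empty:
        return pd.DataFrame(columns=["node"])
    sub["cell"] = np.where(sub["stars"] != "", sub["direction"] + sub["stars"], "-")
    label_col = "region" if "region" in sub.columns else "node"
    metrics = [m for m in ("SC", "FA", "AD", "RD", "MD") if m in set(sub["metric"])]
    filterings = [f for f in ("unfiltered", "filtered") if f in set(sub["filtering"])]
    col_order = [f"{m}/{'U' if f == 'unfiltered' else 'F'}"
                 for m in metrics for f in filterings]
    sub["column"] = (sub["metric"] + "/" +
                     sub["filtering"].map({"unfiltered": "U", "filtered": "F"}))
    wide = sub.pivot_table(index=label_col, columns="column", values="cell",
                           aggfunc="first").reindex(columns=col_order).fillna("-")
    best = sub.groupby(label_col)["p_uncorrected"].min()
    wide = wide.loc[best.sort_values().index]
    if only_significant:
        wide = wide[(wide != "-").any(axis=1)]
    return wide.reset_index().rename_axis(None, axis=1)
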