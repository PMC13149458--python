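import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from connectogroup.group_stats import (by_adjust, filtering_impact,
                                       global_group_tests, node_group_tests,
                                       significance_report)
from connectogroup.core import CohortManifest


def _manifest(n_hc, n_pd):
    rows = [{"subject_id": f"h{i}", "group": "HC", "sex": "F", "age": 60.0}
            for i in range(n_hc)]
    rows += [{"subject_id": f"p{i}", "group": "PD", "sex": "M", "age": 61.0}
             for i in range(n_pd)]
    return CohortManifest(pd.DataFrame(rows))


def _node_table(values, manifest, metric="SC", filtering="unfiltered",
                measure="strength"):
    """values: (n_subjects, n_nodes) in manifest order."""
    rows = []
    for sid, row in zip(manifest.subject_ids, values):
        for node, v in enumerate(row):
            rows.append({"subject_id": sid, "metric": metric, "filtering": filtering,
                         "measure": measure, "node": node,
                         "region": f"Region_{node + 1:03d}", "value": v})
    return pd.DataFrame(rows)


class TestBYAdjustment:
    def test_closed_form_three_p_values(self):
        # m=3, c(3) = 1 + 1/2 + 1/3; BY_i = p_i * m/i * c(m), then step-up
        adj = by_adjust(np.array([0.001, 0.02, 0.5]))
        c3 = 1 + 0.5 + 1 / 3
        np.testing.assert_allclose(adj, [0.001 * 3 * c3, 0.02 * 3 / 2 * c3,
                                         0.5 * c3], rtol=1e-12)

    def test_monotone_bounded_and_above_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = by_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_nan_passthrough_shrinks_family(self):
        p = np.array([0.01, np.nan, 0.04])
        adj = by_adjust(p)
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]],
                                   multipletests([0.01, 0.04], method="fdr_by")[1])


class TestNodeGroupTests:
    def test_identical_groups_no_stars(self):
        manifest = _manifest(5, 5)
        # the two groups hold identical value multisets => t = 0, p = 1
        group_vals = np.arange(5.0)[:, None] + np.arange(4.0)
        vals = np.vstack([group_vals, group_vals])
        res = node_group_tests(_node_table(vals, manifest), manifest)
        assert (res["stars"] == "").all()
        assert np.allclose(res["p_uncorrected"], 1.0)

    def test_matches_independent_welch_and_by_oracle(self):
        rng = np.random.default_rng(5)
        manifest = _manifest(8, 12)
        vals = rng.normal(size=(20, 10))
        res = node_group_tests(_node_table(vals, manifest), manifest).sort_values("node")
        pd_rows, hc_rows = vals[8:], vals[:8]
        p_ref = []
        for node in range(10):
            t_ref = stats.ttest_ind(pd_rows[:, node], hc_rows[:, node], equal_var=False)
            row = res[res.node == node].iloc[0]
            assert row["t"] == pytest.approx(t_ref.statistic, rel=1e-12)
            assert row["p_uncorrected"] == pytest.approx(t_ref.pvalue, rel=1e-12)
            p_ref.append(t_ref.pvalue)
        np.testing.assert_allclose(res["p_by"].to_numpy(),
                                   multipletests(p_ref, method="fdr_by")[1], rtol=1e-12)

    def test_direction_and_d_are_sign_consistent(self):
        rng = np.random.default_rng(6)
        manifest = _manifest(10, 10)
        vals = rng.normal(size=(20, 6))
        vals[10:, :3] += 2.0          # PD higher on first three nodes
        res = node_group_tests(_node_table(vals, manifest), manifest)
        for _, row in res.iterrows():
            assert (row["d"] > 0) == (row["direction"] == "P")
            assert (row["t"] > 0) == (row["d"] > 0)

    def test_zero_variance_marked_untestable(self):
        manifest = _manifest(3, 3)
        vals = np.ones((6, 2))
        res = node_group_tests(_node_table(vals, manifest), manifest)
        assert (~res["testable"]).all()
        assert res["p_uncorrected"].isna().all()

    def test_stars_reflect_precorrection_thresholds(self):
        manifest = _manifest(20, 20)
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(40, 8))
        vals[20:, 0] += 2.0
        res = node_group_tests(_node_table(vals, manifest), manifest)
        for _, row in res.iterrows():
            p = row["p_uncorrected"]
            expected = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            assert row["stars"] == expected

    def test_mannwhitney_switch(self):
        manifest = _manifest(8, 8)
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(16, 3))
        res = node_group_tests(_node_table(vals, manifest), manifest,
                               test="mannwhitney")
        ref = stats.mannwhitneyu(vals[8:, 0], vals[:8, 0], alternative="two-sided")
        assert res[res.node == 0]["p_uncorrected"].iloc[0] == pytest.approx(ref.pvalue)


class TestGlobalTests:
    def _global_table(self, vals_u, vals_f, manifest, measure="mean_strength"):
        rows = []
        for filt, vals in (("unfiltered", vals_u), ("filtered", vals_f)):
            for sid, v in zip(manifest.subject_ids, vals):
                rows.append({"subject_id": sid, "metric": "SC", "filtering": filt,
                             "measure": measure, "value": v})
        return pd.DataFrame(rows)

    def test_identical_states_give_delta_d_zero(self):
        rng = np.random.default_rng(9)
        manifest = _manifest(10, 10)
        vals = rng.normal(size=20)
        comp, summ = global_group_tests(self._global_table(vals, vals, manifest),
                                        manifest)
        assert summ["delta_d"].iloc[0] == 0.0
        assert summ["d_unfiltered"].iloc[0] == summ["d_filtered"].iloc[0]

    def test_ci_brackets_d_and_is_ordered(self):
        rng = np.random.default_rng(10)
        manifest = _manifest(15, 25)
        vals = rng.normal(size=40)
        vals[15:] += 0.6
        comp, summ = global_group_tests(self._global_table(vals, vals, manifest),
                                        manifest)
        row = comp.iloc[0]
        assert row["d_ci_low"] < row["d"] < row["d_ci_high"]

    def test_nan_subjects_excluded_pairwise(self):
        rng = np.random.default_rng(11)
        manifest = _manifest(6, 6)
        vals = rng.normal(size=12)
        vals[0] = np.nan              # e.g. undefined assortativity
        comp, _ = global_group_tests(
            self._global_table(vals, vals, manifest, measure="assortativity"),
            manifest)
        assert comp["n_excluded"].iloc[0] == 1
        assert comp["n_hc"].iloc[0] == 5

    def test_node_effect_averages_out_at_global_scale(self):
        """A strong effect on a few nodes shrinks when node values are
        averaged into a whole-brain mean."""
        rng = np.random.default_rng(12)
        manifest = _manifest(40, 40)
        n_nodes = 20
        node_vals = rng.normal(size=(80, n_nodes))
        node_vals[40:, :2] += 1.5     # effect on 2 of 20 nodes
        node_d = []
        for node in range(2):
            a, b = node_vals[40:, node], node_vals[:40, node]
            sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            node_d.append((a.mean() - b.mean()) / sp)
        gvals = node_vals.mean(axis=1)
        comp, _ = global_group_tests(self._global_table(gvals, gvals, manifest),
                                     manifest)
        assert abs(comp["d"].iloc[0]) < min(node_d)


class TestFilteringImpact:
    def _comp(self, p_u, p_f):
        rows_u, rows_f = [], []
        for node, (pu, pf) in enumerate(zip(p_u, p_f)):
            base = {"metric": "SC", "measure": "strength", "node": node}
            rows_u.append({**base, "p_uncorrected": pu, "direction": "P"})
            rows_f.append({**base, "p_uncorrected": pf, "direction": "P"})
        return pd.DataFrame(rows_u), pd.DataFrame(rows_f)

    def test_category_definitions(self):
        u, f = self._comp([0.03, 0.03, 0.20, 0.20], [0.04, 0.20, 0.03, 0.30])
        out = filtering_impact(u, f)
        assert out.sort_values("node")["category"].tolist() == [
            "null_effect", "removal", "emergence", "never_significant"]

    def test_pure_function_of_significance_patterns(self):
        u, f = self._comp([0.01, 0.5, 0.04], [0.2, 0.03, 0.04])
        out1 = filtering_impact(u, f)
        out2 = filtering_impact(u.sample(frac=1, random_state=0),
                                f.sample(frac=1, random_state=1))
        m1 = out1.set_index("node")["category"]
        m2 = out2.set_index("node")["category"]
        assert m1.sort_index().equals(m2.sort_index())

    def test_grid_mismatch_raises_with_missing_cells(self):
        u, f = self._comp([0.01, 0.5], [0.2, 0.03])
        with pytest.raises(ValueError, match="missing cells"):
            filtering_impact(u, f.iloc[:1])


class TestSignificanceReport:
    def _comparisons(self):
        rows = []
        for metric in ("SC", "FA"):
            for filt in ("unfiltered", "filtered"):
                for node in range(3):
                    p = 0.004 if (node == 0 and metric == "SC"
                                  and filt == "unfiltered") else 0.6
                    rows.append({
                        "metric": metric, "filtering": filt, "measure": "strength",
                        "node": node, "region": f"R{node}", "p_uncorrected": p,
                        "direction": "P" if node == 0 else "H",
                        "stars": "**" if p < 0.01 else "",
                    })
        return pd.DataFrame(rows)

    def test_cell_grammar_and_placement(self):
        rep = significance_report(self._comparisons(), "strength")
        assert rep.iloc[0]["region"] == "R0"
        assert rep.iloc[0]["SC/U"] == "P**"
        assert rep.iloc[0]["FA/U"] == "-"

    def test_rows_sorted_by_best_p(self):
        rep = significance_report(self._comparisons(), "strength",
                                  only_significant=False)
        assert rep.iloc[0]["region"] == "R0"
        assert len(rep) == 3

    def test_empty_input_gives_empty_table(self):
        rep = significance_report(self._comparisons(), "clustering")
        assert rep.empty
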