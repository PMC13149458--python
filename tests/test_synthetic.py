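import numpy as np
import pytest

from connectogroup.synthetic import (ConfigError, EffectSpec, SimulationConfig,
                                     cohens_d, clique_edges, empirical_effect_size,
                                     scenario_config, sift2_weight_histograms,
                                     simulate_cohort)


class TestConfigValidation:
    def test_effect_members_must_be_upper_triangle(self):
        with pytest.raises(ConfigError, match="upper-triangle"):
            EffectSpec("edge_set", ((3, 1),), 1.0, "SC")

    def test_empty_members_rejected(self):
        with pytest.raises(ConfigError, match="non-empty"):
            EffectSpec("edge_set", (), 1.0, "SC")

    def test_out_of_range_members_rejected_before_sampling(self):
        with pytest.raises(ConfigError, match="atlas"):
            SimulationConfig(n_regions=10, metrics=("SC",),
                             effects=(EffectSpec("edge_set", ((1, 40),), 1.0, "SC"),))

    def test_infeasible_fa_effect_rejected(self):
        with pytest.raises(ConfigError, match="FA"):
            SimulationConfig(n_regions=10, fa_logit_mean=8.0, fa_logit_between_sd=2.0,
                             effects=(EffectSpec("edge_set", ((0, 1),), 40.0, "FA"),))

    def test_group_sizes_must_allow_inference(self):
        with pytest.raises(ConfigError, match="2 subjects"):
            SimulationConfig(n_hc=1, n_pd=5)


class TestGeneratorInvariants:
    @pytest.fixture(scope="class")
    def cohort_trace(self):
        cfg = SimulationConfig(n_hc=6, n_pd=8, n_regions=12, seed=5)
        return simulate_cohort(cfg)

    def test_same_seed_identical_cohorts(self):
        cfg = SimulationConfig(n_hc=3, n_pd=3, n_regions=8, seed=9, metrics=("SC",))
        c1, t1 = simulate_cohort(cfg)
        c2, t2 = simulate_cohort(cfg)
        for key in c1.connectomes:
            np.testing.assert_array_equal(c1.connectomes[key].weights,
                                          c2.connectomes[key].weights)
        for sid in t1.multipliers:
            np.testing.assert_array_equal(t1.multipliers[sid], t2.multipliers[sid])
        assert c1.manifest.table.equals(c2.manifest.table)

    def test_default_cohort_composition_and_demographics(self):
        cfg = SimulationConfig(metrics=("SC",))
        cohort, _ = simulate_cohort(cfg)
        t = cohort.manifest.table
        assert (t["group"] == "HC").sum() == 67
        assert (t["group"] == "PD").sum() == 166
        assert ((t["group"] == "HC") & (t["sex"] == "F")).sum() == 24
        assert ((t["group"] == "PD") & (t["sex"] == "F")).sum() == 61
        ages = t["age"]
        assert 55 < ages.mean() < 67  # published group means are ~59-62 years

    def test_value_ranges_per_metric(self, cohort_trace):
        cohort, _ = cohort_trace
        iu = np.triu_indices(12, 1)
        for (sid, metric, filt), c in cohort.connectomes.items():
            vals = c.weights[iu]
            assert (vals >= 0).all()
            assert np.allclose(c.weights, c.weights.T)
            assert np.all(np.diag(c.weights) == 0)
            if metric == "FA":
                assert (vals > 0).all() and (vals < 1).all()
            else:
                assert (vals > 0).all()

    def test_md_is_tensor_coupled_to_ad_and_rd(self, cohort_trace):
        cohort, _ = cohort_trace
        for sid in cohort.manifest.subject_ids:
            for filt in ("unfiltered", "filtered"):
                ad = cohort.get(sid, "AD", filt).weights
                rd = cohort.get(sid, "RD", filt).weights
                md = cohort.get(sid, "MD", filt).weights
                np.testing.assert_allclose(md, (ad + 2 * rd) / 3, atol=1e-12)

    def test_filtered_sc_equals_multiplier_times_unfiltered(self, cohort_trace):
        cohort, trace = cohort_trace
        iu = np.triu_indices(12, 1)
        for sid in cohort.manifest.subject_ids:
            unf = cohort.get(sid, "SC", "unfiltered").weights
            fil = cohort.get(sid, "SC", "filtered").weights
            m = trace.multipliers[sid]
            assert (m[iu] >= 0).all() and (m[iu] <= 1).all()
            np.testing.assert_allclose(fil[iu], m[iu] * unf[iu], rtol=1e-10)

    def test_filtered_mean_metric_stays_in_range(self, cohort_trace):
        cohort, _ = cohort_trace
        iu = np.triu_indices(12, 1)
        for sid in cohort.manifest.subject_ids:
            unf = cohort.get(sid, "FA", "unfiltered").weights[iu]
            fil = cohort.get(sid, "FA", "filtered").weights[iu]
            assert fil.min() >= 0 and fil.max() < 1
            # pulled toward a weighted mean => dispersion does not explode
            assert fil.std() <= unf.std() * 1.5


class TestEffectSizes:
    def test_identical_groups_give_zero_d(self):
        x = np.tile(np.arange(5.0), (4, 1))
        d = cohens_d(x[:2], x[2:])
        assert np.allclose(d[np.isfinite(d)], 0.0)
        # zero pooled variance -> NaN marker, not an exception
        same = np.ones((4, 3))
        assert np.isnan(cohens_d(same[:2], same[2:])).all()

    def test_unit_shift_gives_d_about_one(self):
        rng = np.random.default_rng(0)
        x_pd = rng.normal(1.0, 1.0, size=(4000, 1))
        x_hc = rng.normal(0.0, 1.0, size=(4000, 1))
        assert abs(cohens_d(x_pd, x_hc)[0] - 1.0) < 0.06

    def test_empirical_effect_size_matches_brute_force(self, tiny_cohort):
        cohort, _ = tiny_cohort
        d = empirical_effect_size(cohort, "SC", "unfiltered")
        x = cohort.edge_matrix("SC", "unfiltered")
        mask = cohort.manifest.group_mask("PD")
        iu = np.triu_indices(10, 1)
        for e in np.random.default_rng(1).choice(iu[0].size, 5, replace=False):
            a, b = x[mask, e], x[~mask, e]
            sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                         / (a.size + b.size - 2))
            expected = (a.mean() - b.mean()) / sp
            assert d[iu[0][e], iu[1][e]] == pytest.approx(expected, rel=1e-12)

    def test_planted_effect_recovered(self):
        cfg = SimulationConfig(n_hc=100, n_pd=100, n_regions=15, seed=3,
                               metrics=("SC",),
                               effects=(EffectSpec("edge_set", ((2, 7),), 1.5, "SC"),))
        cohort, _ = simulate_cohort(cfg)
        d = empirical_effect_size(cohort, "SC", "unfiltered")
        assert abs(d[2, 7] - 1.5) < 0.25
        off_target = d[np.triu_indices(15, 1)]
        assert np.nanmedian(np.abs(off_target)) < 0.3


class TestSift2Histograms:
    def test_groups_similar_under_shared_filtering_model(self):
        cfg = SimulationConfig(n_hc=15, n_pd=15, n_regions=15, seed=2, metrics=("SC",))
        cohort, trace = simulate_cohort(cfg)
        table, ks, _ = sift2_weight_histograms(trace, cohort.manifest,
                                               n_subjects=20, seed=0)
        assert set(table.columns) >= {"bin_left", "bin_right", "HC", "PD"}
        assert ks < 0.1  # filtering is not biased by disease status

    def test_degenerate_all_one_multipliers(self, toy_manifest):
        from connectogroup.synthetic import FilteringTrace
        mult = {sid: np.ones((5, 5)) - np.eye(5) for sid in toy_manifest.subject_ids}
        for m in mult.values():
            np.fill_diagonal(m, 0)
        trace = FilteringTrace(mult)
        table, ks, _ = sift2_weight_histograms(trace, toy_manifest, n_subjects=8, seed=0)
        assert ks == 0.0

    def test_group_separation_increases_ks(self):
        rng = np.random.default_rng(4)
        cfg = SimulationConfig(n_hc=15, n_pd=15, n_regions=15, seed=2, metrics=("SC",))
        cohort, trace = simulate_cohort(cfg)
        _, ks_null, _ = sift2_weight_histograms(trace, cohort.manifest, 20, seed=0)
        biased = {}
        for sid in trace.multipliers:
            m = trace.multipliers[sid].copy()
            if sid.startswith("pd"):
                m = np.clip(m * 0.55, 0, 1)  # constructed group-dependent filtering
            biased[sid] = m
        from connectogroup.synthetic import FilteringTrace
        _, ks_biased, p = sift2_weight_histograms(FilteringTrace(biased),
                                                  cohort.manifest, 20, seed=0)
        assert ks_biased > ks_null
        assert p < 0.01

    def test_insufficient_subjects_error_lists_availability(self, toy_manifest):
        from connectogroup.synthetic import FilteringTrace
        trace = FilteringTrace({"s0": np.zeros((4, 4))})
        with pytest.raises(ValueError, match="available"):
            sift2_weight_histograms(trace, toy_manifest, n_subjects=8, seed=0)


class TestScenarios:
    def test_clique_edges_enumeration(self):
        assert clique_edges([3, 1, 5]) == ((1, 3), (1, 5), (3, 5))

    @pytest.mark.parametrize("name", ["null", "edge_effect", "node_effect",
                                      "removal", "emergence"])
    def test_presets_are_valid_configs(self, name):
        cfg = scenario_config(name, seed=1, n_regions=20, n_hc=5, n_pd=5)
        cohort, _ = simulate_cohort(cfg)
        assert len(cohort.manifest) == 10

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigError):
            scenario_config("bogus")
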