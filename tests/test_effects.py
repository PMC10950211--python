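"""Design suite: exact identities, planted-effect recovery, matching and
placebo contracts."""

import numpy as np
import pandas as pd
import pytest

import epivote as ev
from epivote.simulate import (
    SimulationConfig,
    build_truth,
    generate_elections,
    generate_municipalities,
)


def make_world(seed=0, n=400, **kwargs):
    cfg = SimulationConfig(
        n_municipalities=n, n_counties=kwargs.pop("n_counties", 20),
        seed=seed, **kwargs,
    )
    pop, cov, counties = generate_municipalities(cfg)
    truth = build_truth(cfg, cov, counties)
    panel = generate_elections(cov, truth, cfg)
    transform = ev.PrevalenceTransform("decile", truth.true_decile.astype(float))
    return cfg, cov.drop(columns="_urbanicity"), truth, panel, transform


class TestDesignMatrix:
    def test_complete_covariates_preserve_rows(self, sim400, dm400):
        n_incumbents = int(sim400.panel["incumbent_running"].sum())
        assert len(dm400) == n_incumbents

    def test_zero_share_logged_with_offset_and_kept(self):
        cfg, cov, truth, panel, tr = make_world(seed=21, n=60, n_counties=5)
        cov = cov.copy()
        cov.loc[cov.index[0], "share_immigrants"] = 0.0
        with pytest.warns(UserWarning, match="offset"):
            dm = ev.build_design_matrix(panel, cov, tr)
        assert cov["municipality_id"].iloc[0] not in dm.index or np.isfinite(
            dm["log_share_immigrants"]
        ).all()
        assert len(dm) == int(panel["incumbent_running"].sum())

    def test_column_order_stable_across_runs(self, sim400):
        tr = ev.PrevalenceTransform(
            "decile", sim400.truth.true_decile.astype(float)
        )
        cov = sim400.covariates.drop(columns="_urbanicity")
        a = ev.build_design_matrix(sim400.panel, cov, tr)
        b = ev.build_design_matrix(sim400.panel, cov, tr)
        assert list(a.columns) == list(b.columns)
        pd.testing.assert_frame_equal(a, b)


class TestLaggedDV:
    def test_noiseless_panel_recovers_planted_effect_exactly(self):
        cfg, cov, truth, panel, tr = make_world(
            seed=22, n=300, noise_sd=0.0, county_sd=2.0
        )
        dm = ev.build_design_matrix(panel, cov, tr)
        est = ev.fit_lagged_dv(dm)
        assert est.coefficient == pytest.approx(cfg.beta_true, abs=1e-8)
        assert est.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_frisch_waugh_dummy_vs_demeaned_identity(self, dm400):
        a = ev.fit_lagged_dv(dm400, fe="dummies")
        b = ev.fit_lagged_dv(dm400, fe="demean")
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-8)

    def test_singular_design_names_collinear_column(self, dm400):
        dm = dm400.copy()
        dm.attrs.update(dm400.attrs)
        dm["dup"] = dm["turnout_2014"]
        with pytest.raises(ev.EstimationError, match="dup"):
            ev.fit_lagged_dv(dm)

    def test_estimate_metadata_consistent(self, dm400):
        est = ev.fit_lagged_dv(dm400)
        assert est.ci_low <= est.coefficient <= est.ci_high
        assert est.n_obs == len(dm400)
        assert 0 <= est.p_value <= 1


class TestPredictions:
    def test_linear_decile_contrast_is_nine_beta(self, dm400):
        est = ev.fit_lagged_dv(dm400)
        pred = ev.predict_at_levels(est, [1, 10])
        assert pred.attrs["top_bottom_difference"] == pytest.approx(
            9 * est.coefficient, abs=1e-10
        )

    def test_prediction_at_mean_equals_mean_fitted(self, dm400):
        est = ev.fit_lagged_dv(dm400)
        mean_cov = float(dm400["cov"].mean())
        pred = ev.predict_at_levels(est, [mean_cov])
        assert pred["predicted"].iloc[0] == pytest.approx(
            float(est.model.fittedvalues.mean()), abs=1e-8
        )

    def test_interval_width_grows_away_from_mean(self, dm400):
        est = ev.fit_lagged_dv(dm400)
        mean_cov = float(dm400["cov"].mean())
        pred = ev.predict_at_levels(est, [mean_cov, mean_cov + 4, mean_cov + 8])
        widths = (pred["ci_high"] - pred["ci_low"]).to_numpy()
        assert widths[0] < widths[1] < widths[2]


class TestFirstDifference:
    def test_level_shift_invariance(self):
        cfg, cov, truth, panel, tr = make_world(seed=23, n=300)
        est = ev.fit_first_difference(panel, cov, tr)
        shifted = panel.copy()
        shifted["share_2014"] = np.clip(shifted["share_2014"] + 0, 0, 100)
        shifted[["share_2014", "share_2020"]] = shifted[
            ["share_2014", "share_2020"]
        ] + 0.0
        shifted["share_2014"] += 3.0
        shifted["share_2020"] += 3.0
        est2 = ev.fit_first_difference(shifted, cov, tr)
        assert est.coefficient == pytest.approx(est2.coefficient, abs=1e-8)

    def test_unit_lag_world_matches_lagged_dv_in_expectation(self):
        diffs = []
        for seed in range(6):
            cfg, cov, truth, panel, tr = make_world(
                seed=300 + seed, n=800, eta_lag=1.0, n_counties=20
            )
            fd = ev.fit_first_difference(panel, cov, tr)
            dm = ev.build_design_matrix(panel, cov, tr)
            ld = ev.fit_lagged_dv(dm)
            diffs.append(fd.coefficient - ld.coefficient)
        assert abs(np.mean(diffs)) < 0.1


class TestTreatmentAndDiD:
    def test_top_two_quartiles_treated(self):
        vals = pd.Series(
            np.linspace(0, 1, 100), index=[f"M{i:03d}" for i in range(100)]
        )
        t = ev.define_treatment(vals)
        assert t.sum() == 50
        assert vals[t].min() > vals[~t].max()

    def test_degenerate_all_equal_raises(self):
        vals = pd.Series(0.0, index=[f"M{i}" for i in range(40)])
        with pytest.raises(ev.ConfigurationError):
            ev.define_treatment(vals)

    def test_four_cell_arithmetic(self):
        panel = pd.DataFrame(
            {
                "municipality_id": ["T1", "T2", "C1", "C2"],
                "share_2014": [70.0, 70.0, 70.0, 70.0],
                "share_2020": [74.0, 74.0, 72.0, 72.0],
            }
        )
        treated = pd.Series(
            [True, True, False, False], index=["T1", "T2", "C1", "C2"]
        )
        assert ev.did_naive(panel, treated) == pytest.approx(2.0, abs=1e-12)

    def test_naive_equals_fe_regression_without_covariates(self):
        rng = np.random.default_rng(8)
        n = 200
        ids = [f"M{i:03d}" for i in range(n)]
        panel = pd.DataFrame(
            {
                "municipality_id": ids,
                "share_2014": rng.uniform(30, 90, n),
                "share_2020": rng.uniform(30, 90, n),
            }
        )
        treated = pd.Series(rng.random(n) < 0.4, index=ids)
        naive = ev.did_naive(panel, treated)
        fe = ev.fit_did(panel, treated, with_fe=True, restrict_incumbents=False)
        assert fe.coefficient == pytest.approx(naive, abs=1e-10)

    def test_null_world_did_centred_at_zero(self):
        ests = []
        for seed in range(8):
            cfg, cov, truth, panel, tr = make_world(
                seed=500 + seed, n=600, beta_true=0.0
            )
            treated = ev.define_treatment(truth.true_prevalence.sort_index())
            ests.append(ev.fit_did(panel, treated).coefficient)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * se + 1e-9


class TestMatching:
    def test_identical_covariates_match_everyone_at_zero_distance(self):
        n = 40
        ids = [f"M{i:02d}" for i in range(n)]
        rng = np.random.default_rng(1)
        dm = pd.DataFrame(
            {
                "y": rng.normal(70, 5, n),
                "cov": rng.integers(1, 11, n).astype(float),
                "lag": 60.0,
                "x1": 1.0,
                "county_id": "C0",
            },
            index=pd.Index(ids, name="municipality_id"),
        )
        dm.attrs["cov_cols"] = ["cov"]
        treated = pd.Series([True] * 20 + [False] * 20, index=ids)
        m = ev.propensity_match(dm, treated, seed=3)
        assert len(m.pairs) == 20
        gaps = (m.pairs["ps_treated"] - m.pairs["ps_control"]).abs()
        assert (gaps < 1e-12).all()

    def test_separated_groups_produce_no_pairs(self):
        # propensity scores constructed directly: all gaps exceed the caliper
        ids = [f"M{i:02d}" for i in range(20)]
        ps = pd.Series([0.9] * 10 + [0.1] * 10, index=ids)
        treated = pd.Series([True] * 10 + [False] * 10, index=ids)
        from epivote.effects import _greedy_caliper_match

        pairs, discarded = _greedy_caliper_match(
            ps, treated, caliper=0.025, rng=np.random.default_rng(0)
        )
        assert len(pairs) == 0 and discarded == 10

    def test_caliper_respected_and_matching_deterministic(self, sim400, dm400):
        treated = ev.define_treatment(sim400.truth.true_prevalence.sort_index())
        treated = treated.reindex(dm400.index)
        a = ev.propensity_match(dm400, treated, seed=9)
        b = ev.propensity_match(dm400, treated, seed=9)
        assert a.pairs.to_csv() == b.pairs.to_csv()
        gaps = (a.pairs["ps_treated"] - a.pairs["ps_control"]).abs()
        assert (gaps <= 0.025 + 1e-12).all()
        # one-to-one without replacement
        assert a.pairs["control_id"].is_unique
        assert a.pairs["treated_id"].is_unique

    def test_balance_improves_on_confounded_world(self):
        cfg, cov, truth, panel, tr = make_world(
            seed=31, n=1500, confounding_strength=1.0
        )
        dm = ev.build_design_matrix(panel, cov, tr)
        treated = ev.define_treatment(truth.true_prevalence.sort_index()).reindex(
            dm.index
        )
        pre = ev.standardized_mean_differences(dm, treated)
        m = ev.propensity_match(dm, treated, seed=5)
        sub = dm.loc[dm.index.intersection(m.matched_ids)]
        sub.attrs.update(dm.attrs)
        post = ev.standardized_mean_differences(sub, treated.reindex(sub.index))
        assert post.mean() < pre.mean()
        assert post.max() < pre.max()

    def test_matched_refit_recovers_effect_direction(self, sim400, dm400):
        treated = ev.define_treatment(sim400.truth.true_prevalence.sort_index())
        m = ev.propensity_match(dm400, treated.reindex(dm400.index), seed=2)
        est = ev.matched_estimate(dm400, m)
        assert est.design == "psm"
        assert est.n_obs == 2 * len(m.pairs)


class TestPlaceboAndTrends:
    def test_missing_2008_column_raises(self, sim400):
        panel = sim400.panel.copy()
        panel["share_2008"] = np.nan
        cov = sim400.covariates.drop(columns="_urbanicity")
        tr = ev.PrevalenceTransform("decile", sim400.truth.true_decile.astype(float))
        with pytest.raises(ev.EstimationError, match="2008"):
            ev.placebo_test(panel, cov, tr)

    def test_small_subsample_warns(self):
        cfg, cov, truth, panel, tr = make_world(
            seed=33, n=300, share_2008_fraction=0.2
        )
        with pytest.warns(UserWarning, match="placebo subsample"):
            ev.placebo_test(panel, cov, tr, min_n=1000)

    def test_planted_2014_leak_detected_by_placebo(self):
        hits = 0
        for seed in range(5):
            cfg, cov, truth, panel, tr = make_world(
                seed=600 + seed, n=1200, beta_2014=1.2, share_2008_fraction=0.8
            )
            est = ev.placebo_test(panel, cov, tr)
            hits += est.p_value < 0.05
        assert hits >= 4  # strong leak: detected in nearly every replicate

    def test_identical_pretrends_give_null_contrast(self):
        n = 100
        ids = [f"M{i:03d}" for i in range(n)]
        panel = pd.DataFrame(
            {
                "municipality_id": ids,
                "share_2008": 60.0,
                "share_2014": 65.0,
                "share_2020": 70.0,
            }
        )
        treated = pd.Series([True] * 50 + [False] * 50, index=ids)
        est, means = ev.parallel_trends(panel, treated, restrict_incumbents=False)
        assert est.coefficient == pytest.approx(0.0, abs=1e-10)
        assert set(means["group"]) == {"treated", "control"}

    def test_planted_differential_pretrend_recovered(self):
        ests = []
        for seed in range(5):
            cfg, cov, truth, panel, tr = make_world(
                seed=700 + seed, n=1500, pre_trend_effect=2.0,
                share_2008_fraction=1.0,
            )
            treated = (truth.true_decile > 5).rename("treated").sort_index()
            est, _ = ev.parallel_trends(panel, treated)
            ests.append(est.coefficient)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(2.0, abs=max(4 * mc_se, 0.3))

    def test_group_means_match_direct_averages(self, sim400):
        treated = ev.define_treatment(sim400.truth.true_prevalence.sort_index())
        est, means = ev.parallel_trends(sim400.panel, treated)
        p = sim400.panel.set_index("municipality_id")
        p = p[p["incumbent_running"]]
        t = treated.reindex(p.index)
        both = p[["share_2008", "share_2014"]].notna().all(axis=1) & t.notna()
        p, t = p[both], t[both].astype(bool)
        direct = p.loc[t, "share_2014"].mean()
        got = means.query("group == 'treated' and year == 2014")["mean_share"].iloc[0]
        assert got == pytest.approx(direct, abs=1e-12)


class TestAnxiety:
    def _resp(self, rows):
        return pd.DataFrame(
            rows, columns=["county_id", "size_category", "item_nervous", "item_worry"]
        )

    def test_scale_endpoints(self):
        cells = ev.aggregate_anxiety(
            self._resp(
                [
                    ("C0", "S1", "never", "never"),
                    ("C1", "S1", "almost every day", "almost every day"),
                ]
            )
        )
        idx = cells.set_index("county_id")["anxiety_mean"]
        assert idx["C0"] == 0.0
        assert idx["C1"] == 1.0

    def test_mixed_items_average_to_two_thirds(self):
        cells = ev.aggregate_anxiety(
            self._resp([("C0", "S1", "several days", "almost every day")])
        )
        assert cells["anxiety_mean"].iloc[0] == pytest.approx(2 / 3)

    def test_unknown_label_raises_schema_error(self):
        with pytest.raises(ev.SchemaError, match="unknown response"):
            ev.aggregate_anxiety(self._resp([("C0", "S1", "sometimes", "never")]))

    def test_cell_counts(self):
        cells = ev.aggregate_anxiety(
            self._resp(
                [
                    ("C0", "S1", "never", "never"),
                    ("C0", "S1", "almost every day", "never"),
                    ("C0", "S2", "never", "several days"),
                ]
            )
        )
        counts = cells.set_index(["county_id", "size_category"])["n_respondents"]
        assert counts[("C0", "S1")] == 2 and counts[("C0", "S2")] == 1


class TestInteractions:
    def test_constant_moderator_raises(self, dm400):
        mod = pd.Series(1.0, index=dm400.index)
        with pytest.raises(ev.EstimationError, match="constant"):
            ev.fit_interaction(dm400, mod)

    def test_planted_moderation_recovered(self):
        coefs = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_municipalities=1500, n_counties=20, seed=800 + seed,
                beta_moderation=0.4,
            )
            pop, cov, counties = generate_municipalities(cfg)
            truth = build_truth(cfg, cov, counties)
            moderator = pd.Series(
                np.random.default_rng(seed).normal(size=len(cov)),
                index=cov["municipality_id"],
            )
            panel = generate_elections(
                cov, truth, cfg, moderator_values=moderator
            )
            tr = ev.PrevalenceTransform("decile", truth.true_decile.astype(float))
            dm = ev.build_design_matrix(
                panel, cov.drop(columns="_urbanicity"), tr
            )
            ir = ev.fit_interaction(dm, moderator, "planted")
            coefs.append(ir.estimate.coefficient)
        mc_se = np.std(coefs, ddof=1) / np.sqrt(len(coefs))
        assert np.mean(coefs) == pytest.approx(0.4, abs=max(4 * mc_se, 0.1))

    def test_affiliation_slopes_indistinguishable_under_shared_effect(self, sim400, dm400):
        aff = sim400.panel.set_index("municipality_id")["affiliation"]
        ir = ev.fit_interaction(dm400, aff, "affiliation")
        assert set(ir.marginal_effects["moderator_value"]) == {"left", "right", "other"}
        # no planted heterogeneity: interaction terms not significant
        assert ir.estimate.p_value > 0.01

    def test_marginal_effect_grid_has_requested_points(self, sim400, dm400):
        merged = sim400.covariates.merge(
            sim400.survey_cells, on=["county_id", "size_category"], how="left"
        ).set_index("municipality_id")
        clu = merged["county_id"].astype(str) + "_" + merged["size_category"].astype(str)
        ir = ev.fit_interaction(
            dm400, merged["anxiety_mean"], "anxiety", cluster=clu, n_points=20
        )
        assert len(ir.marginal_effects) == 20
        assert (ir.marginal_effects["se"] > 0).all()
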