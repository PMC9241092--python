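import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import normgap as ng
from normgap.core import STRATA, STRATUM_LABELS, ConfigurationError, ParameterisationError


class TestConfigValidation:
    def test_zero_clusters_rejected(self):
        with pytest.raises(ConfigurationError):
            ng.generate_survey(ng.GeneratorConfig(n_clusters=0))

    def test_shares_must_sum_to_one(self):
        cfg = ng.GeneratorConfig(gender_age_shares=(0.2, 0.2, 0.2, 0.2, 0.1, 0.2))
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_shares_must_have_six_entries(self):
        with pytest.raises(ConfigurationError):
            ng.GeneratorConfig(gender_age_shares=(0.5, 0.5)).validate()

    def test_negative_share_rejected(self):
        with pytest.raises(ConfigurationError):
            ng.GeneratorConfig(gender_age_shares=(-0.1, 0.3, 0.2, 0.2, 0.2, 0.2)).validate()

    def test_unknown_pathway_key_rejected(self):
        with pytest.raises(ConfigurationError):
            ng.GeneratorConfig(true_log_rr_per_10pp={"XX": 0.1}).validate()

    def test_unknown_modifier_stratum_rejected(self):
        with pytest.raises(ConfigurationError):
            ng.GeneratorConfig(effect_modifiers={"female_99": 0.1}).validate()

    def test_baseline_risk_bounds(self):
        with pytest.raises(ConfigurationError):
            ng.GeneratorConfig(baseline_hiv_risk=1.5).validate()


class TestGeneration:
    def test_determinism_bit_identical(self, small_survey):
        cfg, dataset, _ = small_survey
        again, _ = ng.generate_survey(cfg)
        pd.testing.assert_frame_equal(dataset.respondents, again.respondents)

    def test_structural_invariants(self, small_survey):
        _, dataset, _ = small_survey
        dataset.validate()

    def test_realised_distribution_matches_shares(self):
        cfg = ng.GeneratorConfig(n_clusters=400, households_per_cluster=10, seed=11)
        dataset, _ = ng.generate_survey(cfg)
        assert dataset.n > 9000
        counts = ng.compute_distribution(dataset).counts.to_numpy()
        expected = np.asarray(cfg.gender_age_shares) * counts.sum()
        stat = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(stat, df=5)
        assert p > 0.001

    def test_null_effect_gives_independence(self):
        cfg = ng.GeneratorConfig(n_clusters=200, households_per_cluster=8, seed=5,
                                 true_log_rr_per_10pp=0.0)
        dataset, _ = ng.generate_survey(cfg)
        df = dataset.respondents
        ados = df[df["age_group"].isin(["15-19", "20-24"]) & df["hiv_positive"].notna()]
        prev = ados.groupby("cluster_id")["hiv_positive"].mean().astype(float)
        disc = (
            ng.compute_discordance(dataset, 1)
            .frame.groupby("cluster_id")["discordance"]
            .mean()
        )
        joined = pd.concat([prev, disc], axis=1).dropna()
        r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(cfg.n_clusters)

    def test_excessive_risk_names_stratum(self):
        cfg = ng.GeneratorConfig(n_clusters=40, seed=3, baseline_hiv_risk=0.5,
                                 true_log_rr_per_10pp=0.5)
        with pytest.raises(ParameterisationError) as err:
            ng.generate_survey(cfg)
        assert any(label in str(err.value) for label in STRATUM_LABELS)

    def test_truth_records_parameters(self, small_survey):
        cfg, _, truth = small_survey
        assert truth.seed == cfg.seed
        assert truth.true_log_rr_per_10pp["FF"] == pytest.approx(np.log(1.27))
        assert set(truth.cluster_norms["gender"]) == {"female", "male"}

    def test_homogeneous_effect_strata_agree(self):
        # with no modifiers, the two adolescent strata carry the same slope
        cfg = ng.GeneratorConfig(n_clusters=400, households_per_cluster=10, seed=13,
                                 true_log_rr_per_10pp={"FF": 0.2}, baseline_hiv_risk=0.08,
                                 cluster_sd=0.8)
        dataset, _ = ng.generate_survey(cfg)
        at = ng.attach_cluster_context(ng.filter_eligible(dataset), min_adults_per_cluster=3)
        df = at.respondents
        slopes = {}
        ses = {}
        import statsmodels.api as sm

        for grp in ("15-19", "20-24"):
            sub = df[(df["gender"] == "female") & (df["age_group"] == grp)
                     & df["hiv_positive"].notna()].dropna(subset=["disc_female"])
            y = sub["hiv_positive"].astype(bool).to_numpy(dtype=float)
            X = sm.add_constant(sub["disc_female"].astype(float).to_numpy())
            res = sm.GLM(y, X, family=sm.families.Poisson(),
                         var_weights=sub["design_weight"].to_numpy()).fit()
            slopes[grp], ses[grp] = res.params[1], res.bse[1]
        z = abs(slopes["15-19"] - slopes["20-24"]) / np.hypot(ses["15-19"], ses["20-24"])
        assert z < 4.0


class TestRecoveryOracle:
    def test_irls_matches_direct_maximiser_and_covers_truth(self):
        """Correctly specified weighted Poisson fit recovers the generative
        slope; the IRLS solution equals a direct numerical maximiser of the
        weighted log-likelihood."""
        beta_true = float(np.log(1.27))
        cfg = ng.GeneratorConfig(n_clusters=300, households_per_cluster=8, seed=1,
                                 true_log_rr_per_10pp={"FF": beta_true},
                                 baseline_hiv_risk=0.08)
        dataset, _ = ng.generate_survey(cfg)
        at = ng.attach_cluster_context(ng.filter_eligible(dataset), min_adults_per_cluster=3)
        spec = ng.ModelSpec("female", "female", ())
        fit = ng.fit_weighted_poisson(at, spec, 3)
        assert fit.converged
        ci = fit.conf_int().loc["discordance"]
        assert ci["lower"] <= beta_true <= ci["upper"]

        design = ng.models.build_design(at, spec, 3)
        y, X, w = design.y, design.X.to_numpy(), design.weights

        def negll(b):
            mu = np.exp(X @ b)
            return -np.sum(w * (y * (X @ b) - mu))

        res = optimize.minimize(negll, np.zeros(X.shape[1]), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        np.testing.assert_allclose(res.x, fit.params.to_numpy(), atol=5e-6)


class TestPresets:
    def test_at_least_five_presets_with_extremes(self):
        ids = {p.preset_id for p in ng.builtin_presets()}
        assert len(ids) >= 5
        assert {"ZAMBIA", "MAI06", "HAI12", "SEN10", "LES09"} <= ids

    def test_printed_male_shares(self):
        assert ng.get_preset("ZAMBIA").male_share_total == pytest.approx(0.453)
        assert ng.get_preset("MAI06").male_share_total == pytest.approx(0.208)
        assert ng.get_preset("HAI12").male_share_total == pytest.approx(0.412)

    def test_printed_adolescent_shares(self):
        assert ng.get_preset("SEN10").female_adolescent_share == pytest.approx(0.050)
        assert ng.get_preset("LES09").male_adolescent_share == pytest.approx(0.420)

    @pytest.mark.parametrize("preset_id", [p.preset_id for p in ng.builtin_presets()])
    def test_proportions_consistent_with_marginals(self, preset_id):
        preset = ng.get_preset(preset_id)
        props = preset.proportions()
        assert props.sum() == pytest.approx(1.0, abs=1e-9)
        assert props.loc["male"].sum() == pytest.approx(preset.male_share_total, abs=1e-9)
        female = props.loc["female"]
        adol = (female["15-19"] + female["20-24"]) / female.sum()
        assert adol == pytest.approx(preset.female_adolescent_share, abs=1e-9)

    def test_unknown_preset_raises(self):
        with pytest.raises(ConfigurationError):
            ng.get_preset("NOPE99")

    def test_target_counts_sum_exactly(self):
        target = ng.get_preset("MAI06").target_counts(10007)
        assert target.total == 10007


class TestMissingnessApplication:
    def test_scenario_one_is_identity(self, small_survey):
        _, dataset, _ = small_survey
        out = ng.apply_missingness_scenario(dataset, 1)
        pd.testing.assert_frame_equal(out.respondents, dataset.respondents)

    def test_scenario_five_blanks_partner_age_and_alcohol(self, small_survey):
        _, dataset, _ = small_survey
        out = ng.apply_missingness_scenario(dataset, 5)
        assert out.respondents["partner_age_diff_large"].isna().all()
        assert out.respondents["alcohol_before_sex"].isna().all()
        assert out.respondents["ipv_history"].notna().sum() > 0
        pd.testing.assert_series_equal(
            out.respondents["education"], dataset.respondents["education"]
        )

    def test_idempotent(self, small_survey):
        _, dataset, _ = small_survey
        once = ng.apply_missingness_scenario(dataset, 4)
        twice = ng.apply_missingness_scenario(once, 4)
        pd.testing.assert_frame_equal(once.respondents, twice.respondents)

    def test_unknown_scenario_raises(self, small_survey):
        _, dataset, _ = small_survey
        with pytest.raises(ConfigurationError):
            ng.apply_missingness_scenario(dataset, 9)
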