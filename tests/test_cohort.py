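import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import normgap as ng
from normgap.cohort import GenderAgeDistribution, SurveyMetadata
from normgap.core import STRATA, DataError
from conftest import toy_dataset


class TestFilterEligible:
    def test_enumerated_six_records(self):
        # two active+tested adolescents, one active+untested, one inactive,
        # two adults -> 2 adolescents + 2 adults survive
        ds = toy_dataset(
            [
                {"age_years": 16, "ever_had_sex": True, "hiv_tested": True, "hiv_positive": False},
                {"age_years": 22, "ever_had_sex": True, "hiv_tested": True, "hiv_positive": True},
                {"age_years": 17, "ever_had_sex": True, "hiv_tested": False},
                {"age_years": 18, "ever_had_sex": False},
                {"age_years": 30},
                {"age_years": 45},
            ]
        )
        out = ng.filter_eligible(ds)
        assert out.n == 4
        assert (out.respondents["age_group"] == "25-49").sum() == 2
        removed = out.metadata["eligibility_removed"]
        assert removed == {"adolescent_no_sexual_history": 1, "adolescent_no_hiv_test": 1}

    def test_adults_only_identity(self):
        ds = toy_dataset([{"age_years": a} for a in (25, 30, 49)])
        with pytest.warns(UserWarning):
            out = ng.filter_eligible(ds)
        pd.testing.assert_frame_equal(
            out.respondents.reset_index(drop=True), ds.respondents.reset_index(drop=True)
        )

    def test_missing_hiv_test_counts_under_test_rule(self):
        ds = toy_dataset([{"age_years": 16, "ever_had_sex": True, "hiv_tested": None}])
        with pytest.warns(UserWarning):
            out = ng.filter_eligible(ds)
        assert out.n == 0
        assert out.metadata["eligibility_removed"]["adolescent_no_hiv_test"] == 1

    def test_idempotent_and_bookkeeping_sums(self, small_survey):
        _, dataset, _ = small_survey
        once = ng.filter_eligible(dataset)
        twice = ng.filter_eligible(once)
        pd.testing.assert_frame_equal(once.respondents, twice.respondents)
        removed = once.metadata["eligibility_removed"]
        assert sum(removed.values()) == dataset.n - once.n
        assert sum(twice.metadata["eligibility_removed"].values()) == 0


class TestComputeDistribution:
    def test_direct_counting(self):
        ds = toy_dataset(
            [{"age_years": 16}, {"age_years": 17}, {"age_years": 18},
             {"age_years": 40, "gender": "male"}]
        )
        dist = ng.compute_distribution(ds)
        props = dist.proportions
        assert props.loc[("female", "15-19")] == pytest.approx(0.75)
        assert props.loc[("male", "25-49")] == pytest.approx(0.25)
        assert props.drop([("female", "15-19"), ("male", "25-49")]).eq(0).all()

    def test_self_concatenation_doubles_counts(self, small_survey):
        _, dataset, _ = small_survey
        doubled = ng.SurveyDataset(
            pd.concat([dataset.respondents, dataset.respondents], ignore_index=True),
            dict(dataset.metadata),
        )
        d1, d2 = ng.compute_distribution(dataset), ng.compute_distribution(doubled)
        pd.testing.assert_series_equal(d2.counts, d1.counts * 2)
        pd.testing.assert_series_equal(d2.proportions, d1.proportions)

    def test_empty_dataset_raises(self):
        ds = toy_dataset([{"age_years": 30}])
        ds.respondents = ds.respondents.iloc[0:0]
        with pytest.raises(DataError):
            ng.compute_distribution(ds)

    def test_generated_preset_marginal(self):
        preset = ng.get_preset("MAI06")
        cfg = ng.GeneratorConfig(
            n_clusters=500, households_per_cluster=10, respondents_per_household=4.0,
            gender_age_shares=tuple(preset.proportions()), seed=21,
        )
        dataset, _ = ng.generate_survey(cfg)
        assert dataset.n >= 20000
        share = ng.compute_distribution(dataset).male_share()
        assert abs(share - 0.208) < 0.01


class TestDistributionType:
    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
        total=st.integers(1, 5000),
    )
    @settings(max_examples=60, deadline=None)
    def test_from_proportions_rounding(self, raw, total):
        p = np.asarray(raw) / np.sum(raw)
        dist = GenderAgeDistribution.from_proportions(
            pd.Series(p, index=pd.MultiIndex.from_tuples(STRATA)), total
        )
        assert dist.total == total
        assert (np.abs(dist.counts.to_numpy() - p * total) <= 1.0).all()

    def test_dissimilarity_utility(self):
        base = GenderAgeDistribution.from_proportions(
            pd.Series([1 / 6] * 6, index=pd.MultiIndex.from_tuples(STRATA)), 600
        )
        same = GenderAgeDistribution(base.counts.copy())
        assert not ng.distributions_dissimilar(base, same)
        shifted = base.counts.copy()
        shifted.iloc[0] = 130  # > 20% relative difference in one stratum
        shifted.iloc[5] = 70
        assert ng.distributions_dissimilar(base, GenderAgeDistribution(shifted))


class TestDiscordance:
    @staticmethod
    def _cluster(att, beh, n=20, cluster=0, gender="female", weight=1.0):
        rows = []
        for i in range(n):
            rows.append(
                {
                    "cluster_id": cluster,
                    "gender": gender,
                    "age_years": 30,
                    "design_weight": weight,
                    "attitude_disapproves_premarital": i < round(att * n),
                    "behaviour_premarital": i < round(beh * n),
                }
            )
        return rows

    def test_perfect_concordance_zero(self):
        ds = toy_dataset(self._cluster(att=1.0, beh=0.0))
        table = ng.compute_discordance(ds, 5)
        assert table.frame.loc[0, "discordance"] == pytest.approx(0.0)

    def test_hand_computed_gap(self):
        # disapproval 0.9, behaviour 0.5 -> 0.5 - (1 - 0.9) = 0.4 -> 4.0 per 10pp
        ds = toy_dataset(self._cluster(att=0.9, beh=0.5))
        table = ng.compute_discordance(ds, 5)
        row = table.frame.iloc[0]
        assert row["attitude_prop"] == pytest.approx(0.9)
        assert row["behaviour_prop"] == pytest.approx(0.5)
        assert row["discordance"] == pytest.approx(4.0)

    def test_weight_rescaling_invariance(self):
        a = toy_dataset(self._cluster(att=0.7, beh=0.4, weight=1.0))
        b = toy_dataset(self._cluster(att=0.7, beh=0.4, weight=2.0))
        va = ng.compute_discordance(a, 5).frame["discordance"]
        vb = ng.compute_discordance(b, 5).frame["discordance"]
        pd.testing.assert_series_equal(va, vb)

    def test_small_cluster_flagged_excluded(self):
        rows = self._cluster(att=0.8, beh=0.3, n=20, cluster=0) + self._cluster(
            att=0.8, beh=0.3, n=3, cluster=1
        )
        table = ng.compute_discordance(toy_dataset(rows), 10)
        frame = table.frame.set_index("cluster_id")
        assert not frame.loc[0, "excluded"]
        assert frame.loc[1, "excluded"]
        assert set(table.included["cluster_id"]) == {0}

    def test_all_excluded_raises(self):
        ds = toy_dataset(self._cluster(att=0.8, beh=0.3, n=4))
        with pytest.raises(DataError):
            ng.compute_discordance(ds, 10)

    def test_no_adults_raises(self):
        ds = toy_dataset([{"age_years": 16, "hiv_tested": True}])
        with pytest.raises(DataError):
            ng.compute_discordance(ds, 1)

    def test_bounds(self, attached_survey):
        disc = ng.compute_discordance(attached_survey, 3).frame["discordance"].dropna()
        assert (disc.abs() <= 10.0).all()


class TestAttachContext:
    def test_columns_attached(self, attached_survey):
        cols = attached_survey.respondents.columns
        assert "disc_female" in cols and "disc_male" in cols
        assert "cl_ipv_history" in cols

    def test_excluded_cluster_gets_nan(self):
        rows = TestDiscordance._cluster(att=0.8, beh=0.3, n=20, cluster=0)
        rows += TestDiscordance._cluster(att=0.8, beh=0.3, n=3, cluster=1)
        rows.append({"cluster_id": 1, "age_years": 16, "hiv_tested": True, "hiv_positive": False})
        out = ng.attach_cluster_context(toy_dataset(rows), min_adults_per_cluster=10)
        df = out.respondents
        assert df.loc[df["cluster_id"] == 0, "disc_female"].notna().all()
        assert df.loc[df["cluster_id"] == 1, "disc_female"].isna().all()


class TestScreenSurveys:
    def test_flowchart_examples(self):
        meta = [
            SurveyMetadata("ZMB07", 2007, 0.453, 2.5, True, True),
            SurveyMetadata("A", 2008, 0.30, 1.5, True, True),
            SurveyMetadata("B", 2010, 0.30, 2.5, False, True),
            SurveyMetadata("C", 2010, 0.30, 2.5, True, True),
            SurveyMetadata("D", 2004, 0.30, 2.5, True, False),
        ]
        out = ng.screen_surveys(meta).set_index("survey_id")
        assert out.loc["ZMB07", "classification"] == "balanced_comparator"
        assert out.loc["A", "classification"] == "excluded"
        assert out.loc["A", "reason"] == "low_gender_hiv_pr"
        assert out.loc["B", "reason"] == "no_individual_hiv"
        assert out.loc["C", "classification"] == "imbalanced_included"
        assert out.loc["D", "reason"] == "pre_dhs_v"

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        meta = [
            SurveyMetadata(
                f"S{i}", 2000 + int(rng.integers(0, 20)),
                float(rng.uniform(0.1, 0.6)), float(rng.uniform(0.5, 4.0)),
                bool(rng.integers(0, 2)), bool(rng.integers(0, 2)),
            )
            for i in range(50)
        ]
        out = ng.screen_surveys(meta)
        assert len(out) == 50
        assert out["survey_id"].nunique() == 50
        assert out["classification"].isin(
            ["balanced_comparator", "imbalanced_included", "excluded"]
        ).all()

    def test_missing_field_raises(self):
        bad = SurveyMetadata("X", 2010, None, 2.5, True, True)
        with pytest.raises(DataError, match="male_share_total"):
            ng.screen_surveys([bad])
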