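import numpy as np
import pandas as pd
import pytest

import normgap as ng
from normgap.core import GROUP_ITEMS


def toy_respondents(rows):
    """Build a full respondent table from terse row dicts.

    Each row dict may override any respondent column; sensible defaults
    fill the rest.
    """
    defaults = {
        "cluster_id": 0,
        "stratum_id": "rural",
        "household_id": 0,
        "gender": "female",
        "age_years": 30,
        "design_weight": 1.0,
        "ever_had_sex": True,
        "hiv_tested": None,
        "hiv_positive": None,
        "education": "primary",
        "marital": "currently",
        "residence": "rural",
        "attitude_disapproves_premarital": None,
        "behaviour_premarital": None,
        **{item: None for item in GROUP_ITEMS},
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("respondent_id", f"t{i:04d}")
        records.append(rec)
    df = pd.DataFrame(records)
    df["age_group"] = ng.cohort.core.age_group_of(df["age_years"])
    bool_cols = ["ever_had_sex", "hiv_tested", "hiv_positive",
                 "attitude_disapproves_premarital", "behaviour_premarital", *GROUP_ITEMS]
    for col in bool_cols:
        df[col] = pd.array(df[col], dtype="boolean")
    return df


def toy_dataset(rows, metadata=None):
    return ng.SurveyDataset(toy_respondents(rows), metadata or {"source": "balanced"})


@pytest.fixture(scope="session")
def small_survey():
    """A medium synthetic survey with a known FF effect, reused across tests."""
    cfg = ng.GeneratorConfig(
        n_clusters=120,
        households_per_cluster=6,
        seed=7,
        true_log_rr_per_10pp={"FF": float(np.log(1.27))},
        baseline_hiv_risk=0.08,
    )
    dataset, truth = ng.generate_survey(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def attached_survey(small_survey):
    _, dataset, _ = small_survey
    eligible = ng.filter_eligible(dataset)
    return ng.attach_cluster_context(eligible, min_adults_per_cluster=3)
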