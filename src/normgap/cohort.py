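"""Eligibility filtering, gender-age distributions, the community
discordance exposure, and survey-metadata screening.

The operations here prepare a respondent-level survey table for the
outcome models: adolescents are screened by sexual-experience and
HIV-testing rules, adults contribute cluster-level norm proportions, and
survey metadata is classified into balanced / imbalanced / excluded arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import core
from .core import (
    ADOLESCENT_GROUPS,
    ADULT_GROUP,
    GENDERS,
    GROUP_ITEMS,
    STRATA,
    ConfigurationError,
    DataError,
)

#: Respondent-table columns required by the downstream pipeline, in the
#: canonical storage order.
RESPONDENT_COLUMNS = (
    "respondent_id",
    "cluster_id",
    "stratum_id",
    "household_id",
    "gender",
    "age_years",
    "age_group",
    "design_weight",
    "ever_had_sex",
    "hiv_tested",
    "hiv_positive",
    "education",
    "marital",
    "residence",
    "attitude_disapproves_premarital",
    "behaviour_premarital",
    "ipv_history",
    "belief_fidelity",
    "belief_beating_justified",
    "partner_age_diff_large",
    "alcohol_before_sex",
)

_BOOL_COLUMNS = (
    "ever_had_sex",
    "hiv_tested",
    "hiv_positive",
    "attitude_disapproves_premarital",
    "behaviour_premarital",
) + GROUP_ITEMS


@dataclass
class SurveyDataset:
    """Respondent-level microdata plus multi-stage design metadata.

    ``respondents`` holds one row per respondent with the columns listed
    in :data:`RESPONDENT_COLUMNS` (extra columns, e.g. attached
    cluster-level exposures, are allowed and preserved).  ``metadata``
    records provenance (``source`` is ``"balanced"`` or
    ``"simulated_imbalanced"``), eligibility bookkeeping and generator
    information.
    """

    respondents: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESPONDENT_COLUMNS if c not in self.respondents.columns]
        if missing:
            raise DataError(f"respondent table missing columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.respondents)

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(self.respondents.copy(), dict(self.metadata))

    def validate(self) -> None:
        """Check structural invariants; raise :class:`DataError` on violation."""
        df = self.respondents
        if (df["design_weight"] <= 0).any():
            raise DataError("design_weight must be strictly positive")
        strat = df.groupby("cluster_id")["stratum_id"].nunique()
        if (strat > 1).any():
            bad = strat[strat > 1].index.tolist()
            raise DataError(f"clusters mapped to multiple strata: {bad}")
        expected = core.age_group_of(df["age_years"])
        if not (expected.to_numpy() == df["age_group"].to_numpy()).all():
            raise DataError("age_group inconsistent with age_years")
        bad_hiv = df["hiv_positive"].notna() & ~df["hiv_tested"].fillna(False).astype(bool)
        if bad_hiv.any():
            raise DataError("hiv_positive present for untested respondents")


@dataclass(frozen=True)
class GenderAgeDistribution:
    """Unweighted counts over the six gender-age strata."""

    counts: pd.Series  # MultiIndex (gender, age_group), canonical order

    def __post_init__(self) -> None:
        counts = self.counts.reindex(pd.MultiIndex.from_tuples(STRATA, names=["gender", "age_group"]))
        if counts.isna().any():
            raise ConfigurationError("distribution must cover all 6 gender-age strata")
        if (counts < 0).any():
            raise ConfigurationError("stratum counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> pd.Series:
        if self.total == 0:
            raise DataError("empty distribution has no proportions")
        return self.counts / self.total

    @classmethod
    def from_counts(cls, counts) -> "GenderAgeDistribution":
        if isinstance(counts, dict):
            counts = pd.Series(counts)
        if not isinstance(counts.index, pd.MultiIndex):
            counts.index = pd.MultiIndex.from_tuples(counts.index)
        return cls(counts)

    @classmethod
    def from_proportions(cls, proportions, total: int) -> "GenderAgeDistribution":
        """Integer counts summing exactly to ``total`` (largest-remainder rounding)."""
        p = pd.Series(proportions)
        if not isinstance(p.index, pd.MultiIndex):
            p.index = pd.MultiIndex.from_tuples(p.index)
        p = p.reindex(pd.MultiIndex.from_tuples(STRATA, names=["gender", "age_group"]))
        if p.isna().any() or (p < 0).any():
            raise ConfigurationError("proportions must be non-negative over all 6 strata")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"proportions sum to {p.sum():.12f}, not 1")
        raw = p.to_numpy() * total
        base = np.floor(raw).astype(int)
        short = total - base.sum()
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
        return cls(pd.Series(base, index=p.index))

    def male_share(self) -> float:
        return float(self.proportions.loc["male"].sum())

    def adolescent_share(self, gender: str) -> float:
        """Share of ``gender`` respondents aged 15-24 (within that gender)."""
        g = self.counts.loc[gender]
        if g.sum() == 0:
            return float("nan")
        return float(g.loc[list(ADOLESCENT_GROUPS)].sum() / g.sum())


@dataclass
class DiscordanceTable:
    """Per (cluster, gender) adult attitude/behaviour proportions and the
    derived discordance exposure in 10-pp units.

    Rows with ``n_adults`` below the inclusion threshold are retained but
    flagged ``excluded`` and carry no exposure for modelling.
    """

    frame: pd.DataFrame  # cluster_id, gender, attitude_prop, behaviour_prop, discordance, n_adults, excluded
    min_adults_per_cluster: int

    @property
    def included(self) -> pd.DataFrame:
        return self.frame[~self.frame["excluded"]]


@dataclass(frozen=True)
class SurveyMetadata:
    """Survey-level screening attributes (one row of the inclusion flowchart)."""

    survey_id: str
    year: int
    male_share_total: float
    gender_hiv_pr: float
    has_individual_hiv: bool
    dhs_phase_post2005: bool


def filter_eligible(dataset: SurveyDataset) -> SurveyDataset:
    """Apply the eligibility rules.

    Adolescents (15-24) are retained only when they report ever having had
    sex *and* have an HIV test; adults (25-49) are always retained.  The
    number of records removed by each rule is recorded in
    ``metadata["eligibility_removed"]``.
    """
    df = dataset.respondents
    adult = df["age_group"] == ADULT_GROUP
    had_sex = df["ever_had_sex"].fillna(False).astype(bool)
    tested = df["hiv_tested"].fillna(False).astype(bool)

    removed_sex = (~adult) & ~had_sex
    removed_test = (~adult) & had_sex & ~tested
    keep = adult | (had_sex & tested)

    out = df[keep].copy()
    meta = dict(dataset.metadata)
    meta["eligibility_removed"] = {
        "adolescent_no_sexual_history": int(removed_sex.sum()),
        "adolescent_no_hiv_test": int(removed_test.sum()),
    }
    meta["eligible"] = True
    if not (out["age_group"].isin(ADOLESCENT_GROUPS)).any():
        warnings.warn("no eligible adolescents remain; outcome models will be empty", stacklevel=2)
    return SurveyDataset(out, meta)


def compute_distribution(dataset: SurveyDataset) -> GenderAgeDistribution:
    """Unweighted counts of respondents per gender-age stratum."""
    df = dataset.respondents
    if df.empty:
        raise DataError("cannot compute a gender-age distribution of an empty dataset")
    counts = df.groupby(["gender", "age_group"], observed=False).size()
    counts = counts.reindex(pd.MultiIndex.from_tuples(STRATA, names=["gender", "age_group"]), fill_value=0)
    return GenderAgeDistribution(counts)


def distributions_dissimilar(
    a: GenderAgeDistribution, b: GenderAgeDistribution, threshold: float = 0.20
) -> bool:
    """True when at least one stratum proportion differs by more than
    ``threshold`` in relative terms between the two distributions."""
    pa, pb = a.proportions, b.proportions
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(pa - pb) / pb
    rel = rel.replace([np.inf], np.nan)
    rel[(pa == 0) & (pb == 0)] = 0.0
    rel = rel.fillna(np.inf)  # stratum present in a but absent in b
    return bool((rel > threshold).any())


def _grouped_weighted_proportion(values: pd.Series, weights: pd.Series, by) -> pd.Series:
    """Vectorised :func:`normgap.core.weighted_proportion` per group."""
    v = values.astype("Float64").astype(float)  # boolean/NA -> float with NaN
    w = weights.astype(float)
    num = (v * w).groupby(by).sum(min_count=1)
    den = w.where(values.notna()).groupby(by).sum(min_count=1)
    return num / den


def _discordance_frame(df: pd.DataFrame, min_adults_per_cluster: int) -> pd.DataFrame:
    adults = df[df["age_group"] == ADULT_GROUP]
    by = [adults["cluster_id"], adults["gender"]]
    att = _grouped_weighted_proportion(
        adults["attitude_disapproves_premarital"], adults["design_weight"], by
    )
    beh = _grouped_weighted_proportion(adults["behaviour_premarital"], adults["design_weight"], by)
    n_adults = adults.groupby(by).size()
    frame = pd.DataFrame(
        {
            "attitude_prop": att,
            "behaviour_prop": beh,
            "discordance": core.discordance_10pp(att, beh),
            "n_adults": n_adults,
        }
    ).reset_index(names=["cluster_id", "gender"])
    frame = frame.sort_values(["cluster_id", "gender"], kind="stable").reset_index(drop=True)
    frame["excluded"] = (frame["n_adults"] < min_adults_per_cluster) | frame["discordance"].isna()
    return frame


def compute_discordance(dataset: SurveyDataset, min_adults_per_cluster: int = 10) -> DiscordanceTable:
    """Weighted per-cluster, per-gender attitude/behaviour proportions and
    discordance in 10-pp units.

    Clusters contributing fewer than ``min_adults_per_cluster`` adults of a
    gender are flagged excluded for that gender.  Raises when no cluster
    survives.
    """
    df = dataset.respondents
    if not (df["age_group"] == ADULT_GROUP).any():
        raise DataError("no adults present; discordance is undefined")
    frame = _discordance_frame(df, min_adults_per_cluster)
    if frame["excluded"].all():
        raise DataError(
            "every cluster falls below min_adults_per_cluster="
            f"{min_adults_per_cluster}; no discordance exposure available"
        )
    return DiscordanceTable(frame, min_adults_per_cluster)


def cluster_group_proportions(df: pd.DataFrame, items=GROUP_ITEMS) -> pd.DataFrame:
    """Weighted adult cluster proportions for the group-level survey items.

    Items whose responses are entirely missing (covariate never asked) get
    NaN, which downstream model building reports as an unavailable column.
    """
    adults = df[df["age_group"] == ADULT_GROUP]
    by = adults["cluster_id"]
    out = pd.DataFrame(
        {
            f"cl_{item}": _grouped_weighted_proportion(adults[item], adults["design_weight"], by)
            for item in items
        }
    )
    return out.sort_index().reset_index(names=["cluster_id"])


def attach_cluster_context(
    dataset: SurveyDataset,
    discordance: DiscordanceTable | None = None,
    min_adults_per_cluster: int = 10,
) -> SurveyDataset:
    """Merge cluster-level exposures onto every respondent.

    Adds ``disc_female`` / ``disc_male`` (adult discordance of each gender,
    10-pp units; NaN where the cluster is excluded) and ``cl_<item>``
    columns (weighted adult proportions of the group-level items).  The
    context is computed once on this dataset and travels with the rows
    through any subsequent resampling, so every arm of a merged dataset
    sees the same community-level exposure values.
    """
    if discordance is None:
        discordance = compute_discordance(dataset, min_adults_per_cluster)
    df = dataset.respondents.copy()
    disc = discordance.frame.copy()
    disc.loc[disc["excluded"], "discordance"] = np.nan
    wide = disc.pivot(index="cluster_id", columns="gender", values="discordance")
    wide = wide.rename(columns={g: f"disc_{g}" for g in GENDERS})
    for g in GENDERS:
        col = f"disc_{g}"
        if col not in wide.columns:
            wide[col] = np.nan
    props = cluster_group_proportions(df).set_index("cluster_id")
    ctx = wide.join(props, how="outer")
    drop = [c for c in ctx.columns if c in df.columns]
    df = df.drop(columns=drop).merge(ctx, left_on="cluster_id", right_index=True, how="left")
    meta = dict(dataset.metadata)
    meta["cluster_context_attached"] = True
    meta["min_adults_per_cluster"] = min_adults_per_cluster
    return SurveyDataset(df, meta)


# --- survey metadata screening -------------------------------------------

BALANCED_MALE_SHARE = 0.40
MIN_GENDER_HIV_PR = 2.0


def screen_surveys(metadata: list[SurveyMetadata]) -> pd.DataFrame:
    """Classify surveys by the inclusion flowchart.

    Returns one row per survey with ``classification`` in
    ``{"balanced_comparator", "imbalanced_included", "excluded"}`` and the
    first failing rule (flowchart order: gender HIV prevalence ratio,
    individual HIV data, survey phase) as ``reason``.
    """
    rows = []
    for m in metadata:
        for name in ("survey_id", "year", "male_share_total", "gender_hiv_pr",
                     "has_individual_hiv", "dhs_phase_post2005"):
            if getattr(m, name, None) is None:
                raise DataError(f"survey {getattr(m, 'survey_id', '?')!r}: missing field {name}")
        if m.gender_hiv_pr <= 0:
            raise DataError(f"survey {m.survey_id!r}: gender_hiv_pr must be positive")
        balanced = m.male_share_total > BALANCED_MALE_SHARE
        if m.gender_hiv_pr < MIN_GENDER_HIV_PR:
            cls, reason = "excluded", "low_gender_hiv_pr"
        elif not m.has_individual_hiv:
            cls, reason = "excluded", "no_individual_hiv"
        elif not m.dhs_phase_post2005:
            cls, reason = "excluded", "pre_dhs_v"
        else:
            cls = "balanced_comparator" if balanced else "imbalanced_included"
            reason = ""
        rows.append({"survey_id": m.survey_id, "classification": cls, "reason": reason})
    return pd.DataFrame(rows)
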