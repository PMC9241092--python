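"""Generator for DHS-like multi-stage cluster survey microdata with a
known community-discordance -> adolescent-HIV data-generating process.

The generator draws clusters (primary sampling units) inside urban/rural
sampling strata, households inside clusters and respondents inside
households.  Adults carry norm attitude/behaviour indicators drawn from
cluster-level logit-normal proportions; adolescents carry a binary HIV
status drawn from a log-linear (Poisson-type) risk model whose discordance
slope per 10 percentage points is a configurable, recoverable parameter.

The exposure entering the risk model is the *realised* weighted cluster
discordance computed from the generated adult responses with the same
formula the analysis pipeline uses, so the fitted estimand equals the
generative parameter by construction.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import cohort, core
from .cohort import GenderAgeDistribution, SurveyDataset
from .core import (
    AGE_BOUNDS,
    GENDERS,
    GROUP_ITEMS,
    PATHWAYS,
    STRATA,
    STRATUM_LABELS,
    ConfigurationError,
    ParameterisationError,
)

#: Individual-level design columns the risk model may load on.
INDIVIDUAL_EFFECT_KEYS = ("adol_15_19", "edu_primary", "edu_secondary", "marital_currently", "urban")

_DEFAULT_PREVALENCE = {
    "edu_primary": 0.45,
    "edu_secondary": 0.25,
    "marital_currently": 0.45,
    "ipv_history": 0.30,
    "belief_fidelity": 0.60,
    "belief_beating_justified": 0.25,
    "partner_age_diff_large": 0.30,
    "alcohol_before_sex": 0.20,
}

#: Default balanced shares: male total 45.3%, adolescent-by-gender shares
#: 28.9% (female) and 26.8% (male), adolescents split 55/45 across 15-19
#: and 20-24.
_DEFAULT_SHARES = (0.0869, 0.0711, 0.3890, 0.0668, 0.0546, 0.3316)


def _normalise_betas(value) -> dict[str, float]:
    if isinstance(value, dict):
        unknown = set(value) - set(PATHWAYS)
        if unknown:
            raise ConfigurationError(f"unknown pathway keys in true_log_rr_per_10pp: {sorted(unknown)}")
        return {p: float(value.get(p, 0.0)) for p in PATHWAYS}
    return {p: float(value) for p in PATHWAYS}


def _normalise_modifiers(value: dict) -> dict[str, dict[str, float]]:
    """Effect modifiers as ``{stratum: {pathway: log-RR slope offset}}``.

    A scalar offset for a stratum applies to all four pathways.
    """
    out: dict[str, dict[str, float]] = {}
    for stratum, offset in value.items():
        if stratum not in STRATUM_LABELS:
            raise ConfigurationError(f"unknown stratum in effect_modifiers: {stratum!r}")
        if isinstance(offset, dict):
            unknown = set(offset) - set(PATHWAYS)
            if unknown:
                raise ConfigurationError(
                    f"unknown pathway keys in effect_modifiers[{stratum}]: {sorted(unknown)}"
                )
            out[stratum] = {p: float(offset.get(p, 0.0)) for p in PATHWAYS}
        else:
            out[stratum] = {p: float(offset) for p in PATHWAYS}
    return out


def _normalise_baseline(value) -> dict[str, float]:
    if isinstance(value, dict):
        unknown = set(value) - set(GENDERS)
        if unknown:
            raise ConfigurationError(f"unknown gender keys in baseline_hiv_risk: {sorted(unknown)}")
        out = {g: float(value[g]) for g in GENDERS if g in value}
        if set(out) != set(GENDERS):
            raise ConfigurationError("baseline_hiv_risk dict must cover both genders")
    else:
        out = {g: float(value) for g in GENDERS}
    for g, v in out.items():
        if not 0.0 < v < 1.0:
            raise ConfigurationError(f"baseline_hiv_risk[{g}] = {v} outside (0, 1)")
    return out


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    ``gender_age_shares`` is a 6-vector over the canonical stratum order
    (F 15-19, F 20-24, F 25-49, M 15-19, M 20-24, M 25-49).
    ``true_log_rr_per_10pp`` may be a scalar (all four pathways) or a dict
    keyed by pathway id; ``effect_modifiers`` maps stratum labels (e.g.
    ``"female_15-19"``) to additive log-RR slope offsets.
    """

    n_clusters: int = 300
    households_per_cluster: int = 6
    respondents_per_household: float = 2.5
    urban_fraction: float = 0.35
    gender_age_shares: tuple = _DEFAULT_SHARES
    baseline_hiv_risk: object = 0.08
    true_log_rr_per_10pp: object = 0.0
    effect_modifiers: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    attitude_mean: float = 0.75
    behaviour_mean: float = 0.30
    cluster_sd: float = 0.5
    covariate_prevalence: dict = field(default_factory=dict)
    adolescent_sex_rate: float = 0.75
    adolescent_test_rate: float = 0.85
    missingness_scenario: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be a positive integer")
        if self.households_per_cluster < 1:
            raise ConfigurationError("households_per_cluster must be a positive integer")
        if self.respondents_per_household < 1:
            raise ConfigurationError("respondents_per_household mean must be >= 1")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigurationError("urban_fraction must be in [0, 1]")
        shares = np.asarray(self.gender_age_shares, dtype=float)
        if shares.shape != (6,):
            raise ConfigurationError("gender_age_shares must have exactly 6 entries")
        if (shares < 0).any():
            raise ConfigurationError("gender_age_shares must be non-negative")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"gender_age_shares sum to {shares.sum():.12f}, not 1")
        _normalise_baseline(self.baseline_hiv_risk)
        _normalise_betas(self.true_log_rr_per_10pp)
        _normalise_modifiers(self.effect_modifiers)
        allowed = set(INDIVIDUAL_EFFECT_KEYS) | set(GROUP_ITEMS)
        unknown = set(self.covariate_effects) - allowed
        if unknown:
            raise ConfigurationError(f"unknown covariate_effects keys: {sorted(unknown)}")
        for p in ("attitude_mean", "behaviour_mean"):
            v = getattr(self, p)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{p} must be in (0, 1)")
        if self.cluster_sd < 0:
            raise ConfigurationError("cluster_sd must be non-negative")
        if self.missingness_scenario is not None and self.missingness_scenario not in range(1, 7):
            raise ConfigurationError("missingness_scenario must be in 1..6")

    def prevalence(self, key: str) -> float:
        return float(self.covariate_prevalence.get(key, _DEFAULT_PREVALENCE[key]))


@dataclass
class SyntheticTruth:
    """The generator's true parameters and realised cluster-level draws.

    Together with the seed this fully determines the conditional outcome
    distribution; regenerating with the same config reproduces the
    dataset bit-identically.
    """

    true_log_rr_per_10pp: dict
    effect_modifiers: dict
    covariate_effects: dict
    baseline_hiv_risk: dict
    cluster_norms: pd.DataFrame  # cluster_id, gender, true/realised proportions, discordance
    seed: int

    def marginal_slope(self, pathway: str, weights_by_stratum: dict[str, float]) -> float:
        """Population-averaged discordance slope for a pathway under a
        given mix of (modelled) adolescent strata.

        Closed-form mixture oracle: the marginal slope is the
        stratum-share-weighted mean of ``beta + modifier``.
        """
        beta = self.true_log_rr_per_10pp[pathway]
        total = sum(weights_by_stratum.values())
        return sum(
            w * (beta + self.effect_modifiers.get(s, {}).get(pathway, 0.0))
            for s, w in weights_by_stratum.items()
        ) / total

    def to_dict(self) -> dict:
        return {
            "true_log_rr_per_10pp": self.true_log_rr_per_10pp,
            "effect_modifiers": self.effect_modifiers,
            "covariate_effects": self.covariate_effects,
            "baseline_hiv_risk": self.baseline_hiv_risk,
            "seed": self.seed,
            "cluster_norms": self.cluster_norms.to_dict(orient="list"),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class DistributionPreset:
    """A named gender-age target distribution.

    Marginals printed in the source material are exact; the remaining
    fields required to complete a 6-stratum vector are flagged
    ``illustrative`` and editable in ``data/presets.csv``.
    """

    preset_id: str
    male_share_total: float
    female_adolescent_share: float
    male_adolescent_share: float
    adol_15_19_fraction: float
    illustrative_fields: tuple

    def adolescent_share_by_gender(self) -> dict[str, float]:
        return {"female": self.female_adolescent_share, "male": self.male_adolescent_share}

    def proportions(self) -> pd.Series:
        """Full 6-stratum proportion vector implied by the marginals."""
        shares = {}
        gender_total = {"female": 1.0 - self.male_share_total, "male": self.male_share_total}
        adol = self.adolescent_share_by_gender()
        for g in GENDERS:
            a = adol[g]
            shares[(g, "15-19")] = gender_total[g] * a * self.adol_15_19_fraction
            shares[(g, "20-24")] = gender_total[g] * a * (1.0 - self.adol_15_19_fraction)
            shares[(g, "25-49")] = gender_total[g] * (1.0 - a)
        s = pd.Series(shares)
        s.index = pd.MultiIndex.from_tuples(s.index, names=["gender", "age_group"])
        return s.reindex(pd.MultiIndex.from_tuples(STRATA, names=["gender", "age_group"]))

    def target_counts(self, total: int) -> GenderAgeDistribution:
        return GenderAgeDistribution.from_proportions(self.proportions(), total)


def builtin_presets() -> list[DistributionPreset]:
    """Packaged gender-age distribution presets (balanced comparator plus
    the printed imbalanced extremes)."""
    path = importlib.resources.files("normgap.data").joinpath("presets.csv")
    with importlib.resources.as_file(path) as p:
        table = pd.read_csv(p)
    presets = []
    for _, row in table.iterrows():
        presets.append(
            DistributionPreset(
                preset_id=row["preset_id"],
                male_share_total=float(row["male_share_total"]),
                female_adolescent_share=float(row["female_adolescent_share"]),
                male_adolescent_share=float(row["male_adolescent_share"]),
                adol_15_19_fraction=float(row["adol_15_19_fraction"]),
                illustrative_fields=tuple(str(row["illustrative_fields"]).split(";")),
            )
        )
    return presets


def get_preset(preset_id: str) -> DistributionPreset:
    for preset in builtin_presets():
        if preset.preset_id == preset_id:
            return preset
    known = [p.preset_id for p in builtin_presets()]
    raise ConfigurationError(f"unknown preset {preset_id!r}; available: {known}")


def _bool_series(values: np.ndarray, mask: np.ndarray) -> pd.Series:
    out = pd.array([pd.NA] * len(values), dtype="boolean")
    out[mask] = values[mask]
    return pd.Series(out)


def generate_survey(config: GeneratorConfig) -> tuple[SurveyDataset, SyntheticTruth]:
    """Generate a survey and the truth object describing it.

    Raises :class:`ConfigurationError` for invalid parameters and
    :class:`ParameterisationError` (naming the offending stratum) when the
    log-linear risk model yields a probability >= 1 for any respondent.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    betas = _normalise_betas(config.true_log_rr_per_10pp)
    baseline = _normalise_baseline(config.baseline_hiv_risk)
    shares = np.asarray(config.gender_age_shares, dtype=float)

    n_cl = config.n_clusters
    cluster_ids = np.arange(n_cl)
    urban_cluster = rng.random(n_cl) < config.urban_fraction
    cluster_w = np.exp(rng.normal(0.0, 0.2, n_cl))

    hh_per = config.households_per_cluster
    hh_sizes = 1 + rng.poisson(config.respondents_per_household - 1.0, size=n_cl * hh_per)
    hh_cluster = np.repeat(cluster_ids, hh_per)
    cl = np.repeat(hh_cluster, hh_sizes)
    hh = np.repeat(np.arange(n_cl * hh_per), hh_sizes)
    n = len(cl)

    stratum_idx = rng.choice(6, size=n, p=shares)
    gender = np.array([STRATA[i][0] for i in stratum_idx])
    age_group = np.array([STRATA[i][1] for i in stratum_idx])
    age = np.empty(n, dtype=int)
    for i, (g, grp) in enumerate(STRATA):
        lo, hi = AGE_BOUNDS[grp]
        mask = stratum_idx == i
        age[mask] = rng.integers(lo, hi + 1, size=mask.sum())

    weight = cluster_w[cl] * np.exp(rng.normal(0.0, 0.15, n))

    p_pri = config.prevalence("edu_primary")
    p_sec = config.prevalence("edu_secondary")
    education = rng.choice(
        np.array(["none", "primary", "secondary"]), size=n, p=[1.0 - p_pri - p_sec, p_pri, p_sec]
    )
    marital = np.where(
        rng.random(n) < config.prevalence("marital_currently"), "currently", "never_formerly"
    )
    residence = np.where(urban_cluster[cl], "urban", "rural")

    adult = age_group == "25-49"
    gender_idx = (gender == "male").astype(int)

    # cluster-level norm proportions (logit-normal per cluster x gender)
    att_p = expit(rng.normal(logit(config.attitude_mean), config.cluster_sd, size=(n_cl, 2)))
    beh_p = expit(rng.normal(logit(config.behaviour_mean), config.cluster_sd, size=(n_cl, 2)))
    attitude = _bool_series(rng.random(n) < att_p[cl, gender_idx], adult)
    behaviour = _bool_series(rng.random(n) < beh_p[cl, gender_idx], adult)

    group_items = {}
    for item in GROUP_ITEMS:
        group_items[item] = _bool_series(rng.random(n) < config.prevalence(item), adult)

    adolescent = ~adult
    ever_sex_draw = rng.random(n)
    ever_had_sex = _bool_series(
        np.where(adolescent, ever_sex_draw < config.adolescent_sex_rate, ever_sex_draw < 0.95),
        np.ones(n, dtype=bool),
    )
    hiv_tested = _bool_series(rng.random(n) < config.adolescent_test_rate, adolescent)

    df = pd.DataFrame(
        {
            "respondent_id": [f"r{i:06d}" for i in range(n)],
            "cluster_id": cl,
            "stratum_id": np.where(urban_cluster[cl], "urban", "rural"),
            "household_id": hh,
            "gender": gender,
            "age_years": age,
            "age_group": age_group,
            "design_weight": weight,
            "ever_had_sex": ever_had_sex,
            "hiv_tested": hiv_tested,
            "hiv_positive": pd.array([pd.NA] * n, dtype="boolean"),
            "education": education,
            "marital": marital,
            "residence": residence,
            "attitude_disapproves_premarital": attitude,
            "behaviour_premarital": behaviour,
        }
    )
    for item in GROUP_ITEMS:
        df[item] = group_items[item]

    # realised weighted cluster discordance -- the exposure of the risk model
    disc_frame = cohort._discordance_frame(df, min_adults_per_cluster=1)
    disc = np.zeros((n_cl, 2))
    for _, row in disc_frame.iterrows():
        if not np.isnan(row["discordance"]):
            disc[int(row["cluster_id"]), int(row["gender"] == "male")] = row["discordance"]

    cl_props = cohort.cluster_group_proportions(df).set_index("cluster_id")

    # adolescent outcome via the log-linear risk model
    tested = adolescent & hiv_tested.fillna(False).to_numpy(dtype=bool)
    lp = np.zeros(n)
    stratum_label = np.array([STRATUM_LABELS[i] for i in stratum_idx])
    modifiers = _normalise_modifiers(config.effect_modifiers)
    for e_idx, e_gender in enumerate(GENDERS):
        pw = np.array([core.pathway_id(g, e_gender) for g in gender])
        beta_vec = np.array([betas[p] for p in pw])
        mod_vec = np.array(
            [modifiers.get(s, {}).get(p, 0.0) for s, p in zip(stratum_label, pw)]
        )
        lp += (beta_vec + mod_vec) * disc[cl, e_idx]
    for key, eff in config.covariate_effects.items():
        if key in INDIVIDUAL_EFFECT_KEYS:
            x = {
                "adol_15_19": (age_group == "15-19").astype(float),
                "edu_primary": (education == "primary").astype(float),
                "edu_secondary": (education == "secondary").astype(float),
                "marital_currently": (marital == "currently").astype(float),
                "urban": (residence == "urban").astype(float),
            }[key]
        else:
            x = cl_props[f"cl_{key}"].reindex(cluster_ids).fillna(0.0).to_numpy()[cl]
        lp += eff * x
    base_vec = np.array([baseline[g] for g in gender])
    prob = base_vec * np.exp(lp)
    bad = tested & (prob >= 1.0)
    if bad.any():
        worst = int(np.argmax(np.where(bad, prob, -np.inf)))
        raise ParameterisationError(
            f"risk model yields probability {prob[worst]:.3f} >= 1 in stratum "
            f"{stratum_label[worst]} (cluster {cl[worst]}); rescale the parameters"
        )
    hiv_draw = rng.random(n)
    hiv = pd.array([pd.NA] * n, dtype="boolean")
    hiv[tested] = (hiv_draw < prob)[tested]
    df["hiv_positive"] = pd.Series(hiv)

    norms = disc_frame.rename(
        columns={"attitude_prop": "attitude_prop_realised", "behaviour_prop": "behaviour_prop_realised"}
    ).drop(columns=["excluded"])
    norms["attitude_p_true"] = att_p[norms["cluster_id"].to_numpy(), (norms["gender"] == "male").to_numpy().astype(int)]
    norms["behaviour_p_true"] = beh_p[norms["cluster_id"].to_numpy(), (norms["gender"] == "male").to_numpy().astype(int)]

    truth = SyntheticTruth(
        true_log_rr_per_10pp=betas,
        effect_modifiers=modifiers,
        covariate_effects=dict(config.covariate_effects),
        baseline_hiv_risk=baseline,
        cluster_norms=norms,
        seed=config.seed,
    )
    metadata = {
        "provenance": f"normgap-generator seed={config.seed}",
        "source": "balanced",
        "n_clusters": n_cl,
    }
    dataset = SurveyDataset(df, metadata)
    if config.missingness_scenario is not None:
        dataset = apply_missingness_scenario(dataset, config.missingness_scenario)
    return dataset, truth


def apply_missingness_scenario(dataset: SurveyDataset, scenario) -> SurveyDataset:
    """Blank every response for the covariates a scenario marks unavailable.

    ``scenario`` is a scenario id (1-6) or a
    :class:`normgap.missingness.CovariateScenario`.  The operation is
    idempotent and leaves all other columns untouched.
    """
    from . import missingness

    if isinstance(scenario, int):
        scenario = missingness.get_scenario(scenario)
    df = dataset.respondents.copy()
    for covariate, _pathways in scenario.unavailable:
        if covariate not in df.columns:
            raise ConfigurationError(f"scenario names unknown covariate {covariate!r}")
        df[covariate] = pd.array([pd.NA] * len(df), dtype="boolean")
    meta = dict(dataset.metadata)
    meta["missingness_scenario"] = scenario.scenario_id
    return SurveyDataset(df, meta)
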