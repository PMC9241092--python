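"""Survey-weighted Poisson (log-link) risk models for the four
sex-stratified discordance -> adolescent-HIV pathways, the bootstrap test
for interaction, and relative-risk summaries.

The binary HIV outcome is modelled with a log link and Poisson working
likelihood (the standard modified-Poisson route to prevalence ratios);
variance is always a cluster-robust sandwich aggregated at the primary
sampling unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import cohort
from .core import (
    ADOLESCENT_GROUPS,
    GENDERS,
    GROUP_ITEMS,
    ConfigurationError,
    DataError,
    ModellingError,
    PATHWAYS,
    pathway_genders,
    pathway_id,
)

#: Expansion of analysis covariates to design-matrix columns.
COVARIATE_DESIGN = {
    "age_group": ("adol_15_19",),
    "education": ("edu_primary", "edu_secondary"),
    "marital": ("marital_currently",),
    "residence": ("urban",),
    **{item: (f"cl_{item}",) for item in GROUP_ITEMS},
}

_COMMON_COVARIATES = (
    "age_group",
    "education",
    "marital",
    "residence",
    "belief_fidelity",
    "belief_beating_justified",
)


def canonical_covariates(outcome_gender: str) -> tuple[str, ...]:
    """Fully adjusted covariate list for an outcome gender.

    Female HIV models additionally adjust for IPV history and large
    partner age difference; male HIV models for alcohol use before sex.
    """
    if outcome_gender == "female":
        return _COMMON_COVARIATES + ("ipv_history", "partner_age_diff_large")
    if outcome_gender == "male":
        return _COMMON_COVARIATES + ("alcohol_before_sex",)
    raise ConfigurationError(f"unknown outcome gender {outcome_gender!r}")


@dataclass(frozen=True)
class ModelSpec:
    """One sex-stratified pathway model."""

    outcome_gender: str
    exposure_gender: str
    covariates: tuple = ()
    include_interaction: bool = False

    def __post_init__(self) -> None:
        for g in (self.outcome_gender, self.exposure_gender):
            if g not in GENDERS:
                raise ConfigurationError(f"unknown gender {g!r}")
        unknown = set(self.covariates) - set(COVARIATE_DESIGN)
        if unknown:
            raise ConfigurationError(f"unknown covariates: {sorted(unknown)}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def pathway(self) -> str:
        return pathway_id(self.outcome_gender, self.exposure_gender)

    @classmethod
    def canonical(cls, pathway: str, include_interaction: bool = False) -> "ModelSpec":
        out_g, exp_g = pathway_genders(pathway)
        return cls(out_g, exp_g, canonical_covariates(out_g), include_interaction)

    def with_interaction(self, flag: bool = True) -> "ModelSpec":
        return replace(self, include_interaction=flag)

    def without(self, covariates) -> "ModelSpec":
        removed = set(covariates)
        missing = removed - set(self.covariates)
        if missing:
            raise ModellingError(f"cannot remove covariates absent from the spec: {sorted(missing)}")
        return replace(self, covariates=tuple(c for c in self.covariates if c not in removed))


def canonical_specs(include_interaction: bool = False) -> list[ModelSpec]:
    """The four pathway models in canonical order (FF, FM, MF, MM)."""
    return [ModelSpec.canonical(p, include_interaction) for p in PATHWAYS]


@dataclass
class Design:
    y: np.ndarray
    X: pd.DataFrame
    weights: np.ndarray
    clusters: np.ndarray
    n_dropped: int


@dataclass
class FitResult:
    """Coefficients and cluster-robust covariance of one fitted model."""

    params: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_clusters: int
    converged: bool
    loglike: float
    spec: ModelSpec

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.se()
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )


def individual_design_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric individual-level design columns derived from the
    categorical respondent fields."""
    return pd.DataFrame(
        {
            "adol_15_19": (df["age_group"] == "15-19").astype(float),
            "edu_primary": (df["education"] == "primary").astype(float),
            "edu_secondary": (df["education"] == "secondary").astype(float),
            "marital_currently": (df["marital"] == "currently").astype(float),
            "urban": (df["residence"] == "urban").astype(float),
        },
        index=df.index,
    )


def build_design(dataset, spec: ModelSpec, min_adults_per_cluster: int = 10) -> Design:
    """Assemble outcome, design matrix, weights and cluster ids.

    ``dataset`` may be a :class:`~normgap.cohort.SurveyDataset` or a
    :class:`~normgap.resampling.MergedDataset`.  Cluster-level exposure
    columns are attached on the fly when absent.
    """
    df = dataset.respondents
    if "disc_female" not in df.columns:
        attached = cohort.attach_cluster_context(
            cohort.SurveyDataset(df.copy(), {"provenance": "inline"}),
            min_adults_per_cluster=min_adults_per_cluster,
        )
        df = attached.respondents

    rows = df[
        (df["gender"] == spec.outcome_gender)
        & df["age_group"].isin(ADOLESCENT_GROUPS)
        & df["hiv_positive"].notna()
    ].copy()
    if rows.empty:
        raise ModellingError(
            f"no adolescent {spec.outcome_gender} respondents with HIV status available"
        )

    X = pd.DataFrame(index=rows.index)
    X["const"] = 1.0
    X["discordance"] = rows[f"disc_{spec.exposure_gender}"].astype(float)
    if spec.include_interaction:
        if "imbalance" not in rows.columns:
            raise ModellingError("include_interaction requires an imbalance indicator column")
        X["imbalance"] = rows["imbalance"].astype(float)
        X["discordance:imbalance"] = X["discordance"] * X["imbalance"]

    indiv = individual_design_columns(rows)
    for cov in spec.covariates:
        for col in COVARIATE_DESIGN[cov]:
            if col in indiv.columns:
                X[col] = indiv[col]
            else:
                if col not in rows.columns:
                    raise ModellingError(f"design column for covariate {cov!r} is absent")
                vals = rows[col].astype(float)
                if vals.isna().all():
                    raise ModellingError(
                        f"covariate {cov!r} has no observed responses (column entirely missing)"
                    )
                X[col] = vals

    keep = X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    rows, X = rows[keep], X[keep]
    if rows.empty:
        raise ModellingError("all rows dropped while assembling the design (missing exposure?)")
    y = rows["hiv_positive"].astype(bool).to_numpy().astype(float)
    w = rows["design_weight"].to_numpy(dtype=float)
    clusters = rows["cluster_id"].to_numpy()
    return Design(y, X, w, clusters, n_dropped)


def weighted_poisson_loglike(y, mu, w) -> float:
    """Weight-multiplied Poisson log-likelihood (constant terms dropped)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return float(np.sum(w * (term - mu)))


def cluster_robust_cov(X: pd.DataFrame, y, mu, w, clusters) -> pd.DataFrame:
    """Cluster-aggregated sandwich covariance for the weighted Poisson
    score equations ``sum_i w_i (y_i - mu_i) x_i = 0``."""
    Xv = X.to_numpy(dtype=float)
    bread = Xv.T @ (Xv * (w * mu)[:, None])
    scores = Xv * (w * (y - mu))[:, None]
    score_sums = pd.DataFrame(scores).groupby(pd.Series(clusters)).sum().to_numpy()
    meat = score_sums.T @ score_sums
    bread_inv = np.linalg.pinv(bread)
    cov = bread_inv @ meat @ bread_inv
    return pd.DataFrame(cov, index=X.columns, columns=X.columns)


def fit_weighted_poisson(dataset, spec: ModelSpec, min_adults_per_cluster: int = 10) -> FitResult:
    """Fit the survey-weighted Poisson model for one pathway.

    Point estimates maximise the weight-multiplied Poisson log-likelihood
    (log link on the binary HIV indicator); the covariance is the
    cluster-robust sandwich.  Non-convergence yields a flagged result, not
    an exception.
    """
    design = build_design(dataset, spec, min_adults_per_cluster)
    y, X, w = design.y, design.X, design.weights
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            glm = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
            res = glm.fit(maxiter=100, tol=1e-10)
            params = pd.Series(res.params, index=X.columns)
            mu = np.asarray(res.mu)
            converged = bool(getattr(res, "converged", True)) and np.isfinite(params).all()
        except Exception:
            params = pd.Series(np.nan, index=X.columns)
            mu = np.full_like(y, np.nan)
            converged = False
    if converged:
        cov = cluster_robust_cov(X, y, mu, w, design.clusters)
        ll = weighted_poisson_loglike(y, mu, w)
    else:
        cov = pd.DataFrame(np.nan, index=X.columns, columns=X.columns)
        ll = float("nan")
    return FitResult(
        params=params,
        cov=cov,
        n_obs=len(y),
        n_clusters=int(pd.Series(design.clusters).nunique()),
        converged=converged,
        loglike=ll,
        spec=spec,
    )


# --- bootstrap test for interaction --------------------------------------


@dataclass
class InteractionSummary:
    """Bootstrap-aggregated interaction-model coefficients for one
    survey-scenario x pathway."""

    pathway: str
    coefficients: pd.DataFrame  # index: term; columns: mean, sd, p_value
    rr_balanced: tuple  # (point, lower, upper), per 10-pp discordance
    rr_imbalanced: tuple
    significant_interaction: bool
    rr_ci_disjoint_from_baseline: bool
    n_replicates: int
    n_dropped: int
    alpha: float
    unreliable: bool
    survey_id: str = ""

    def __post_init__(self) -> None:
        for rr in (self.rr_balanced, self.rr_imbalanced):
            if not (rr[1] <= rr[0] <= rr[2]):
                raise ModellingError("RR confidence bounds must bracket the point estimate")


def _summary_p_value(mean: float, sd: float) -> float:
    """Two-sided normal p-value for a bootstrap-summarised coefficient
    (z = mean over replicates / SD over replicates)."""
    if sd == 0.0:
        return 1.0 if mean == 0.0 else 0.0
    return float(2.0 * stats.norm.sf(abs(mean / sd)))


def _rr_summary(values: np.ndarray) -> tuple:
    mean, sd = float(np.mean(values)), float(np.std(values, ddof=1))
    return (
        float(np.exp(mean)),
        float(np.exp(mean - 1.96 * sd)),
        float(np.exp(mean + 1.96 * sd)),
    )


def interaction_test(
    replicates,
    spec: ModelSpec,
    min_adults_per_cluster: int = 10,
    alpha: float = 0.05,
    survey_id: str = "",
) -> InteractionSummary:
    """Fit the interaction model on every bootstrap replicate and
    aggregate coefficients across replicates.

    Non-convergent replicates are dropped with a logged count; when more
    than 10% drop, the summary is flagged ``unreliable``.
    """
    if not spec.include_interaction:
        spec = spec.with_interaction(True)
    rows = []
    n_dropped = 0
    n_total = 0
    for rep in replicates:
        n_total += 1
        fit = fit_weighted_poisson(rep, spec, min_adults_per_cluster)
        if not fit.converged:
            n_dropped += 1
            continue
        rows.append(
            (
                fit.params["discordance"],
                fit.params["imbalance"],
                fit.params["discordance:imbalance"],
            )
        )
    if n_total < 2:
        raise ModellingError("interaction_test requires at least 2 replicates")
    return _aggregate_interaction(rows, n_total, n_dropped, spec, alpha, survey_id)


def _aggregate_interaction(rows, n_total, n_dropped, spec, alpha, survey_id) -> InteractionSummary:
    if len(rows) < 2:
        raise ModellingError(f"all {n_total} replicates failed to converge")
    betas = np.asarray(rows)
    terms = ("discordance", "imbalance", "discordance:imbalance")
    means = betas.mean(axis=0)
    sds = betas.std(axis=0, ddof=1)
    coeffs = pd.DataFrame(
        {
            "mean": means,
            "sd": sds,
            "p_value": [_summary_p_value(m, s) for m, s in zip(means, sds)],
        },
        index=pd.Index(terms, name="term"),
    )
    rr_bal = _rr_summary(betas[:, 0])
    rr_imb = _rr_summary(betas[:, 0] + betas[:, 2])
    p_int = float(coeffs.loc["discordance:imbalance", "p_value"])
    disjoint = rr_imb[1] > rr_bal[0] or rr_imb[2] < rr_bal[0]
    return InteractionSummary(
        pathway=spec.pathway,
        coefficients=coeffs,
        rr_balanced=rr_bal,
        rr_imbalanced=rr_imb,
        significant_interaction=p_int < alpha,
        rr_ci_disjoint_from_baseline=bool(disjoint),
        n_replicates=len(rows),
        n_dropped=n_dropped,
        alpha=alpha,
        unreliable=n_dropped > 0.1 * n_total,
        survey_id=survey_id,
    )


class ReplicateFitter:
    """Precomputed design cache for fitting the interaction model on many
    bootstrap replicates without materialising merged datasets.

    Reproduces the general ``interaction_test`` over
    ``iter_bootstrap_merged`` exactly up to floating-point associativity:
    the per-replicate RNG stream, the design-row order and the IRLS
    arithmetic all match the general path (asserted by the test suite);
    only the pandas row shuffling is skipped.
    """

    def __init__(self, balanced, spec: ModelSpec, min_adults_per_cluster: int = 10):
        from .core import STRATA  # local import to keep module top uncluttered

        spec = spec.with_interaction(True)
        df = balanced.respondents
        if "disc_female" not in df.columns:
            df = cohort.attach_cluster_context(
                cohort.SurveyDataset(df.copy(), {"provenance": "inline"}),
                min_adults_per_cluster=min_adults_per_cluster,
            ).respondents
        self.spec = spec
        self.strata = STRATA

        # column order must match build_design: const, discordance,
        # imbalance, discordance:imbalance, then covariates in spec order
        indiv = individual_design_columns(df)
        columns = ["const", "discordance", "imbalance", "discordance:imbalance"]
        design = {
            "const": np.ones(len(df)),
            "discordance": df[f"disc_{spec.exposure_gender}"].astype(float).to_numpy(),
        }
        for cov in spec.covariates:
            for col in COVARIATE_DESIGN[cov]:
                columns.append(col)
                if col in indiv.columns:
                    design[col] = indiv[col].to_numpy(dtype=float)
                else:
                    if col not in df.columns:
                        raise ModellingError(f"design column for covariate {cov!r} is absent")
                    vals = df[col].astype(float)
                    if vals.isna().all():
                        raise ModellingError(
                            f"covariate {cov!r} has no observed responses (column entirely missing)"
                        )
                    design[col] = vals.to_numpy(dtype=float)
        self.columns = columns
        n = len(df)
        x_static = np.column_stack(
            [design[c] for c in columns if c not in ("imbalance", "discordance:imbalance")]
        )
        self._x_static = x_static  # (n, k-2): const, discordance, covariates
        self._y = df["hiv_positive"].astype("Float64").astype(float).to_numpy()
        self._w = df["design_weight"].to_numpy(dtype=float)
        self._clusters = df["cluster_id"].to_numpy()

        gender = df["gender"].to_numpy()
        age_group = df["age_group"].to_numpy()
        outcome_row = (
            (gender == spec.outcome_gender)
            & np.isin(age_group, list(ADOLESCENT_GROUPS))
            & ~np.isnan(self._y)
        )
        self._valid = outcome_row & np.isfinite(x_static).all(axis=1)
        if not self._valid.any():
            raise ModellingError(
                f"no adolescent {spec.outcome_gender} respondents with HIV status available"
            )
        self._stratum_positions = [
            np.flatnonzero((gender == g) & (age_group == a)) for (g, a) in STRATA
        ]
        bal = np.flatnonzero(self._valid)
        self._bal_positions = bal

    def _assemble(self, positions, factors):
        """Stack balanced + drawn rows into the interaction design."""
        bal = self._bal_positions
        all_pos = np.concatenate([bal, positions])
        x_static = self._x_static[all_pos]
        imb = np.zeros(len(all_pos))
        imb[len(bal):] = 1.0
        X = np.column_stack(
            [x_static[:, 0], x_static[:, 1], imb, x_static[:, 1] * imb, x_static[:, 2:]]
        )
        w = self._w[all_pos].copy()
        w[len(bal):] *= factors
        y = self._y[all_pos]
        clusters = self._clusters[all_pos]
        return X, y, w, clusters

    def fit_replicate(self, target, seed: int, return_cov: bool = False):
        """Fit one bootstrap replicate; returns a :class:`FitResult`."""
        rng = np.random.default_rng(seed)
        drawn = []
        factors = []
        for s_idx, (g, a) in enumerate(self.strata):
            m = int(target.counts.loc[(g, a)])
            if m == 0:
                continue
            pos = self._stratum_positions[s_idx]
            n_s = len(pos)
            if n_s == 0:
                raise DataError(
                    f"target requires {m} records in stratum {g}_{a} but the source has none"
                )
            idx = rng.integers(0, n_s, size=m)  # same stream as resample_to_distribution
            dpos = pos[idx]
            keep = self._valid[dpos]
            if keep.any():
                drawn.append(dpos[keep])
                factors.append(np.full(int(keep.sum()), n_s / m))
        positions = np.concatenate(drawn) if drawn else np.empty(0, dtype=int)
        factor_vec = np.concatenate(factors) if factors else np.empty(0)
        X, y, w, clusters = self._assemble(positions, factor_vec)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w).fit(
                    maxiter=100, tol=1e-10
                )
                params = pd.Series(res.params, index=self.columns)
                mu = np.asarray(res.mu)
                converged = bool(getattr(res, "converged", True)) and np.isfinite(params).all()
            except Exception:
                params = pd.Series(np.nan, index=self.columns)
                mu = np.full_like(y, np.nan)
                converged = False
        if converged and return_cov:
            cov = cluster_robust_cov(
                pd.DataFrame(X, columns=self.columns), y, mu, w, clusters
            )
            ll = weighted_poisson_loglike(y, mu, w)
        else:
            cov = pd.DataFrame(np.nan, index=self.columns, columns=self.columns)
            ll = weighted_poisson_loglike(y, mu, w) if converged else float("nan")
        return FitResult(
            params=params,
            cov=cov,
            n_obs=len(y),
            n_clusters=int(pd.Series(clusters).nunique()),
            converged=converged,
            loglike=ll,
            spec=self.spec,
        )


def interaction_test_fast(
    balanced,
    resample_spec,
    spec: ModelSpec,
    min_adults_per_cluster: int = 10,
    alpha: float = 0.05,
    survey_id: str = "",
) -> InteractionSummary:
    """Equivalent of ``interaction_test(iter_bootstrap_merged(...), ...)``
    computed through the :class:`ReplicateFitter` cache."""
    from .resampling import replicate_seed

    fitter = ReplicateFitter(balanced, spec, min_adults_per_cluster)
    rows = []
    n_dropped = 0
    n_total = 0
    for b in range(resample_spec.n_bootstrap):
        n_total += 1
        fit = fitter.fit_replicate(
            resample_spec.target, replicate_seed(resample_spec.base_seed, b)
        )
        if not fit.converged:
            n_dropped += 1
            continue
        rows.append(
            (
                fit.params["discordance"],
                fit.params["imbalance"],
                fit.params["discordance:imbalance"],
            )
        )
    if n_total < 2:
        raise ModellingError("interaction_test requires at least 2 replicates")
    return _aggregate_interaction(
        rows, n_total, n_dropped, fitter.spec, alpha, survey_id
    )


def format_rr(rr: tuple) -> str:
    return f"{rr[0]:.2f} ({rr[1]:.2f}–{rr[2]:.2f})"


def summarise_rr(summary: InteractionSummary) -> dict:
    """One presentation-ready report row for a survey-scenario x pathway."""
    return {
        "survey_id": summary.survey_id,
        "pathway": summary.pathway,
        "rr_balanced": format_rr(summary.rr_balanced),
        "rr_imbalanced": format_rr(summary.rr_imbalanced),
        "interaction_mean": float(summary.coefficients.loc["discordance:imbalance", "mean"]),
        "interaction_p": float(summary.coefficients.loc["discordance:imbalance", "p_value"]),
        "significant_interaction": bool(summary.significant_interaction),
        "biased_away_from_baseline": bool(summary.rr_ci_disjoint_from_baseline),
        "unreliable": bool(summary.unreliable),
    }
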