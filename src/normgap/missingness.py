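"""Wald-test comparison of fully adjusted versus covariate-reduced
models, alone and jointly with imbalanced sampling.

Covariate-availability scenarios mirror the observed patterns of wholly
unasked survey questions; each scenario removes whole covariates from the
models of the pathway it affects.  The test is a Wald test of joint
nullity of the dropped coefficients in the full model, using the
cluster-robust covariance, reported on the F scale (df_numerator = number
of coefficients dropped) with a chi-square reference.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigurationError, ModellingError
from .models import COVARIATE_DESIGN, FitResult, ModelSpec, fit_weighted_poisson

#: Survey counts per availability scenario.
SCENARIO_SURVEY_COUNTS = {1: 5, 2: 9, 3: 2, 4: 5, 5: 1, 6: 3}


@dataclass(frozen=True)
class CovariateScenario:
    """One pattern of covariate availability.

    ``unavailable`` is a tuple of ``(covariate, affected_pathways)`` pairs
    where ``affected_pathways`` is a frozenset drawn from
    ``{"female_hiv", "male_hiv"}``.
    """

    scenario_id: int
    n_surveys: int
    unavailable: tuple

    def removed_covariates(self, outcome_gender: str) -> tuple:
        tag = f"{outcome_gender}_hiv"
        return tuple(cov for cov, pathways in self.unavailable if tag in pathways)


def enumerate_scenarios() -> list[CovariateScenario]:
    """The six covariate-availability scenarios, loaded from the packaged
    CSV matrix (editable; ships the row/column reading of the pattern)."""
    path = importlib.resources.files("normgap.data").joinpath("scenarios.csv")
    with importlib.resources.as_file(path) as p:
        table = pd.read_csv(p, index_col="covariate")
    scenarios = []
    for sid, n_surveys in SCENARIO_SURVEY_COUNTS.items():
        col = table[f"scenario_{sid}"]
        unavailable = tuple(
            (cov, frozenset(val.split("|")))
            for cov, val in col.items()
            if val != "available"
        )
        scenarios.append(CovariateScenario(sid, n_surveys, unavailable))
    return scenarios


def get_scenario(scenario_id: int) -> CovariateScenario:
    for sc in enumerate_scenarios():
        if sc.scenario_id == scenario_id:
            return sc
    raise ConfigurationError(f"unknown covariate scenario id {scenario_id!r} (expected 1..6)")


@dataclass
class WaldSummary:
    """Wald comparison of a fully adjusted model against its reduced
    variant for one pathway x scenario."""

    pathway: str
    scenario_id: int
    F_statistic: float
    df_numerator: int
    reference: str  # "chi2" (normal-reference large-sample convention)
    p_value: float
    significant: bool
    removed: tuple = ()
    n_replicates: int = 1


def wald_quadratic(params: pd.Series, cov: pd.DataFrame, terms) -> tuple[float, int]:
    """Wald statistic ``beta_r' V_r^{-1} beta_r`` for joint nullity of the
    named coefficients."""
    terms = list(terms)
    beta = params.loc[terms].to_numpy(dtype=float)
    v = cov.loc[terms, terms].to_numpy(dtype=float)
    w = float(beta @ np.linalg.solve(v, beta))
    return w, len(terms)


def _removed_design_columns(spec: ModelSpec, scenario: CovariateScenario) -> list[str]:
    removed = scenario.removed_covariates(spec.outcome_gender)
    missing = set(removed) - set(spec.covariates)
    if missing:
        raise ModellingError(
            f"scenario {scenario.scenario_id} removes covariates absent from the "
            f"full model spec: {sorted(missing)}"
        )
    cols: list[str] = []
    for cov in removed:
        cols.extend(COVARIATE_DESIGN[cov])
    return cols


def _wald_from_fit(fit: FitResult, cols) -> tuple[float, int]:
    w, df = wald_quadratic(fit.params, fit.cov, cols)
    return w / df, df


def wald_full_vs_reduced(
    dataset,
    spec: ModelSpec,
    scenario: CovariateScenario,
    min_adults_per_cluster: int = 10,
    alpha: float = 0.05,
) -> WaldSummary:
    """Wald test of the coefficients a scenario would remove from one
    pathway's fully adjusted model.

    When the scenario removes nothing relevant to the pathway the defined
    no-op result (F = 0, p = 1) is returned.
    """
    cols = _removed_design_columns(spec, scenario)
    if not cols:
        return WaldSummary(spec.pathway, scenario.scenario_id, 0.0, 0, "chi2", 1.0, False)
    fit = fit_weighted_poisson(dataset, spec, min_adults_per_cluster)
    if not fit.converged:
        raise ModellingError("full model did not converge; Wald comparison unavailable")
    f_stat, df = _wald_from_fit(fit, cols)
    p = float(stats.chi2.sf(f_stat * df, df))
    return WaldSummary(
        spec.pathway,
        scenario.scenario_id,
        float(f_stat),
        df,
        "chi2",
        p,
        p < alpha,
        removed=tuple(cols),
    )


def joint_imbalance_missingness(
    replicates,
    spec: ModelSpec,
    scenario: CovariateScenario,
    min_adults_per_cluster: int = 10,
    alpha: float = 0.05,
) -> WaldSummary:
    """Apply the full-vs-reduced Wald comparison to the interaction model
    on every bootstrap replicate and summarise via the mean F statistic.

    The mean-F p-value reuses the chi-square reference applied to the mean
    (an approximation mirroring the bootstrap aggregation of the
    interaction test).
    """
    if not spec.include_interaction:
        spec = spec.with_interaction(True)
    cols = _removed_design_columns(spec, scenario)
    if not cols:
        return WaldSummary(spec.pathway, scenario.scenario_id, 0.0, 0, "chi2", 1.0, False)
    f_stats = []
    n_total = 0
    for rep in replicates:
        n_total += 1
        fit = fit_weighted_poisson(rep, spec, min_adults_per_cluster)
        if not fit.converged:
            continue
        f_stat, df = _wald_from_fit(fit, cols)
        f_stats.append(f_stat)
    if n_total < 2:
        raise ModellingError("joint test requires at least 2 replicates")
    if not f_stats:
        raise ModellingError(f"all {n_total} replicates failed to converge")
    df = len(cols)
    mean_f = float(np.mean(f_stats))
    p = float(stats.chi2.sf(mean_f * df, df))
    return WaldSummary(
        spec.pathway,
        scenario.scenario_id,
        mean_f,
        df,
        "chi2",
        p,
        p < alpha,
        removed=tuple(cols),
        n_replicates=len(f_stats),
    )
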