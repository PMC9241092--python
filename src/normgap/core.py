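"""Shared constants, exception types and weighted-statistics helpers.

Every module in :mod:`normgap` works with the same six gender-age strata
(two genders crossed with three age groups) and the same cluster-level
discordance exposure.  The definitions live here so that the generator,
the cohort-preparation code and the outcome models cannot drift apart.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VERSION = "0.1.0"

GENDERS = ("female", "male")
AGE_GROUPS = ("15-19", "20-24", "25-49")
ADOLESCENT_GROUPS = ("15-19", "20-24")
ADULT_GROUP = "25-49"

#: Stratum order used everywhere a 6-vector appears:
#: (F 15-19, F 20-24, F 25-49, M 15-19, M 20-24, M 25-49)
STRATA = tuple((g, a) for g in GENDERS for a in AGE_GROUPS)
STRATUM_LABELS = tuple(f"{g}_{a}" for g, a in STRATA)

AGE_BOUNDS = {"15-19": (15, 19), "20-24": (20, 24), "25-49": (25, 49)}

#: Pathway identifiers: first letter is the adolescent outcome gender,
#: second the adult exposure gender (e.g. "FM" = female adolescent HIV
#: regressed on male adult discordance).
PATHWAYS = ("FF", "FM", "MF", "MM")
_GENDER_CODE = {"F": "female", "M": "male"}

#: The discordance exposure is expressed per 10 percentage points so that
#: the exponentiated model coefficient reads directly as the relative risk
#: per 10-pp increase in discordance.
DISCORDANCE_SCALE = 10.0

#: Group-level survey items pooled to cluster proportions for modelling.
GROUP_ITEMS = (
    "ipv_history",
    "belief_fidelity",
    "belief_beating_justified",
    "partner_age_diff_large",
    "alcohol_before_sex",
)


class NormgapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NormgapError):
    """Invalid configuration (shares, sizes, unknown identifiers...)."""


class ParameterisationError(NormgapError):
    """Generator parameters produce an invalid risk model (probability > 1)."""


class DataError(NormgapError):
    """A dataset violates a structural precondition."""


class ModellingError(NormgapError):
    """A model cannot be specified or estimated on the given data."""


def pathway_genders(pathway: str) -> tuple[str, str]:
    """Return ``(outcome_gender, exposure_gender)`` for a pathway id."""
    if pathway not in PATHWAYS:
        raise ConfigurationError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    return _GENDER_CODE[pathway[0]], _GENDER_CODE[pathway[1]]


def pathway_id(outcome_gender: str, exposure_gender: str) -> str:
    codes = {v: k for k, v in _GENDER_CODE.items()}
    return codes[outcome_gender] + codes[exposure_gender]


def age_group_of(age_years: np.ndarray | pd.Series) -> pd.Series:
    """Map integer ages in [15, 49] to the three analysis age groups."""
    age = pd.Series(np.asarray(age_years))
    out = pd.Series(pd.NA, index=age.index, dtype="object")
    for group, (lo, hi) in AGE_BOUNDS.items():
        out[(age >= lo) & (age <= hi)] = group
    if out.isna().any():
        bad = age[out.isna()].unique()
        raise DataError(f"ages outside the 15-49 design range: {bad!r}")
    return out


def weighted_proportion(values: pd.Series, weights: pd.Series) -> float:
    """Weighted share of True among non-missing boolean responses.

    Returns NaN when every response is missing.
    """
    mask = values.notna()
    if not mask.any():
        return float("nan")
    v = values[mask].astype(float)
    w = weights[mask].astype(float)
    return float(np.average(v, weights=w))


def discordance_gap(attitude_prop: float, behaviour_prop: float) -> float:
    """Attitude-behaviour discordance on the raw proportion scale.

    Defined as the apparent pre-marital-sex behaviour share minus the
    professed approval share (one minus the disapproval share).  Perfect
    concordance -- everyone disapproves, nobody does it -- gives 0.  The
    definition is deliberately isolated here so it can be swapped without
    touching any caller.
    """
    return behaviour_prop - (1.0 - attitude_prop)


def discordance_10pp(attitude_prop, behaviour_prop):
    """Discordance in 10-percentage-point units (the modelling scale)."""
    return DISCORDANCE_SCALE * discordance_gap(attitude_prop, behaviour_prop)
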