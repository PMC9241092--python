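"""Resampling with replacement to a target gender-age distribution, with
design-weight recalculation, plus construction of bootstrap merged
datasets carrying the imbalance indicator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GenderAgeDistribution, SurveyDataset
from .core import STRATA, ConfigurationError, DataError


@dataclass(frozen=True)
class ResampleSpec:
    """Target distribution and bootstrap settings for one survey scenario."""

    target: GenderAgeDistribution
    n_bootstrap: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")


@dataclass
class MergedDataset:
    """Balanced dataset stacked with one resampled dataset.

    The ``imbalance`` column is 0 for balanced-origin rows and 1 for
    resampled-origin rows; resampled rows carry recalculated weights.
    """

    respondents: pd.DataFrame
    metadata: dict

    @property
    def n(self) -> int:
        return len(self.respondents)


def weight_recalculation_factor(n_source: int, n_drawn: int) -> float:
    """Per-stratum weight rescaling applied to resampled records.

    ``w' = w * (N_s / m_s)`` inverts each record's expected resampling
    multiplicity, so the expected recalculated weight mass of a stratum
    equals its source weighted total.  Isolated here so the formula can be
    replaced wholesale.
    """
    return n_source / n_drawn


def replicate_seed(base_seed: int, b: int) -> int:
    """Deterministic, collision-resistant per-replicate seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(b,))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def resample_to_distribution(
    balanced: SurveyDataset, target: GenderAgeDistribution, seed: int
) -> SurveyDataset:
    """Draw, uniformly with replacement within each gender-age stratum,
    exactly the target count of respondents, rescaling their weights.

    Cluster/stratum design columns (and any attached cluster-level
    exposure columns) are preserved from the source records.
    """
    df = balanced.respondents
    rng = np.random.default_rng(seed)
    parts = []
    factors = {}
    for (g, a) in STRATA:
        m = int(target.counts.loc[(g, a)])
        if m == 0:
            continue
        src = df[(df["gender"] == g) & (df["age_group"] == a)]
        n_s = len(src)
        if n_s == 0:
            raise DataError(
                f"target requires {m} records in stratum {g}_{a} but the source has none"
            )
        idx = rng.integers(0, n_s, size=m)
        part = src.iloc[idx].copy()
        factor = weight_recalculation_factor(n_s, m)
        part["design_weight"] = part["design_weight"] * factor
        factors[f"{g}_{a}"] = factor
        parts.append(part)
    if not parts:
        out = df.iloc[0:0].copy()
    else:
        out = pd.concat(parts, ignore_index=True)
    meta = dict(balanced.metadata)
    meta.update(
        {
            "source": "simulated_imbalanced",
            "resample_seed": int(seed),
            "weight_factors": factors,
        }
    )
    return SurveyDataset(out, meta)


def make_merged(balanced: SurveyDataset, resampled: SurveyDataset) -> MergedDataset:
    """Stack the balanced dataset with a resampled one under an imbalance
    indicator, disambiguating record ids."""
    if balanced.metadata.get("source") == resampled.metadata.get("source"):
        raise DataError("balanced and resampled parts must carry distinct provenance labels")
    bal = balanced.respondents.copy()
    res = resampled.respondents.copy()
    bal["imbalance"] = 0
    res["imbalance"] = 1
    bal["respondent_id"] = "b:" + bal["respondent_id"].astype(str)
    res["respondent_id"] = [f"r:{i}:{rid}" for i, rid in enumerate(res["respondent_id"])]
    merged = pd.concat([bal, res], ignore_index=True)
    if merged["respondent_id"].duplicated().any():
        raise DataError("record ids remain ambiguous after disambiguation")
    meta = {
        "balanced": dict(balanced.metadata),
        "resampled": dict(resampled.metadata),
        "n_balanced": len(bal),
        "n_resampled": len(res),
    }
    return MergedDataset(merged, meta)


def bootstrap_merged(balanced: SurveyDataset, spec: ResampleSpec) -> list[MergedDataset]:
    """The bootstrap series of merged datasets (replicate b is seeded
    deterministically from ``(base_seed, b)``, so any replicate can be
    regenerated in isolation)."""
    return list(iter_bootstrap_merged(balanced, spec))


def iter_bootstrap_merged(balanced: SurveyDataset, spec: ResampleSpec):
    """Lazy variant of :func:`bootstrap_merged`."""
    if spec.n_bootstrap < 1:
        raise ConfigurationError("n_bootstrap must be >= 1")
    for b in range(spec.n_bootstrap):
        res = resample_to_distribution(balanced, spec.target, replicate_seed(spec.base_seed, b))
        merged = make_merged(balanced, res)
        merged.metadata["replicate"] = b
        yield merged
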