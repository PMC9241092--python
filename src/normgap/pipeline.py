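"""End-to-end orchestration: generate/load -> eligibility -> discordance
-> per-target bootstrap -> interaction tests -> missingness tests ->
inter-survey meta-analysis, with deterministic seeding and diff-stable
outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, intersurvey, missingness, models, resampling, synthetic
from .core import VERSION, ConfigurationError, NormgapError

log = logging.getLogger("normgap")

_CSV_FLOAT_FORMAT = "%.6g"

INTERACTION_COLUMNS = (
    "survey_id",
    "pathway",
    "beta_discordance_mean",
    "beta_discordance_sd",
    "beta_discordance_p",
    "beta_imbalance_mean",
    "beta_imbalance_sd",
    "beta_imbalance_p",
    "beta_interaction_mean",
    "beta_interaction_sd",
    "beta_interaction_p",
    "rr_balanced",
    "rr_balanced_lower",
    "rr_balanced_upper",
    "rr_imbalanced",
    "rr_imbalanced_lower",
    "rr_imbalanced_upper",
    "significant_interaction",
    "biased_away_from_baseline",
    "n_replicates",
    "n_dropped",
    "unreliable",
)


class PipelineError(NormgapError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one full experiment run."""

    generator: dict = field(default_factory=dict)
    input_path: str | None = None
    targets: list = field(default_factory=lambda: ["MAI06"])
    pathways: list = field(default_factory=lambda: list(models.PATHWAYS))
    scenarios: list = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    n_bootstrap: int = 100
    base_seed: int = 0
    output_dir: str = "normgap-run"
    alpha: float = 0.05
    min_adults_per_cluster: int = 10
    target_size: int | None = None
    joint_missingness: bool = False
    run_intersurvey: bool = True

    def validate(self) -> None:
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("significance level must be in (0, 1)")
        for p in self.pathways:
            if p not in models.PATHWAYS:
                raise ConfigurationError(f"unknown pathway {p!r}")
        for s in self.scenarios:
            missingness.get_scenario(int(s))
        for ref in self.targets:
            _resolve_target_ref(ref)
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigurationError(f"input dataset not found: {self.input_path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_target_ref(ref) -> None:
    if isinstance(ref, str) and Path(ref).suffix == ".csv":
        if not Path(ref).exists():
            raise ConfigurationError(f"target file not found: {ref}")
    else:
        synthetic.get_preset(str(ref))


def _resolve_target(ref) -> tuple[str, pd.Series]:
    """A target reference is a preset id or a CSV path holding the
    6-stratum proportions (columns gender, age_group, proportion)."""
    if isinstance(ref, str) and Path(ref).suffix == ".csv":
        if not Path(ref).exists():
            raise ConfigurationError(f"target file not found: {ref}")
        table = pd.read_csv(ref)
        props = table.set_index(["gender", "age_group"])["proportion"]
        return Path(ref).stem, props
    preset = synthetic.get_preset(str(ref))
    return preset.preset_id, preset.proportions()


def load_survey_csv(path) -> cohort.SurveyDataset:
    """Read a respondent table written by :func:`write_survey_csv`."""
    df = pd.read_csv(path)
    for col in cohort._BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map({True: True, False: False, "True": True, "False": False})
            df[col] = pd.array(df[col], dtype="boolean")
    return cohort.SurveyDataset(df, {"provenance": str(path), "source": "balanced"})


def write_survey_csv(dataset: cohort.SurveyDataset, path) -> None:
    dataset.respondents.to_csv(path, index=False)


def run_pipeline(config: RunConfig, quiet: bool = False) -> Path:
    """Execute the full experiment; returns the output directory.

    Any stage failure is re-raised as :class:`PipelineError` carrying the
    stage name; partial outputs are retained next to an ``INCOMPLETE``
    marker.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    stage = "config"
    try:
        config.validate()
        seed_root = np.random.SeedSequence(config.base_seed)
        gen_seed = int(seed_root.generate_state(1, dtype=np.uint64)[0])

        stage = "generate"
        if config.input_path:
            balanced = load_survey_csv(config.input_path)
            truth = None
        else:
            gen_cfg = synthetic.GeneratorConfig(**{**config.generator, "seed": gen_seed})
            balanced, truth = synthetic.generate_survey(gen_cfg)

        stage = "eligibility"
        eligible = cohort.filter_eligible(balanced)

        stage = "discordance"
        disc = cohort.compute_discordance(eligible, config.min_adults_per_cluster)
        attached = cohort.attach_cluster_context(eligible, disc, config.min_adults_per_cluster)
        balanced_dist = cohort.compute_distribution(eligible)

        stage = "interaction"
        interaction_rows = []
        records = []
        target_seeds = {}
        n_target = config.target_size or eligible.n
        for t_idx, ref in enumerate(config.targets):
            target_id, props = _resolve_target(ref)
            target = cohort.GenderAgeDistribution.from_proportions(props, n_target)
            t_seed = int(
                np.random.SeedSequence(config.base_seed, spawn_key=(1, t_idx)).generate_state(
                    1, dtype=np.uint64
                )[0]
            )
            target_seeds[target_id] = t_seed
            spec_rs = resampling.ResampleSpec(target, config.n_bootstrap, t_seed)
            for pathway in config.pathways:
                mspec = models.ModelSpec.canonical(pathway, include_interaction=True)
                summary = models.interaction_test_fast(
                    attached,
                    spec_rs,
                    mspec,
                    config.min_adults_per_cluster,
                    config.alpha,
                    survey_id=target_id,
                )
                c = summary.coefficients
                interaction_rows.append(
                    {
                        "survey_id": target_id,
                        "pathway": pathway,
                        "beta_discordance_mean": c.loc["discordance", "mean"],
                        "beta_discordance_sd": c.loc["discordance", "sd"],
                        "beta_discordance_p": c.loc["discordance", "p_value"],
                        "beta_imbalance_mean": c.loc["imbalance", "mean"],
                        "beta_imbalance_sd": c.loc["imbalance", "sd"],
                        "beta_imbalance_p": c.loc["imbalance", "p_value"],
                        "beta_interaction_mean": c.loc["discordance:imbalance", "mean"],
                        "beta_interaction_sd": c.loc["discordance:imbalance", "sd"],
                        "beta_interaction_p": c.loc["discordance:imbalance", "p_value"],
                        "rr_balanced": summary.rr_balanced[0],
                        "rr_balanced_lower": summary.rr_balanced[1],
                        "rr_balanced_upper": summary.rr_balanced[2],
                        "rr_imbalanced": summary.rr_imbalanced[0],
                        "rr_imbalanced_lower": summary.rr_imbalanced[1],
                        "rr_imbalanced_upper": summary.rr_imbalanced[2],
                        "significant_interaction": summary.significant_interaction,
                        "biased_away_from_baseline": summary.rr_ci_disjoint_from_baseline,
                        "n_replicates": summary.n_replicates,
                        "n_dropped": summary.n_dropped,
                        "unreliable": summary.unreliable,
                    }
                )
                records.append(
                    {
                        "survey_id": target_id,
                        "pathway": pathway,
                        "adolescent_female_share": target.adolescent_share("female"),
                        "adolescent_male_share": target.adolescent_share("male"),
                        "male_share_total": target.male_share(),
                        "significant_interaction": int(summary.significant_interaction),
                        "interaction_coef": c.loc["discordance:imbalance", "mean"],
                        "rr": summary.rr_imbalanced[0],
                    }
                )
        interaction_df = pd.DataFrame(interaction_rows, columns=list(INTERACTION_COLUMNS))
        _write_csv(interaction_df, out / "interaction_summary.csv")
        _write_csv(pd.DataFrame(records, columns=list(intersurvey.RECORD_COLUMNS)),
                   out / "intersurvey_records.csv")

        stage = "missingness"
        wald_rows = []
        for sid in config.scenarios:
            scenario = missingness.get_scenario(int(sid))
            for pathway in config.pathways:
                mspec = models.ModelSpec.canonical(pathway)
                ws = missingness.wald_full_vs_reduced(
                    attached, mspec, scenario, config.min_adults_per_cluster, config.alpha
                )
                wald_rows.append(
                    {
                        "scenario_id": ws.scenario_id,
                        "pathway": ws.pathway,
                        "F_statistic": ws.F_statistic,
                        "df_numerator": ws.df_numerator,
                        "p_value": ws.p_value,
                        "significant": ws.significant,
                    }
                )
        _write_csv(pd.DataFrame(wald_rows), out / "wald_balanced.csv")

        if config.joint_missingness:
            stage = "missingness-joint"
            joint_rows = []
            for t_idx, ref in enumerate(config.targets):
                target_id, props = _resolve_target(ref)
                target = cohort.GenderAgeDistribution.from_proportions(props, n_target)
                spec_rs = resampling.ResampleSpec(
                    target, config.n_bootstrap, target_seeds[target_id]
                )
                for sid in config.scenarios:
                    scenario = missingness.get_scenario(int(sid))
                    for pathway in config.pathways:
                        mspec = models.ModelSpec.canonical(pathway, include_interaction=True)
                        ws = missingness.joint_imbalance_missingness(
                            resampling.iter_bootstrap_merged(attached, spec_rs),
                            mspec,
                            scenario,
                            config.min_adults_per_cluster,
                            config.alpha,
                        )
                        joint_rows.append(
                            {
                                "survey_id": target_id,
                                "scenario_id": ws.scenario_id,
                                "pathway": ws.pathway,
                                "F_statistic": ws.F_statistic,
                                "df_numerator": ws.df_numerator,
                                "p_value": ws.p_value,
                                "significant": ws.significant,
                                "n_replicates": ws.n_replicates,
                            }
                        )
            _write_csv(pd.DataFrame(joint_rows), out / "wald_joint.csv")

        stage = "intersurvey"
        if config.run_intersurvey and len(config.targets) >= 10:
            rec_df = pd.DataFrame(records)
            logit = intersurvey.fit_significance_logit(rec_df)
            linear = intersurvey.fit_outcome_linear(rec_df)
            _write_csv(logit.frame, out / "intersurvey_logit.csv")
            _write_csv(linear.frame, out / "intersurvey_linear.csv")

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "version": VERSION,
            "generator_seed": gen_seed,
            "target_seeds": target_seeds,
            "n_eligible": eligible.n,
            "eligibility_removed": eligible.metadata.get("eligibility_removed"),
            "balanced_male_share": balanced_dist.male_share(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

        stage = "report"
        marker.unlink(missing_ok=True)
        (out / "report.txt").write_text(render_report(out))
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        if stage == "report":
            marker.write_text("report stage failed\n")
        raise PipelineError(stage, str(exc)) from exc
    if not quiet:
        log.info("run complete: %s", out)
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def render_report(out_dir) -> str:
    """Human-readable roll-up of a results directory.

    Regeneration is idempotent; incomplete bundles yield a partial report
    with warnings rather than an error.
    """
    out = Path(out_dir)
    lines = ["normgap run report", "=" * 40]
    inter_path = out / "interaction_summary.csv"
    if inter_path.exists():
        inter = pd.read_csv(inter_path)
        lines.append("")
        lines.append("Interaction tests (per pathway):")
        for pathway, grp in inter.groupby("pathway", sort=True):
            n = len(grp)
            n_sig = int(grp["significant_interaction"].sum())
            n_bias = int(grp["biased_away_from_baseline"].sum())
            lines.append(
                f"  {pathway}: {n_sig}/{n} scenarios with significant interaction; "
                f"{n_bias}/{n} with RR CI excluding the balanced point estimate"
            )
    else:
        lines.append("WARNING: interaction summary missing (incomplete run)")
    wald_path = out / "wald_balanced.csv"
    if wald_path.exists():
        wald = pd.read_csv(wald_path)
        lines.append("")
        lines.append("Missing-covariate Wald tests on the balanced dataset:")
        for pathway, grp in wald.groupby("pathway", sort=True):
            n_sig = int(grp["significant"].sum())
            lines.append(f"  {pathway}: {n_sig}/{len(grp)} scenarios with significant fit change")
    else:
        lines.append("WARNING: Wald summary missing (incomplete run)")
    for name, label in (
        ("intersurvey_logit.csv", "Inter-survey logistic fits"),
        ("intersurvey_linear.csv", "Inter-survey linear fits"),
    ):
        path = out / name
        if path.exists():
            table = pd.read_csv(path)
            lines.append("")
            lines.append(f"{label}:")
            for _, row in table.iterrows():
                outcome = f" {row['outcome']}" if "outcome" in table.columns else ""
                flag = row.get("flag", "")
                if isinstance(flag, str) and flag:
                    est = flag
                else:
                    est = f"{row['estimate']:.4g} ({row['ci_lower']:.4g}, {row['ci_upper']:.4g})"
                lines.append(f"  {row['pathway']}{outcome} ~ {row['predictor']}: {est}")
    if (out / "INCOMPLETE").exists():
        lines.append("")
        lines.append("WARNING: run marked incomplete")
    return "\n".join(lines) + "\n"
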