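"""End-to-end orchestration: simulate (or load) -> screen -> measure ->
fit -> compare -> report, with a flat YAML config and full seeded
reproducibility.

Given one seed the whole run is deterministic: the same config produces
byte-identical report bodies.  The report carries a provenance block
(config hash, seed, package version) so every number can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, production, reproduction, synthetic

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "validate_config",
    "run_pipeline",
    "load_config",
    "save_config",
    "default_models",
]

logger = logging.getLogger(__name__)

MEASURE_CHOICES = ("sd", "rmsr", "scaled_rmsr")


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the task's design constants as
    defaults: two start-up trials, a 3-s / 5-trial aberrance screen, a
    (0.5 s, 2.5 s) response-time outlier window, and centering on 1.4 s."""

    seed: int = 0
    # input generation
    generate: bool = True
    n_participants: int = 63
    n_production_trials: int = 20
    hyperparams: dict = field(default_factory=dict)
    production_csv: str | None = None
    reproduction_csv: str | None = None
    # production processing
    n_startup: int = 2
    screening_limit: float = 3.0
    screening_min_count: int = 5
    # reproduction processing
    outlier_low: float = 0.5
    outlier_high: float = 2.5
    center_reference: float = 1.4
    # reproduction design
    n_blocks: int = 2
    trials_per_block: int = 120
    duration_levels: tuple = (1.17, 1.4, 1.68)
    presentations_per_level_per_block: int = 40
    # inference
    measure: str = "scaled_rmsr"
    bf_backend: str = "quadrature"
    r_fixed: float = bayes.DEFAULT_FIXED_SCALE
    r_random: float = bayes.DEFAULT_RANDOM_SCALE
    corr_kappa: float = 1.0
    credible_level: float = 0.90
    # outputs
    out_dir: str | None = None
    figures: bool = False

    def design(self) -> synthetic.TaskDesign:
        return synthetic.TaskDesign(
            n_blocks=self.n_blocks,
            trials_per_block=self.trials_per_block,
            duration_levels=tuple(float(d) for d in self.duration_levels),
            presentations_per_level_per_block=self.presentations_per_level_per_block,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["duration_levels"] = list(self.duration_levels)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violation messages; empty iff the config is valid."""
    v: list[str] = []
    if config.n_participants < 0:
        v.append("n_participants: must be >= 0")
    if config.n_startup < 0:
        v.append("n_startup: must be >= 0")
    if config.n_production_trials <= config.n_startup:
        v.append("n_production_trials: must exceed n_startup")
    if config.screening_limit <= 0:
        v.append("screening_limit: must be positive")
    if config.screening_min_count < 1:
        v.append("screening_min_count: must be >= 1")
    if not (0 < config.outlier_low < config.outlier_high):
        v.append("outlier_low/outlier_high: need 0 < low < high")
    if config.center_reference <= 0:
        v.append("center_reference: must be positive")
    if config.measure not in MEASURE_CHOICES:
        v.append(f"measure: must be one of {MEASURE_CHOICES}")
    if config.bf_backend not in ("quadrature", "bic"):
        v.append("bf_backend: must be 'quadrature' or 'bic'")
    for name in ("r_fixed", "r_random", "corr_kappa"):
        if getattr(config, name) <= 0:
            v.append(f"{name}: must be positive")
    if not 0 < config.credible_level < 1:
        v.append("credible_level: must be in (0, 1)")
    try:
        config.design()
    except ValueError as err:
        v.append(f"design: {err}")
    try:
        rng = np.random.default_rng(0)
        for name, spec in config.hyperparams.items():
            if name not in synthetic.DEFAULT_HYPERPARAMS:
                raise ValueError(f"unknown hyperparameter {name!r}")
            synthetic._sample_field(name, spec, 1, rng)
    except ValueError as err:
        v.append(f"hyperparams: {err}")
    if not config.generate and not (config.production_csv and config.reproduction_csv):
        v.append("production_csv/reproduction_csv: required when generate is off")
    return v


def default_models(include_order: bool = True) -> list[bayes.ModelSpec]:
    """The nested model ladder of the analysis, baseline first."""
    models = [
        bayes.ModelSpec("intercept_only", {"intercept"}),
        bayes.ModelSpec("duration", {"intercept", "presented_duration"}),
    ]
    if include_order:
        models.append(
            bayes.ModelSpec(
                "duration_order", {"intercept", "presented_duration", "order"}
            )
        )
    models.append(
        bayes.ModelSpec(
            "duration_measure",
            {"intercept", "presented_duration", "measure", "measure:presented_duration"},
        )
    )
    models.append(
        bayes.ModelSpec(
            "full",
            {"intercept", "presented_duration", "order", "measure",
             "measure:presented_duration"},
        )
    )
    return models


@dataclass
class AnalysisReport:
    """Everything one run computes, plus provenance."""

    provenance: dict
    screening: dict
    filter_summary: dict
    measures: pd.DataFrame
    fits: pd.DataFrame
    condition_means: pd.DataFrame
    drift_test: bayes.BayesFactorResult
    correlation: bayes.CorrelationResult
    model_comparison: bayes.ModelComparisonResult
    headline: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "screening": self.screening,
            "filter_summary": self.filter_summary,
            "drift_test": {
                "bf10": self.drift_test.bf10,
                "log_bf10": self.drift_test.log_bf10,
                "label": self.drift_test.interpretation_label,
            },
            "correlation": {
                "bf10": self.correlation.bf10,
                "log_bf10": self.correlation.log_bf10,
                "posterior_median_r": self.correlation.posterior_median_r,
                "posterior_mad": self.correlation.posterior_mad,
                "credible_interval": list(self.correlation.credible_interval),
                "credible_level": self.correlation.credible_level,
                "label": self.correlation.interpretation_label,
            },
            "model_comparison": self.model_comparison.table.to_dict(orient="records"),
            "headline": self.headline,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        h = self.headline
        corr = self.correlation
        lines = [
            "clockvar analysis report",
            f"  config hash: {self.provenance['config_hash']}  seed: {self.provenance['seed']}",
            f"  participants: {self.screening['n_input']} in, "
            f"{self.screening['n_kept']} kept, {self.screening['n_excluded']} excluded",
            f"  reproduction outliers removed: {self.filter_summary['n_removed']} of "
            f"{self.filter_summary['n_input']} "
            f"({100 * self.filter_summary['proportion_removed']:.2f}%)",
            f"  mean scaled RMSR: {h['mean_scaled_rmsr']:.4f}",
            f"  drift (one-sample test on |slope|): BF10 = "
            f"{self.drift_test.bf10:.4g} [{self.drift_test.interpretation_label}]",
            f"  mean central-tendency slope: {h['mean_slope']:.4f}",
            f"  scaled RMSR vs slope: r_median = {corr.posterior_median_r:.3f}, "
            f"MAD = {corr.posterior_mad:.3f}, "
            f"{int(corr.credible_level * 100)}% CI ({corr.credible_interval[0]:.3f}, "
            f"{corr.credible_interval[1]:.3f}), BF10 = {corr.bf10:.4g} "
            f"[{corr.interpretation_label}]",
            self.model_comparison.to_text(),
        ]
        return "\n".join(lines) + "\n"


def _load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    if config.generate:
        if config.n_participants == 0:
            raise ValueError("generator enabled but n_participants is 0")
        rng = np.random.default_rng(config.seed)
        s_pop, s_cohort = (int(s) for s in rng.integers(0, 2**31, size=2))
        participants = synthetic.sample_participants(
            config.n_participants, config.hyperparams or None, seed=s_pop
        )
        prod, repr_ = synthetic.simulate_cohort(
            participants,
            design=config.design(),
            n_production_trials=config.n_production_trials,
            n_startup=config.n_startup,
            seed=s_cohort,
        )
        return prod, repr_, synthetic.participants_to_frame(participants)
    if not (config.production_csv and config.reproduction_csv):
        raise ValueError("no input CSVs given and generator disabled")
    prod = synthetic.read_production_csv(config.production_csv)
    repr_ = synthetic.read_reproduction_csv(config.reproduction_csv)
    if prod.empty or repr_.empty:
        raise ValueError("input CSVs contain no trials")
    return prod, repr_, None


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis and (optionally) write per-stage artifacts."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))

    prod_raw, repr_raw, truth = _load_inputs(config)
    n_input = prod_raw["participant_id"].nunique()

    # production branch: start-up removal -> screening -> variability measures
    prod = production.remove_startup(prod_raw, config.n_startup)
    screening = production.screen_participants(
        prod, limit=config.screening_limit, min_count=config.screening_min_count
    )
    prod_kept = prod[prod["participant_id"].isin(screening.kept_ids)]
    measures = production.summarize_cohort(prod_kept)

    # reproduction branch: outlier filter -> centering -> per-participant slopes
    repr_kept = repr_raw[repr_raw["participant_id"].isin(screening.kept_ids)]
    repr_filtered, fsummary = reproduction.filter_outliers(
        repr_kept, low=config.outlier_low, high=config.outlier_high
    )
    cond_means = reproduction.condition_means(repr_filtered)
    centered = reproduction.center_durations(repr_filtered, config.center_reference)
    fits = reproduction.fit_cohort(centered)

    # inference: correlation of the clock measure with the slope, and the
    # nested mixed-model ladder
    joined = measures.merge(fits, on="participant_id", how="inner")
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} participants with both measures and fits; "
            "cannot run inference"
        )
    drift_test = bayes.bf_one_sample(np.abs(joined["drift_slope"]), 0.0)
    corr = bayes.bf_correlation(
        joined[config.measure], joined["slope"],
        kappa=config.corr_kappa, credible_level=config.credible_level,
    )
    model_data = centered.merge(
        measures[["participant_id", config.measure]].rename(
            columns={config.measure: "measure"}
        ),
        on="participant_id",
        how="inner",
    )
    include_order = model_data["order_condition"].nunique() > 1
    comparison = bayes.bf_model_comparison(
        model_data,
        default_models(include_order=include_order),
        r_fixed=config.r_fixed,
        r_random=config.r_random,
        backend=config.bf_backend,
    )

    headline = {
        "n_participants_analyzed": int(len(joined)),
        "mean_scaled_rmsr": float(joined["scaled_rmsr"].mean())
        if "scaled_rmsr" in joined else float("nan"),
        "mean_slope": float(joined["slope"].mean()),
        "correlation_median_r": corr.posterior_median_r,
        "correlation_bf10": corr.bf10,
        "log_bf_measure_vs_duration": comparison.log_bf("duration_measure", "duration"),
    }
    report = AnalysisReport(
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": _package_version(),
        },
        screening={
            "n_input": int(n_input),
            "n_kept": len(screening.kept_ids),
            "n_excluded": len(screening.excluded_ids),
            "excluded_ids": sorted(screening.excluded_ids),
        },
        filter_summary={
            "n_input": fsummary.n_input,
            "n_removed": fsummary.n_removed,
            "proportion_removed": fsummary.proportion_removed,
        },
        measures=measures,
        fits=fits,
        condition_means=cond_means,
        drift_test=drift_test,
        correlation=corr,
        model_comparison=comparison,
        headline=headline,
    )

    if config.out_dir:
        _write_artifacts(config, report, prod_raw, repr_raw, truth, screening)
    return report


def _write_artifacts(config, report, prod_raw, repr_raw, truth, screening) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.generate:
        synthetic.write_production_csv(prod_raw, out / "production_trials.csv")
        synthetic.write_reproduction_csv(repr_raw, out / "reproduction_trials.csv")
        if truth is not None:
            truth.to_csv(out / "participant_params.csv", index=False, float_format="%.9f")
    production.write_measures_csv(report.measures, out / "production_measures.csv")
    production.write_screening_csv(screening, out / "screening_report.csv")
    reproduction.write_fits_csv(report.fits, out / "central_tendency_fits.csv")
    report.condition_means.to_csv(out / "condition_means.csv", index=False,
                                  float_format="%.9f")
    report.model_comparison.table.to_csv(out / "model_comparison.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
    save_config(config, out / "config_used.yaml")
    if config.figures:
        _write_figures(report, out)
    logger.info("wrote artifacts to %s", out)


def _write_figures(report: AnalysisReport, out: Path) -> None:
    """Cosmetic summary plots (condition means; measure vs slope)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for order, grp in report.condition_means.groupby("order_condition"):
        ax.plot(grp["presented_duration_s"], grp["mean_reproduced_s"],
                marker="o", label=order)
    lims = [report.condition_means["presented_duration_s"].min() - 0.1,
            report.condition_means["presented_duration_s"].max() + 0.1]
    ax.plot(lims, lims, ":", color="gray", label="veridical")
    ax.set_xlabel("presented duration (s)")
    ax.set_ylabel("mean reproduced duration (s)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "condition_means.png", dpi=120)
    plt.close(fig)

    merged = report.measures.merge(report.fits, on="participant_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(merged["scaled_rmsr"], merged["slope"], s=18)
    ax.set_xlabel("scaled RMSR")
    ax.set_ylabel("central-tendency slope")
    fig.tight_layout()
    fig.savefig(out / "measure_vs_slope.png", dpi=120)
    plt.close(fig)


def _package_version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# Flat YAML config I/O
# ---------------------------------------------------------------------------


def load_config(path) -> PipelineConfig:
    """Read a flat ``key: value`` YAML config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "duration_levels" in raw:
        raw["duration_levels"] = tuple(raw["duration_levels"])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )
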