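"""Consolidated analysis runs and machine-readable outputs.

`run_full_analysis` chains the pipeline stages in a fixed order —
study table, frequentist synthesis, Beta–Binomial empirical Bayes,
hierarchical logit MCMC — and returns one JSON-serializable report
validated against the pydantic schema shipped with the package
(``data/report.schema.json``).  Every stochastic block carries its seed
and draw count.  Forest- and funnel-plot data are exported as CSV; no
plotting happens here.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import asdict
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, bayes_betabinom, bayes_logit, freq_meta, study_table
from .errors import ConsistencyError, InsufficientStudiesError
from .freq_meta import PooledResult, TransformedEffect
from .study_table import StudyTable, crude_pooled_proportion

__all__ = [
    "AnalysisConfig",
    "Report",
    "run_full_analysis",
    "export_forest_data",
    "export_funnel_data",
    "report_json_schema",
]


class AnalysisConfig(BaseModel):
    """Configuration mirroring the YAML config file; flags override fields."""

    model_config = ConfigDict(frozen=True)

    input: str = "bundled"  # "bundled" or a CSV path
    schema_mode: str = "strict"
    run_frequentist: bool = True
    run_beta_binomial: bool = True
    run_logit_mcmc: bool = True
    thresholds: tuple[float, ...] = (0.02, 0.03)
    predictive_sizes: tuple[int, ...] = (100, 200, 300)
    mu_prior_mean: float = float(bayes_logit.LogitModelSpec().mu_prior_mean)
    mu_prior_sd: float = 1.5
    tau_prior_family: str = "half_normal"
    tau_prior_scale: float = 0.5
    chains: int = 4
    iterations: int = 2000
    mc_draws: int = 100_000
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        if any(s < 1 for s in self.predictive_sizes):
            raise ValueError("predictive sizes must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def logit_spec(self) -> bayes_logit.LogitModelSpec:
        return bayes_logit.LogitModelSpec(
            mu_prior_mean=self.mu_prior_mean,
            mu_prior_sd=self.mu_prior_sd,
            tau_prior=(self.tau_prior_family, self.tau_prior_scale),
            chains=self.chains,
            iterations=self.iterations,
            seed=self.seed,
        )


class CrudeBlock(BaseModel):
    estimate: float
    ci_low: float
    ci_high: float
    events: int
    n: int
    ci_method: str


class PooledBlock(BaseModel):
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    method: str
    k: int
    n_harmonic: float
    t_bar: float
    se_t: float
    back_transform: str
    label: str
    fixed_fallback: bool


class EggerBlock(BaseModel):
    intercept: float
    se_intercept: float
    t_stat: float
    p_value: float
    k: int


class FrequentistSection(BaseModel):
    fixed: PooledBlock
    random_dl: PooledBlock
    egger: EggerBlock
    leave_one_out: list[PooledBlock]
    subgroups: dict[str, PooledBlock]


class BetaBinomSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    a_hat: float
    b_hat: float
    max_marginal_loglik: Optional[float]
    population_mean: float
    quantiles: dict[str, float]
    threshold_probs: dict[str, float]
    shrinkage: list[dict[str, Any]]
    ppc_fraction_inside: float
    ppc_table: list[dict[str, Any]]
    predictive: dict[str, dict[str, Any]]
    subgroups: dict[str, dict[str, Any]]


class LogitSection(BaseModel):
    mean: float
    median: float
    ci_low: float
    ci_high: float
    threshold_probs: dict[str, float]
    rhat: dict[str, float]
    ess: dict[str, float]
    seed: int
    n_draws: int
    chains: int
    iterations: int


class Report(BaseModel):
    package_version: str
    timestamp: str
    seed: int
    config: dict[str, Any]
    crude: dict[str, CrudeBlock]
    frequentist: Optional[FrequentistSection] = None
    beta_binomial: Optional[BetaBinomSection] = None
    logit_mcmc: Optional[LogitSection] = None
    errors: dict[str, str] = Field(default_factory=dict)


def report_json_schema() -> dict:
    return Report.model_json_schema()


def _crude_section(table: StudyTable) -> dict[str, CrudeBlock]:
    out = {
        "table_counts": crude_pooled_proportion(table.total_events, table.total_n),
        "text_totals": crude_pooled_proportion(
            study_table.TEXT_TOTAL_EVENTS, study_table.TEXT_TOTAL_PATIENTS
        ),
        "no_dopamine_text": crude_pooled_proportion(
            study_table.TEXT_NO_DOPAMINE_EVENTS, study_table.TEXT_NO_DOPAMINE_PATIENTS
        ),
    }
    return {k: CrudeBlock(**asdict(v)) for k, v in out.items()}


def _frequentist_section(table: StudyTable) -> FrequentistSection:
    effects = freq_meta.transform_table(table)
    subgroups = {}
    for label, selector in (
        ("design_prospective", freq_meta.by_design("prospective")),
        ("design_retrospective", freq_meta.by_design("retrospective")),
        ("bias_low", freq_meta.by_bias_class("low")),
        ("exclude_small_n20", freq_meta.min_n(20)),
    ):
        try:
            res = freq_meta.subgroup_pool(table, selector, label=label)
        except InsufficientStudiesError:
            continue
        subgroups[label] = PooledBlock(**asdict(res))
    return FrequentistSection(
        fixed=PooledBlock(**asdict(freq_meta.pool_fixed(effects))),
        random_dl=PooledBlock(**asdict(freq_meta.pool_random_dl(effects))),
        egger=EggerBlock(**asdict(freq_meta.egger_test(effects))),
        leave_one_out=[
            PooledBlock(**asdict(r)) for r in freq_meta.leave_one_out(table)
        ],
        subgroups=subgroups,
    )


def _betabinom_section(table: StudyTable, config: AnalysisConfig) -> BetaBinomSection:
    fit = bayes_betabinom.fit_empirical_bayes(table)
    pop = bayes_betabinom.population_summary(fit, thresholds=config.thresholds)
    ppc = bayes_betabinom.posterior_predictive_check(fit, table)
    predictive = {}
    for n_f in config.predictive_sizes:
        pred = bayes_betabinom.predictive_distribution(fit, n_f)
        predictive[str(n_f)] = {
            "quantiles": {str(q): v for q, v in pred.quantiles.items()},
            "mean_proportion": pred.mean_proportion,
        }
    subgroups = {}
    for name, sel_a, sel_b, la, lb in (
        (
            "transport_vs_in_hospital",
            bayes_betabinom.transport_only,
            bayes_betabinom.in_hospital,
            "transport",
            "in_hospital",
        ),
        (
            "dopa_dobu_vs_epi_norepi",
            bayes_betabinom.dopamine_dobutamine_predominant,
            bayes_betabinom.epi_norepi_predominant,
            "dopa_dobu_predominant",
            "epi_norepi_predominant",
        ),
    ):
        cmp = bayes_betabinom.compare_subgroups(
            table, sel_a, sel_b, la, lb, mc_draws=config.mc_draws, seed=config.seed
        )
        subgroups[name] = {
            "label_a": cmp.label_a,
            "label_b": cmp.label_b,
            "mean_a": cmp.mean_a,
            "mean_b": cmp.mean_b,
            "cri_a": list(cmp.cri_a),
            "cri_b": list(cmp.cri_b),
            "p_a_greater_b": cmp.p_a_greater_b,
            "p_b_greater_a": cmp.p_b_greater_a,
            "diff_mean": cmp.diff_mean,
            "diff_ci": list(cmp.diff_ci),
            "mc_draws": cmp.mc_draws,
            "seed": cmp.seed,
        }
    loglik = fit.max_marginal_loglik
    return BetaBinomSection(
        a_hat=fit.a_hat,
        b_hat=fit.b_hat,
        max_marginal_loglik=None if math.isnan(loglik) else loglik,
        population_mean=pop.mean,
        quantiles={str(q): v for q, v in pop.quantiles.items()},
        threshold_probs={str(t): v for t, v in pop.threshold_probs.items()},
        shrinkage=bayes_betabinom.study_shrinkage_estimates(fit, table).to_dict("records"),
        ppc_fraction_inside=ppc.fraction_inside,
        ppc_table=ppc.table.to_dict("records"),
        predictive=predictive,
        subgroups=subgroups,
    )


def _logit_section(table: StudyTable, config: AnalysisConfig) -> LogitSection:
    spec = config.logit_spec()
    samples = bayes_logit.sample_posterior(table, spec)
    summ = bayes_logit.summarize_pooled_rate(samples, thresholds=config.thresholds)
    return LogitSection(
        mean=summ.mean,
        median=summ.median,
        ci_low=summ.ci_low,
        ci_high=summ.ci_high,
        threshold_probs={str(t): p for t, p in summ.threshold_probs.items()},
        rhat=samples.rhat,
        ess=samples.ess,
        seed=spec.seed,
        n_draws=samples.n_draws,
        chains=spec.chains,
        iterations=spec.iterations,
    )


def run_full_analysis(config: AnalysisConfig | None = None) -> dict:
    """Run every enabled stage and return the validated report as a dict.

    A stage failure is recorded under ``errors`` with the stage name;
    earlier stages' results are preserved.
    """
    config = config or AnalysisConfig()
    if config.input == "bundled":
        table = study_table.bundled_dataset()
    else:
        table = study_table.load_study_table(config.input, schema_mode=config.schema_mode)

    sections: dict[str, Any] = {}
    errors: dict[str, str] = {}
    stages = []
    if config.run_frequentist:
        stages.append(("frequentist", lambda: _frequentist_section(table)))
    if config.run_beta_binomial:
        stages.append(("beta_binomial", lambda: _betabinom_section(table, config)))
    if config.run_logit_mcmc:
        stages.append(("logit_mcmc", lambda: _logit_section(table, config)))
    for name, stage in stages:
        try:
            sections[name] = stage()
        except Exception as exc:  # stage errors must not lose earlier results
            errors[name] = f"{type(exc).__name__}: {exc}"

    report = Report(
        package_version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        seed=config.seed,
        config=config.model_dump(),
        crude=_crude_section(table),
        errors=errors,
        **sections,
    )
    return report.model_dump(mode="json")


def export_forest_data(
    pooled: PooledResult,
    effects: Sequence[TransformedEffect],
    table: StudyTable,
    path,
) -> pd.DataFrame:
    """Forest-plot data: per-study proportion, Wilson CI, weight %, pooled row."""
    ids = tuple(e.study_id for e in effects)
    if ids != table.study_ids:
        raise ConsistencyError("effects and table describe different study sets")
    v = np.array([e.v for e in effects])
    w = 1.0 / (v + pooled.tau2)
    weights = 100.0 * w / w.sum()
    rows = []
    for r, e, wt in zip(table, effects, weights):
        crude = crude_pooled_proportion(r.events, r.n)
        rows.append(
            {
                "study_id": r.study_id,
                "events": r.events,
                "n": r.n,
                "proportion": crude.estimate,
                "ci_low": crude.ci_low,
                "ci_high": crude.ci_high,
                "weight_pct": wt,
            }
        )
    rows.append(
        {
            "study_id": f"POOLED ({pooled.method})",
            "events": table.total_events,
            "n": table.total_n,
            "proportion": pooled.estimate,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": np.nan,
        }
    )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def export_funnel_data(
    effects: Sequence[TransformedEffect], pooled: PooledResult, path
) -> pd.DataFrame:
    """Funnel-plot data: per-study (t, se) pairs plus the pooled reference."""
    if len(effects) < 3:
        raise InsufficientStudiesError("funnel data needs k >= 3 studies")
    rows = [
        {"study_id": e.study_id, "t": e.t, "se": e.se, "is_pooled": False}
        for e in effects
    ]
    rows.append(
        {"study_id": "POOLED", "t": pooled.t_bar, "se": 0.0, "is_pooled": True}
    )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
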