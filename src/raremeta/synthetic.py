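"""Synthetic study-table generation and parameter-recovery experiments.

Generates study-level binomial counts with the exact generative
structure the inferential modules assume: per-study event probabilities
drawn from either a Beta(a, b) population or a logit-normal(mu, tau^2)
population, then ``y_i ~ Binomial(n_i, p_i)``.  Tables come back in the
same schema as the bundled dataset, so every pipeline stage runs
unchanged on simulated data.

Seeding: a root seed and a replicate id feed ``default_rng([seed,
replicate_id])``, so any replicate is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from . import bayes_betabinom, bayes_logit, freq_meta
from .errors import RareMetaError
from .study_table import StudyRecord, StudyTable

__all__ = [
    "BetaPopulation",
    "LogitNormalPopulation",
    "SizePolicy",
    "SyntheticConfig",
    "RecoveryReport",
    "simulate_study_table",
    "recovery_experiment",
]


@dataclass(frozen=True)
class BetaPopulation:
    """True rates p_i ~ Beta(a, b) across studies."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shapes must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(self.a, self.b, size=size)


@dataclass(frozen=True)
class LogitNormalPopulation:
    """True rates p_i = invlogit(mu + tau * z_i), z_i ~ N(0, 1)."""

    mu: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")

    @property
    def mean(self) -> float:
        """Typical-study rate invlogit(mu) (the estimand of the logit model)."""
        return float(special.expit(self.mu))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return special.expit(self.mu + self.tau * rng.standard_normal(size))


@dataclass(frozen=True)
class SizePolicy:
    """Fixed list of study sizes, or log-uniform sizes on [n_min, n_max].

    The log-uniform default [30, 400] mimics the spread of the bundled
    table's study sizes.
    """

    kind: str = "log_uniform"  # "fixed" | "log_uniform"
    sizes: tuple[int, ...] = ()
    n_min: int = 30
    n_max: int = 400

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "log_uniform"):
            raise ValueError(f"unknown size policy {self.kind!r}")
        if self.kind == "fixed" and not self.sizes:
            raise ValueError("fixed size policy needs an explicit sizes list")
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ValueError("need 1 <= n_min <= n_max")

    def draw(self, rng: np.random.Generator, K: int) -> np.ndarray:
        if self.kind == "fixed":
            if len(self.sizes) != K:
                raise ValueError(f"fixed sizes list has {len(self.sizes)} entries, K={K}")
            return np.asarray(self.sizes, dtype=int)
        lo, hi = math.log(self.n_min), math.log(self.n_max)
        return np.exp(rng.uniform(lo, hi, size=K)).astype(int).clip(self.n_min, self.n_max)


@dataclass(frozen=True)
class SyntheticConfig:
    K: int
    truth: BetaPopulation | LogitNormalPopulation
    size_policy: SizePolicy = field(default_factory=SizePolicy)
    seed: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")


def simulate_study_table(config: SyntheticConfig) -> StudyTable:
    """Draw a study table; deterministic given (seed, replicate_id)."""
    rng = np.random.default_rng([config.seed, config.replicate_id])
    n = config.size_policy.draw(rng, config.K)
    p = config.truth.draw(rng, config.K)
    y = rng.binomial(n, p)
    records = tuple(
        StudyRecord(
            study_id=f"sim{i:03d}",
            year=2000,
            n=int(n[i]),
            events=int(y[i]),
            event_pct=round(100.0 * y[i] / n[i], 1),
            settings=frozenset({"PICU"}),
            design="retrospective",
            bias_score=9,
        )
        for i in range(config.K)
    )
    return StudyTable(
        records=records,
        provenance=(
            f"synthetic truth={config.truth!r} seed={config.seed} "
            f"replicate={config.replicate_id}"
        ),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Per-replicate estimates plus aggregate bias/RMSE/coverage."""

    truth: BetaPopulation | LogitNormalPopulation
    true_mean: float
    per_replicate: pd.DataFrame
    summary: pd.DataFrame  # one row per estimator
    replicates: int
    seed: int

    def __post_init__(self) -> None:
        for _, row in self.summary.iterrows():
            if not (math.isnan(row["coverage"]) or 0.0 <= row["coverage"] <= 1.0):
                raise ValueError("coverage out of [0, 1]")


def _fit_one(estimator: str, table: StudyTable, seed: int) -> dict:
    """Population-mean estimate and (where defined) a 95% interval."""
    if estimator == "eb_betabinom":
        fit = bayes_betabinom.fit_empirical_bayes(table)
        return {"estimate": fit.mean, "ci_low": math.nan, "ci_high": math.nan}
    if estimator == "ft_dl":
        pooled = freq_meta.pool_random_dl(freq_meta.transform_table(table))
        return {"estimate": pooled.estimate, "ci_low": pooled.ci_low, "ci_high": pooled.ci_high}
    if estimator == "mcmc_logit":
        spec = bayes_logit.LogitModelSpec(seed=seed)
        samples = bayes_logit.sample_posterior(table, spec)
        summ = bayes_logit.summarize_pooled_rate(samples)
        return {"estimate": summ.mean, "ci_low": summ.ci_low, "ci_high": summ.ci_high}
    raise ValueError(f"unknown estimator {estimator!r}")


def recovery_experiment(
    truth: BetaPopulation | LogitNormalPopulation,
    K: int,
    n_policy: SizePolicy,
    replicates: int,
    estimators: Sequence[str] = ("eb_betabinom",),
    seed: int = 0,
) -> RecoveryReport:
    """Simulate-fit-aggregate loop for the population-mean estimand.

    Estimator failures (boundary data, non-convergence) are recorded per
    replicate and surface as a failure rate, never as an exception.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    true_mean = truth.mean
    rows = []
    for rep in range(replicates):
        table = simulate_study_table(
            SyntheticConfig(K=K, truth=truth, size_policy=n_policy, seed=seed, replicate_id=rep)
        )
        for est in estimators:
            row = {"replicate": rep, "seed": seed, "estimator": est}
            try:
                row.update(_fit_one(est, table, seed=seed + rep))
                row["failed"] = False
            except RareMetaError as exc:
                row.update(
                    {"estimate": math.nan, "ci_low": math.nan, "ci_high": math.nan}
                )
                row["failed"] = True
                row["failure"] = str(exc)
            rows.append(row)
    per_rep = pd.DataFrame(rows)

    summaries = []
    for est in estimators:
        sub = per_rep[(per_rep["estimator"] == est) & (~per_rep["failed"])]
        err = sub["estimate"] - true_mean
        covered = (sub["ci_low"] <= true_mean) & (true_mean <= sub["ci_high"])
        n_int = int(sub[["ci_low", "ci_high"]].notna().all(axis=1).sum())
        summaries.append(
            {
                "estimator": est,
                "bias": float(err.mean()) if len(sub) else math.nan,
                "rmse": float(np.sqrt(np.mean(err**2))) if len(sub) else math.nan,
                "coverage": float(covered.mean()) if n_int else math.nan,
                "n_ok": len(sub),
                "failure_rate": 1.0 - len(sub) / replicates,
            }
        )
    return RecoveryReport(
        truth=truth,
        true_mean=true_mean,
        per_replicate=per_rep,
        summary=pd.DataFrame(summaries),
        replicates=replicates,
        seed=seed,
    )
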