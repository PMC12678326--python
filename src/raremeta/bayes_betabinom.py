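"""Hierarchical Beta–Binomial model with empirical-Bayes estimation.

Study-specific event probabilities are modeled as ``p_i ~ Beta(a, b)``
with ``y_i ~ Binomial(n_i, p_i)``; integrating ``p_i`` out gives the
Beta–Binomial marginal pmf.  The hyperparameters ``(a, b)`` are
estimated by maximizing the marginal likelihood over ``(log a, log b)``
from multiple starting points (empirical Bayes).  Everything downstream
is conjugate or closed-form:

* population summaries (mean ``a/(a+b)``, Beta quantiles, threshold
  probabilities ``P(rate < c)`` via the regularized incomplete beta),
* per-study shrinkage posteriors ``Beta(a + y_i, b + n_i - y_i)``,
* exact predictive distributions for hypothetical future studies,
* posterior predictive checks, and
* Monte Carlo subgroup comparisons of the population Beta densities.

When the observed counts show no detectable overdispersion the marginal
likelihood increases monotonically in the concentration ``a + b`` and
the optimizer runs to the (bounded) no-overdispersion boundary, where
the population Beta degenerates toward a point mass at the common rate.
This is expected behavior, not a failure; the optimizer record keeps
every start for inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import BoundaryError, FitError, InsufficientStudiesError
from .study_table import StudyRecord, StudyTable

__all__ = [
    "BetaBinomFit",
    "PredictiveSummary",
    "SubgroupComparison",
    "beta_binomial_log_pmf",
    "marginal_log_likelihood",
    "fit_empirical_bayes",
    "population_summary",
    "study_shrinkage_estimates",
    "predictive_distribution",
    "posterior_predictive_check",
    "compare_subgroups",
    "transport_only",
    "in_hospital",
    "dopamine_or_dobutamine",
    "epi_norepi_only",
    "dopamine_dobutamine_predominant",
    "epi_norepi_predominant",
]

SHAPE_BOUNDS = (1e-3, 1e6)


def beta_binomial_log_pmf(y, n, a: float, b: float):
    """Log pmf of the Beta–Binomial: log C(n,y) + log B(y+a, n-y+b) - log B(a,b).

    Computed with log-gamma throughout; vectorized over ``y`` and ``n``.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if a <= 0 or b <= 0:
        raise ValueError(f"shapes must be positive, got a={a}, b={b}")
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= y <= n")
    out = (
        special.gammaln(n + 1)
        - special.gammaln(y + 1)
        - special.gammaln(n - y + 1)
        + special.betaln(y + a, n - y + b)
        - special.betaln(a, b)
    )
    return out if out.shape else float(out)


def marginal_log_likelihood(a: float, b: float, table: StudyTable) -> float:
    """Sum of Beta–Binomial log pmfs over the studies."""
    if len(table) == 0:
        raise ValueError("table must be nonempty")
    y = np.array([r.events for r in table], dtype=float)
    n = np.array([r.n for r in table], dtype=float)
    return float(np.sum(beta_binomial_log_pmf(y, n, a, b)))


@dataclass(frozen=True)
class BetaBinomFit:
    """Empirical-Bayes hyperparameters and the optimization record."""

    a_hat: float
    b_hat: float
    max_marginal_loglik: float
    optimizer_record: tuple[dict, ...] = ()
    data_ref: str = ""

    def __post_init__(self) -> None:
        if self.a_hat <= 0 or self.b_hat <= 0:
            raise ValueError("fitted shapes must be positive")

    @property
    def mean(self) -> float:
        return self.a_hat / (self.a_hat + self.b_hat)

    @classmethod
    def from_hyperparameters(cls, a: float, b: float) -> "BetaBinomFit":
        """Wrap externally supplied hyperparameters (no fit performed)."""
        return cls(
            a_hat=a,
            b_hat=b,
            max_marginal_loglik=math.nan,
            data_ref="externally supplied hyperparameters",
        )


def _default_starts(table: StudyTable) -> list[tuple[float, float]]:
    """Method-of-moments start plus mean-2% starts at several concentrations."""
    starts: list[tuple[float, float]] = []
    p = np.array([r.events / r.n for r in table])
    m = float(p.mean())
    s2 = float(p.var(ddof=1)) if len(p) > 1 else 0.0
    if 0.0 < m < 1.0 and s2 > 0.0:
        c = m * (1.0 - m) / s2 - 1.0
        if c > 0.0:
            starts.append((m * c, (1.0 - m) * c))
    for conc in (10.0, 100.0, 1000.0):
        starts.append((0.02 * conc, 0.98 * conc))
    return starts


def fit_empirical_bayes(
    table: StudyTable,
    starts: Sequence[tuple[float, float]] | None = None,
    tol: float = 1e-10,
) -> BetaBinomFit:
    """Maximize the marginal likelihood over (log a, log b), multi-start.

    Shapes are bounded to ``[1e-3, 1e6]``.  Ties between starts are
    broken by the higher marginal log-likelihood, then by the smaller
    ``a``.  Requires at least two studies and at least one event.
    """
    if len(table) < 2:
        raise InsufficientStudiesError("empirical Bayes needs at least 2 studies")
    if table.total_events == 0:
        raise BoundaryError(
            "all event counts are zero: the population mean is not identifiable away from 0"
        )
    y = np.array([r.events for r in table], dtype=float)
    n = np.array([r.n for r in table], dtype=float)
    const = np.sum(
        special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    )

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        return -float(
            const + np.sum(special.betaln(y + a, n - y + b) - special.betaln(a, b))
        )

    log_bounds = [(math.log(SHAPE_BOUNDS[0]), math.log(SHAPE_BOUNDS[1]))] * 2
    record = []
    for a0, b0 in starts or _default_starts(table):
        x0 = np.clip(
            np.log([a0, b0]), math.log(SHAPE_BOUNDS[0]), math.log(SHAPE_BOUNDS[1])
        )
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=log_bounds, options={"ftol": tol}
        )
        a, b = np.exp(res.x)
        record.append(
            {
                "start": (float(a0), float(b0)),
                "a": float(a),
                "b": float(b),
                "loglik": -float(res.fun),
                "iterations": int(res.nit),
                "converged": bool(res.success),
            }
        )
    converged = [r for r in record if r["converged"]]
    if not converged:
        raise FitError("optimizer failed to converge from every start", trace=record)
    best = max(converged, key=lambda r: (r["loglik"], -r["a"]))
    return BetaBinomFit(
        a_hat=best["a"],
        b_hat=best["b"],
        max_marginal_loglik=best["loglik"],
        optimizer_record=tuple(record),
        data_ref=table.provenance,
    )


@dataclass(frozen=True)
class PopulationSummary:
    mean: float
    quantiles: dict[float, float]
    threshold_probs: dict[float, float]
    a: float
    b: float


def population_summary(
    fit: BetaBinomFit,
    thresholds: Sequence[float] = (0.02, 0.03),
    quantile_levels: Sequence[float] = (0.025, 0.5, 0.975),
) -> PopulationSummary:
    """Mean, quantiles and threshold CDF values of the population Beta(a, b)."""
    a, b = fit.a_hat, fit.b_hat
    for thr in thresholds:
        if not 0.0 < thr < 1.0:
            raise ValueError(f"thresholds must lie in (0, 1), got {thr}")
    return PopulationSummary(
        mean=a / (a + b),
        quantiles={float(q): float(stats.beta.ppf(q, a, b)) for q in quantile_levels},
        threshold_probs={float(t): float(stats.beta.cdf(t, a, b)) for t in thresholds},
        a=a,
        b=b,
    )


def study_shrinkage_estimates(fit: BetaBinomFit, table: StudyTable) -> pd.DataFrame:
    """Conjugate per-study posteriors Beta(a + y_i, b + n_i - y_i).

    Every posterior mean lies between the study's crude rate and the
    population mean (convex combination with weight n_i/(a+b+n_i)).
    """
    rows = []
    a, b = fit.a_hat, fit.b_hat
    for r in table:
        ap, bp = a + r.events, b + r.n - r.events
        rows.append(
            {
                "study_id": r.study_id,
                "n": r.n,
                "events": r.events,
                "crude_rate": r.crude_rate,
                "posterior_mean": ap / (ap + bp),
                "ci_low": float(stats.beta.ppf(0.025, ap, bp)),
                "ci_high": float(stats.beta.ppf(0.975, ap, bp)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PredictiveSummary:
    n_future: int
    pmf: np.ndarray  # support 0..n_future
    quantiles: dict[float, float]  # proportion-scale y/n quantiles
    mean_proportion: float

    def variance_proportion(self) -> float:
        support = np.arange(self.n_future + 1) / self.n_future
        return float(np.sum(self.pmf * support**2) - np.sum(self.pmf * support) ** 2)


def predictive_distribution(
    fit: BetaBinomFit,
    n_future: int,
    quantile_levels: Sequence[float] = (0.025, 0.5, 0.975),
) -> PredictiveSummary:
    """Exact Beta–Binomial predictive pmf for a future study of ``n_future``.

    Proportion quantiles follow the discrete-CDF convention: the
    smallest support point ``y/n`` whose CDF reaches the level.
    """
    if n_future < 1:
        raise ValueError(f"n_future must be >= 1, got {n_future}")
    support = np.arange(n_future + 1)
    pmf = np.exp(beta_binomial_log_pmf(support, n_future, fit.a_hat, fit.b_hat))
    cdf = np.cumsum(pmf)
    quantiles = {
        float(q): float(support[np.searchsorted(cdf, q)] / n_future)
        for q in quantile_levels
    }
    return PredictiveSummary(
        n_future=n_future,
        pmf=pmf,
        quantiles=quantiles,
        mean_proportion=fit.mean,
    )


@dataclass(frozen=True)
class PPCReport:
    table: pd.DataFrame
    fraction_inside: float


def posterior_predictive_check(fit: BetaBinomFit, table: StudyTable) -> PPCReport:
    """Central 95% predictive interval and mid-p tail probability per study."""
    rows = []
    inside = 0
    for r in table:
        support = np.arange(r.n + 1)
        pmf = np.exp(beta_binomial_log_pmf(support, r.n, fit.a_hat, fit.b_hat))
        cdf = np.cumsum(pmf)
        lo = int(support[np.searchsorted(cdf, 0.025)])
        hi = int(support[np.searchsorted(cdf, 0.975)])
        yobs = r.events
        p_lower = float(cdf[yobs] - 0.5 * pmf[yobs])  # mid-p P(Y <= y)
        p_upper = float(1.0 - cdf[yobs] + 0.5 * pmf[yobs])
        midp = min(1.0, 2.0 * min(p_lower, p_upper))
        ok = lo <= yobs <= hi
        inside += ok
        rows.append(
            {
                "study_id": r.study_id,
                "n": r.n,
                "observed": yobs,
                "pred_low": lo,
                "pred_high": hi,
                "inside": ok,
                "midp_two_sided": midp,
            }
        )
    return PPCReport(table=pd.DataFrame(rows), fraction_inside=inside / len(table))


# Subgroup assignment policy -------------------------------------------------

def transport_only(record: StudyRecord) -> bool:
    """A study is 'transport' only when TRANSPORT is its sole setting tag."""
    return record.settings == frozenset({"TRANSPORT"})


def in_hospital(record: StudyRecord) -> bool:
    """Complement of :func:`transport_only`; multi-setting studies land here."""
    return not transport_only(record)


def dopamine_or_dobutamine(record: StudyRecord) -> bool:
    """Regimen includes dopamine or dobutamine (missing counts read as absent).

    Note that on the bundled table this any-exposure reading leaves a
    single epi/norepi-only study, so it cannot support a two-sided
    comparison there; see :func:`dopamine_dobutamine_predominant`.
    """
    return (
        record.agent_counts.get("dopamine", 0) > 0
        or record.agent_counts.get("dobutamine", 0) > 0
    )


def epi_norepi_only(record: StudyRecord) -> bool:
    return not dopamine_or_dobutamine(record)


def dopamine_dobutamine_predominant(record: StudyRecord) -> bool:
    """Dopamine/dobutamine patients outnumber epinephrine/norepinephrine ones.

    The partition used for the catecholamine-regimen comparison: it
    splits the bundled table 4 vs 7, whereas any-exposure does not
    yield two usable sides.
    """
    dopa = record.agent_counts.get("dopamine", 0) + record.agent_counts.get("dobutamine", 0)
    epi = record.agent_counts.get("epinephrine", 0) + record.agent_counts.get(
        "norepinephrine", 0
    )
    return dopa > epi


def epi_norepi_predominant(record: StudyRecord) -> bool:
    return not dopamine_dobutamine_predominant(record)


@dataclass(frozen=True)
class SubgroupComparison:
    label_a: str
    label_b: str
    fit_a: BetaBinomFit
    fit_b: BetaBinomFit
    mean_a: float
    mean_b: float
    cri_a: tuple[float, float]
    cri_b: tuple[float, float]
    p_a_greater_b: float
    diff_mean: float
    diff_ci: tuple[float, float]
    mc_draws: int
    seed: int

    @property
    def p_b_greater_a(self) -> float:
        return 1.0 - self.p_a_greater_b


def compare_subgroups(
    table: StudyTable,
    selector_a: Callable[[StudyRecord], bool],
    selector_b: Callable[[StudyRecord], bool],
    label_a: str = "A",
    label_b: str = "B",
    mc_draws: int = 100_000,
    seed: int = 0,
) -> SubgroupComparison:
    """Independent empirical-Bayes fits per side + Monte Carlo comparison.

    ``P(A > B)`` and the difference density are estimated from seeded
    draws of the two fitted population Beta distributions.
    """
    side_a = table.select(selector_a, label=label_a)
    side_b = table.select(selector_b, label=label_b)
    for label, side in ((label_a, side_a), (label_b, side_b)):
        if len(side) < 2:
            raise InsufficientStudiesError(f"subgroup {label!r} retains fewer than 2 studies")
        if side.total_events == 0:
            raise BoundaryError(f"subgroup {label!r} has no events; fit not identifiable")
    fit_a = fit_empirical_bayes(side_a)
    fit_b = fit_empirical_bayes(side_b)
    rng = np.random.default_rng(seed)
    pa = rng.beta(fit_a.a_hat, fit_a.b_hat, size=mc_draws)
    pb = rng.beta(fit_b.a_hat, fit_b.b_hat, size=mc_draws)
    diff = pa - pb
    return SubgroupComparison(
        label_a=label_a,
        label_b=label_b,
        fit_a=fit_a,
        fit_b=fit_b,
        mean_a=fit_a.mean,
        mean_b=fit_b.mean,
        cri_a=(
            float(stats.beta.ppf(0.025, fit_a.a_hat, fit_a.b_hat)),
            float(stats.beta.ppf(0.975, fit_a.a_hat, fit_a.b_hat)),
        ),
        cri_b=(
            float(stats.beta.ppf(0.025, fit_b.a_hat, fit_b.b_hat)),
            float(stats.beta.ppf(0.975, fit_b.a_hat, fit_b.b_hat)),
        ),
        p_a_greater_b=float(np.mean(pa > pb)),
        diff_mean=float(diff.mean()),
        diff_ci=(float(np.quantile(diff, 0.025)), float(np.quantile(diff, 0.975))),
        mc_draws=mc_draws,
        seed=seed,
    )
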