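"""Hierarchical logit-normal binomial meta-analysis fitted by MCMC.

Model: for study *i*, ``y_i ~ Binomial(n_i, p_i)`` with
``logit(p_i) = mu + u_i`` and ``u_i ~ Normal(0, tau^2)``.  ``mu`` is the
population log-odds of an adverse event and ``tau`` the between-study
heterogeneity on the logit scale.  The default weakly informative
priors are ``mu ~ Normal(logit(0.02), 1.5^2)`` and
``tau ~ Half-Normal(0, 0.5)``; broader and alternative prior sets are
available as named specs.

The "pooled rate" reported throughout is ``invlogit(mu)`` — the event
rate of a typical study (``u_i = 0``) — not the marginal mean over the
random effect.

Sampling uses adaptive Metropolis-within-Gibbs on the *non-centered*
parameterization ``u_i = tau * z_i`` (which removes the tau -> 0 funnel
that defeats centered samplers on rare-event data).  Given
``(mu, tau)`` the ``z_i`` are conditionally independent, so the whole
z-block is updated in one vectorized Metropolis step; ``mu`` and
``log tau`` get scalar random-walk updates with the Jacobian term
included.  Proposal scales adapt toward 44% acceptance during warmup
only, and several full sweeps are performed per stored iteration to
keep autocorrelation low.  Convergence is checked with rank-normalized
split R-hat and effective sample size (arviz).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

from .errors import NonConvergenceError
from .study_table import StudyTable

__all__ = [
    "LogitModelSpec",
    "PosteriorSamples",
    "PooledRateSummary",
    "methods_priors",
    "broad_priors",
    "abstract_priors",
    "log_posterior_density",
    "sample_posterior",
    "convergence_diagnostics",
    "summarize_pooled_rate",
]

RHAT_LIMIT = 1.01


@dataclass(frozen=True)
class LogitModelSpec:
    """Priors, chain geometry and seed for the hierarchical logit model."""

    mu_prior_mean: float = float(special.logit(0.02))
    mu_prior_sd: float = 1.5
    tau_prior: tuple[str, float] = ("half_normal", 0.5)
    chains: int = 4
    iterations: int = 2000  # per-chain total; first warmup_fraction discarded
    warmup_fraction: float = 0.5
    seed: int = 0
    sweeps_per_iteration: int = 5
    prior_only: bool = False

    def __post_init__(self) -> None:
        if self.mu_prior_sd <= 0:
            raise ValueError("mu_prior_sd must be positive")
        family, scale = self.tau_prior
        if family not in ("half_normal", "half_cauchy"):
            raise ValueError(f"unknown tau prior family {family!r}")
        if scale <= 0:
            raise ValueError("tau prior scale must be positive")
        if self.chains < 2:
            raise ValueError("need at least 2 chains")
        if self.iterations < 100:
            raise ValueError("need at least 100 iterations")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")

    @property
    def warmup(self) -> int:
        return int(self.iterations * self.warmup_fraction)

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup


def methods_priors(**overrides) -> LogitModelSpec:
    """Default priors: mu ~ N(logit 0.02, 1.5^2), tau ~ Half-Normal(0, 0.5)."""
    return LogitModelSpec(**overrides)


def broad_priors(**overrides) -> LogitModelSpec:
    """Sensitivity priors: mu ~ N(logit 0.02, 2.0^2), tau ~ Half-Normal(0, 1.0)."""
    return LogitModelSpec(mu_prior_sd=2.0, tau_prior=("half_normal", 1.0), **overrides)


def abstract_priors(**overrides) -> LogitModelSpec:
    """Alternative set: mu ~ N(0, 1), tau ~ Half-Cauchy(1).

    Kept as a named spec because it is sometimes quoted alongside the
    default set; the two are not equivalent and both are preserved.
    """
    return LogitModelSpec(
        mu_prior_mean=0.0, mu_prior_sd=1.0, tau_prior=("half_cauchy", 1.0), **overrides
    )


def _tau_log_prior(tau: float | np.ndarray, spec: LogitModelSpec) -> float | np.ndarray:
    family, s = spec.tau_prior
    if family == "half_normal":
        return 0.5 * math.log(2.0 / math.pi) - math.log(s) - np.square(tau) / (2.0 * s * s)
    # half-Cauchy
    return math.log(2.0 / (math.pi * s)) - np.log1p(np.square(tau / s))


def log_posterior_density(
    mu: float,
    tau: float,
    u: Sequence[float],
    table: StudyTable,
    spec: LogitModelSpec | None = None,
) -> float:
    """Log joint density of ``(mu, tau, u)`` given the table, up to nothing.

    All normalizing constants (including the binomial coefficients) are
    included, so the value matches a term-by-term summation of the
    stated model exactly.  ``tau = 0`` is admitted only in the
    degenerate case ``u = 0`` (point-mass convention, the u-density
    contribution is dropped); otherwise ``tau`` must be positive.
    """
    spec = spec or LogitModelSpec()
    u = np.asarray(u, dtype=float)
    y = np.array([r.events for r in table], dtype=float)
    n = np.array([r.n for r in table], dtype=float)
    if u.shape != y.shape:
        raise ValueError(f"u has length {u.size}, table has {y.size} studies")
    if tau < 0:
        raise ValueError("tau must be nonnegative")

    lp = mu + u
    loglik = float(
        np.sum(
            special.gammaln(n + 1)
            - special.gammaln(y + 1)
            - special.gammaln(n - y + 1)
            + y * lp
            - n * np.logaddexp(0.0, lp)
        )
    )
    if spec.prior_only:
        loglik = 0.0
    log_prior = float(stats.norm.logpdf(mu, spec.mu_prior_mean, spec.mu_prior_sd))
    log_prior += float(_tau_log_prior(tau, spec))
    if tau == 0.0:
        if np.any(u != 0.0):
            return -math.inf
        u_density = 0.0
    else:
        u_density = float(np.sum(stats.norm.logpdf(u, 0.0, tau)))
    return loglik + log_prior + u_density


@dataclass(frozen=True)
class PosteriorSamples:
    """Post-warmup draws indexed (chain, iteration), plus diagnostics."""

    mu: np.ndarray  # (chains, kept)
    tau: np.ndarray  # (chains, kept)
    u: np.ndarray  # (chains, kept, k)
    study_ids: tuple[str, ...]
    spec: LogitModelSpec
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.mu.size

    def pooled_rate_draws(self) -> np.ndarray:
        return special.expit(self.mu)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        chains, kept = self.mu.shape
        frames = []
        cidx = np.repeat(np.arange(chains), kept)
        it = np.tile(np.arange(kept), chains)
        for name, arr in (("mu", self.mu), ("tau", self.tau)):
            frames.append(
                pd.DataFrame(
                    {"chain": cidx, "iteration": it, "parameter": name, "value": arr.ravel()}
                )
            )
        for j, sid in enumerate(self.study_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "chain": cidx,
                        "iteration": it,
                        "parameter": f"u[{sid}]",
                        "value": self.u[:, :, j].ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _rhat_ess(draws: np.ndarray) -> tuple[float, float]:
    """Rank-normalized split R-hat and bulk ESS for a (chains, draws) array."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(draws)
        r = float(az.rhat(ds)["x"].values)
        e = float(az.ess(ds)["x"].values)
    return r, e


def sample_posterior(
    table: StudyTable,
    spec: LogitModelSpec | None = None,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Draw from the posterior; seeded and reproducible.

    Raises :class:`NonConvergenceError` (with the diagnostics attached)
    if split R-hat on ``mu`` or ``tau`` reaches 1.01; pass
    ``check_convergence=False`` for deliberately short exploratory runs.
    """
    spec = spec or LogitModelSpec()
    if len(table) < 1:
        raise ValueError("table must contain at least one study")
    y = np.array([r.events for r in table], dtype=float)
    n = np.array([r.n for r in table], dtype=float)
    K = len(table)
    C = spec.chains
    warm, kept = spec.warmup, spec.kept
    rng = np.random.default_rng(spec.seed)
    family, _ = spec.tau_prior

    def study_ll(mu, tau, z):
        # (C, K) binomial log-likelihood terms, constants dropped
        lp = mu[:, None] + tau[:, None] * z
        out = y[None, :] * lp - n[None, :] * np.logaddexp(0.0, lp)
        if spec.prior_only:
            out = np.zeros_like(out)
        return out

    def eta_log_prior(eta):
        # tau prior density plus the log-scale Jacobian term
        return _tau_log_prior(np.exp(eta), spec) + eta

    # Overdispersed but plausible chain starts
    mu = spec.mu_prior_mean + 0.5 * rng.standard_normal(C)
    eta = np.log(0.3) + 0.3 * rng.standard_normal(C)
    z = 0.1 * rng.standard_normal((C, K))
    s_mu = np.full(C, 0.5)
    s_eta = np.full(C, 0.5)
    s_anc = np.full(C, 0.5)
    s_scl = np.full(C, 0.5)
    s_z = np.ones((C, K))
    ll = study_ll(mu, np.exp(eta), z)

    out_mu = np.empty((C, kept))
    out_tau = np.empty((C, kept))
    out_u = np.empty((C, kept, K))

    for it in range(spec.iterations):
        adapt = it < warm
        gain = 1.0 / math.sqrt(1.0 + it)
        for _ in range(spec.sweeps_per_iteration):
            tau = np.exp(eta)
            # z-block: conditionally independent given (mu, tau)
            zp = z + s_z * rng.standard_normal((C, K))
            llp = study_ll(mu, tau, zp)
            logr = (llp - ll) - 0.5 * (zp**2 - z**2)
            acc = np.log(rng.uniform(size=(C, K))) < logr
            z = np.where(acc, zp, z)
            ll = np.where(acc, llp, ll)
            if adapt:
                s_z *= np.exp((acc - 0.44) * gain)
            # mu
            mup = mu + s_mu * rng.standard_normal(C)
            llp = study_ll(mup, tau, z)
            logr = (llp.sum(axis=1) - ll.sum(axis=1)) - 0.5 * (
                ((mup - spec.mu_prior_mean) / spec.mu_prior_sd) ** 2
                - ((mu - spec.mu_prior_mean) / spec.mu_prior_sd) ** 2
            )
            acc1 = np.log(rng.uniform(size=C)) < logr
            mu = np.where(acc1, mup, mu)
            ll = np.where(acc1[:, None], llp, ll)
            if adapt:
                s_mu *= np.exp((acc1 - 0.44) * gain)
            # eta = log tau (Jacobian included in eta_log_prior)
            etap = eta + s_eta * rng.standard_normal(C)
            llp = study_ll(mu, np.exp(etap), z)
            logr = (llp.sum(axis=1) - ll.sum(axis=1)) + eta_log_prior(etap) - eta_log_prior(eta)
            acc1 = np.log(rng.uniform(size=C)) < logr
            eta = np.where(acc1, etap, eta)
            ll = np.where(acc1[:, None], llp, ll)
            if adapt:
                s_eta *= np.exp((acc1 - 0.44) * gain)
            # ancillary translation: shift mu, compensate in z so the
            # likelihood is untouched -- mixes the mu/(tau z) ridge that
            # appears when single large studies dominate
            tau = np.exp(eta)
            d = s_anc * rng.standard_normal(C)
            zp = z - (d / tau)[:, None]
            mup = mu + d
            logr = -0.5 * (
                ((mup - spec.mu_prior_mean) / spec.mu_prior_sd) ** 2
                - ((mu - spec.mu_prior_mean) / spec.mu_prior_sd) ** 2
            ) - 0.5 * (zp**2 - z**2).sum(axis=1)
            acc1 = np.log(rng.uniform(size=C)) < logr
            mu = np.where(acc1, mup, mu)
            z = np.where(acc1[:, None], zp, z)
            if adapt:
                s_anc *= np.exp((acc1 - 0.44) * gain)
            # ancillary rescaling: shift log tau, rescale z to keep tau*z
            # (hence the likelihood) fixed; Jacobian term is -K*d
            d = s_scl * rng.standard_normal(C)
            etap = eta + d
            zp = z * np.exp(-d)[:, None]
            logr = (
                eta_log_prior(etap)
                - eta_log_prior(eta)
                - 0.5 * (zp**2 - z**2).sum(axis=1)
                - K * d
            )
            acc1 = np.log(rng.uniform(size=C)) < logr
            eta = np.where(acc1, etap, eta)
            z = np.where(acc1[:, None], zp, z)
            if adapt:
                s_scl *= np.exp((acc1 - 0.44) * gain)
        if it >= warm:
            j = it - warm
            out_mu[:, j] = mu
            out_tau[:, j] = np.exp(eta)
            out_u[:, j, :] = np.exp(eta)[:, None] * z

    rhat = {}
    ess = {}
    for name, arr in (("mu", out_mu), ("tau", out_tau)):
        rhat[name], ess[name] = _rhat_ess(arr)
    for j, sid in enumerate(table.study_ids):
        rhat[f"u[{sid}]"], ess[f"u[{sid}]"] = _rhat_ess(out_u[:, :, j])

    samples = PosteriorSamples(
        mu=out_mu,
        tau=out_tau,
        u=out_u,
        study_ids=table.study_ids,
        spec=spec,
        rhat=rhat,
        ess=ess,
    )
    if check_convergence and (rhat["mu"] >= RHAT_LIMIT or rhat["tau"] >= RHAT_LIMIT):
        raise NonConvergenceError(
            f"split R-hat >= {RHAT_LIMIT} (mu: {rhat['mu']:.4f}, tau: {rhat['tau']:.4f})",
            diagnostics={"rhat": rhat, "ess": ess},
        )
    return samples


def convergence_diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Rank-normalized split R-hat and ESS per parameter, with flags."""
    if samples.mu.shape[0] < 2:
        raise ValueError("diagnostics are undefined for a single chain")
    if samples.mu.shape[1] < 4:
        raise ValueError("need at least 4 post-warmup draws per chain")
    rows = []
    arrays = {"mu": samples.mu, "tau": samples.tau}
    for j, sid in enumerate(samples.study_ids):
        arrays[f"u[{sid}]"] = samples.u[:, :, j]
    for name, arr in arrays.items():
        r, e = _rhat_ess(arr)
        rows.append({"parameter": name, "rhat": r, "ess": e, "flagged": r >= RHAT_LIMIT})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PooledRateSummary:
    mean: float
    median: float
    ci_low: float
    ci_high: float
    threshold_probs: dict[float, float]
    n_draws: int


def summarize_pooled_rate(
    samples: PosteriorSamples, thresholds: Sequence[float] = ()
) -> PooledRateSummary:
    """Posterior summary of the pooled rate ``invlogit(mu)``.

    The 95% interval is equal-tailed; for each threshold the fraction of
    draws below it is reported.
    """
    p = samples.pooled_rate_draws().ravel()
    if p.size == 0:
        raise ValueError("no posterior draws")
    for thr in thresholds:
        if not 0.0 < thr < 1.0:
            raise ValueError(f"thresholds must lie in (0, 1), got {thr}")
    lo, med, hi = np.quantile(p, [0.025, 0.5, 0.975])
    return PooledRateSummary(
        mean=float(p.mean()),
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        threshold_probs={float(t): float(np.mean(p < t)) for t in thresholds},
        n_draws=int(p.size),
    )
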