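"""Frequentist synthesis of binomial proportions.

Implements the classical pipeline for meta-analysing rare-event
proportions: the Freeman–Tukey (FT) double-arcsine transform
``t = ½[arcsin√(y/(n+1)) + arcsin√((y+1)/(n+1))]`` with sampling
variance ``1/(4n+2)`` (well defined for zero-event studies without a
continuity correction), inverse-variance fixed-effect pooling, the
DerSimonian–Laird (DL) moment estimator of the between-study variance
τ², Cochran's Q / I² heterogeneity statistics, Egger's regression test
for small-study effects, and leave-one-out / subgroup sensitivity
analyses.

Back-transformation to the proportion scale supports two variants:

``"asin"``
    Inversion of the single arcsine, ``p = sin²(t)``.  This is the
    variant under which the pooled transformed-scale confidence bounds
    reproduce classically reported intervals, and it is the default for
    pooled results.
``"miller"``
    Miller's harmonic-mean-corrected inversion, which round-trips a
    single study's transform back to exactly ``y/n`` and is used when a
    study-level proportion is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import EmptySelectionError, InsufficientStudiesError
from .study_table import StudyRecord, StudyTable

__all__ = [
    "TransformedEffect",
    "PooledResult",
    "EggerResult",
    "ft_transform",
    "ft_back_transform",
    "transform_table",
    "pool_fixed",
    "pool_random_dl",
    "egger_test",
    "leave_one_out",
    "subgroup_pool",
]

Z975 = 1.959964  # normal 97.5% quantile used for all 95% intervals


@dataclass(frozen=True)
class TransformedEffect:
    """Freeman–Tukey point estimate and variance for one study."""

    study_id: str
    t: float  # double-arcsine value, radians, in [0, pi/2]
    v: float  # sampling variance 1/(4n+2), radians^2
    n: int

    @property
    def se(self) -> float:
        return math.sqrt(self.v)


@dataclass(frozen=True)
class PooledResult:
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    method: str  # "fixed" | "random_DL"
    k: int
    n_harmonic: float
    t_bar: float
    se_t: float
    back_transform: str = "asin"
    label: str = ""
    fixed_fallback: bool = False


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    t_stat: float
    p_value: float
    k: int


def ft_transform(events: int, n: int, study_id: str = "") -> TransformedEffect:
    """Freeman–Tukey double-arcsine transform of ``events/n``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= events <= n:
        raise ValueError(f"need 0 <= events <= n, got {events}/{n}")
    t = 0.5 * (
        math.asin(math.sqrt(events / (n + 1)))
        + math.asin(math.sqrt((events + 1) / (n + 1)))
    )
    return TransformedEffect(study_id=study_id, t=t, v=1.0 / (4 * n + 2), n=n)


def ft_back_transform(t_bar: float, n_harmonic: float, method: str = "miller") -> float:
    """Invert a (pooled) Freeman–Tukey value to the proportion scale.

    ``method="miller"`` applies the harmonic-mean correction; since the
    FT statistic is a half-angle, the inversion operates on ``2·t_bar``.
    ``method="asin"`` is the plain ``sin²`` inversion.  Either way the
    result is clipped to [0, 1] and ``t_bar <= 0`` maps to 0.
    """
    if n_harmonic <= 0:
        raise ValueError(f"n_harmonic must be positive, got {n_harmonic}")
    if t_bar <= 0.0:
        return 0.0
    if method == "asin":
        return float(np.clip(math.sin(min(t_bar, math.pi / 2)) ** 2, 0.0, 1.0))
    if method != "miller":
        raise ValueError(f"unknown back-transform {method!r}")
    x = 2.0 * min(t_bar, math.pi / 2)
    s = math.sin(x)
    inner = 1.0 - (s + (s - 1.0 / s) / n_harmonic) ** 2
    p = 0.5 * (1.0 - math.copysign(1.0, math.cos(x)) * math.sqrt(max(inner, 0.0)))
    return float(np.clip(p, 0.0, 1.0))


def transform_table(table: StudyTable) -> list[TransformedEffect]:
    return [ft_transform(r.events, r.n, r.study_id) for r in table]


def _heterogeneity(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Cochran's Q, DL tau^2 and I^2 from fixed-effect weights."""
    w = 1.0 / v
    t_fe = float(np.sum(w * t) / np.sum(w))
    Q = float(np.sum(w * (t - t_fe) ** 2))
    k = len(t)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if k > 1 and denom > 0 else 0.0
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return Q, tau2, I2


def _pooled(
    effects: Sequence[TransformedEffect],
    tau2: float,
    Q: float,
    I2: float,
    method: str,
    back_transform: str,
    label: str,
    fixed_fallback: bool = False,
) -> PooledResult:
    t = np.array([e.t for e in effects])
    v = np.array([e.v for e in effects])
    n = np.array([e.n for e in effects])
    w = 1.0 / (v + tau2)
    t_bar = float(np.sum(w * t) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    n_h = float(len(n) / np.sum(1.0 / n))
    est = ft_back_transform(t_bar, n_h, method=back_transform)
    lo = ft_back_transform(max(t_bar - Z975 * se, 0.0), n_h, method=back_transform)
    hi = ft_back_transform(min(t_bar + Z975 * se, math.pi / 2), n_h, method=back_transform)
    return PooledResult(
        estimate=est,
        ci_low=min(lo, est),
        ci_high=max(hi, est),
        tau2=tau2,
        Q=Q,
        I2=I2,
        method=method,
        k=len(effects),
        n_harmonic=n_h,
        t_bar=t_bar,
        se_t=se,
        back_transform=back_transform,
        label=label,
        fixed_fallback=fixed_fallback,
    )


def pool_fixed(
    effects: Sequence[TransformedEffect],
    back_transform: str = "asin",
    label: str = "",
) -> PooledResult:
    """Inverse-variance fixed-effect pooling on the transformed scale."""
    if len(effects) < 1:
        raise ValueError("pool_fixed needs at least one study")
    t = np.array([e.t for e in effects])
    v = np.array([e.v for e in effects])
    Q, _, I2 = _heterogeneity(t, v) if len(effects) > 1 else (0.0, 0.0, 0.0)
    return _pooled(effects, 0.0, Q, I2, "fixed", back_transform, label)


def pool_random_dl(
    effects: Sequence[TransformedEffect],
    back_transform: str = "asin",
    label: str = "",
) -> PooledResult:
    """DerSimonian–Laird random-effects pooling on the transformed scale."""
    if len(effects) < 2:
        raise InsufficientStudiesError(
            "random-effects pooling needs k >= 2 studies; use pool_fixed for k = 1"
        )
    t = np.array([e.t for e in effects])
    v = np.array([e.v for e in effects])
    Q, tau2, I2 = _heterogeneity(t, v)
    return _pooled(effects, tau2, Q, I2, "random_DL", back_transform, label)


def egger_test(effects: Sequence[TransformedEffect]) -> EggerResult:
    """Egger's regression test for funnel-plot asymmetry.

    Ordinary least squares of the standardized effect ``z_i = t_i/√v_i``
    on precision ``1/√v_i``; the intercept's two-sided p-value comes
    from a t distribution with k − 2 degrees of freedom.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs k >= 3 studies, got {k}")
    t = np.array([e.t for e in effects])
    se = np.sqrt(np.array([e.v for e in effects]))
    z = t / se
    prec = 1.0 / se
    X = np.column_stack([np.ones(k), prec])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    sigma2 = float(resid @ resid) / (k - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_b0 = math.sqrt(cov[0, 0])
    t_stat = beta[0] / se_b0 if se_b0 > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t_stat), df=k - 2)
    return EggerResult(
        intercept=float(beta[0]),
        se_intercept=se_b0,
        t_stat=float(t_stat),
        p_value=float(p),
        k=k,
    )


def leave_one_out(
    table: StudyTable, back_transform: str = "asin"
) -> list[PooledResult]:
    """Re-pool (DL) with each study removed in turn."""
    if len(table) < 3:
        raise InsufficientStudiesError("leave-one-out needs k >= 3 studies")
    effects = transform_table(table)
    results = []
    for i, omitted in enumerate(table.study_ids):
        subset = effects[:i] + effects[i + 1 :]
        results.append(
            pool_random_dl(subset, back_transform=back_transform, label=f"omit:{omitted}")
        )
    return results


def subgroup_pool(
    table: StudyTable,
    selector: Callable[[StudyRecord], bool],
    label: str = "",
    back_transform: str = "asin",
) -> PooledResult:
    """DL pooling restricted to the studies a predicate retains.

    A single retained study falls back to fixed-effect pooling and the
    result carries ``fixed_fallback=True``.
    """
    subset = table.select(selector, label=label)
    if len(subset) == 0:
        raise EmptySelectionError(f"selector {label or selector!r} retained no studies")
    effects = transform_table(subset)
    if len(effects) < 2:
        result = pool_fixed(effects, back_transform=back_transform, label=label)
        return PooledResult(**{**result.__dict__, "fixed_fallback": True})
    return pool_random_dl(effects, back_transform=back_transform, label=label)


# Predefined sensitivity/subgroup selectors ---------------------------------

def by_design(design: str) -> Callable[[StudyRecord], bool]:
    return lambda r: r.design == design


def by_bias_class(bias_class: str) -> Callable[[StudyRecord], bool]:
    return lambda r: r.bias_class == bias_class


def min_n(threshold: int = 20) -> Callable[[StudyRecord], bool]:
    """Exclude small studies (fewer than ``threshold`` participants)."""
    return lambda r: r.n >= threshold
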