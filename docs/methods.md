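# Methods

This note records the models implemented by `raremeta`, the choices
made where the design was genuinely open, and what the test suite does
and does not establish.

## Data model

One row per study: patients receiving a peripheral vasopressor
infusion (`n`), local adverse events (`events`), the printed event
percentage, care-setting tags (PICU, ER, WARD, TRANSPORT), design
(prospective/retrospective), a 0–9 methodological-quality score
(classed low ≥ 7, moderate 4–6, high ≤ 3), optional infusion-duration
medians/IQRs and per-agent patient counts.

The bundled table prints percentages, not counts, so counts are
derived as `round(n·pct/100)` with ties away from zero; a re-derived
percentage must agree with the printed one within 0.15 points (one
decimal of printing slack).  One row (Kohn-Loncarica, 2.0% of 56) is
internally inconsistent with *every* integer count under that
tolerance; the record validator therefore also accepts a stored count
equal to the nearest integer, and `derive_event_count` raises the
documented inconsistency error for that input.  Two totals coexist in
the source and are deliberately not reconciled: sums over the table
rows (29 events / 1,510 patients) and the free-text totals (31 / 1,575,
and 4 / 141 for the no-dopamine subgroup).  The records carry the
table-level counts; the text totals are module constants used for the
crude worked examples.  Per-agent counts are stored but excluded from
validation (the source's agent table mixes patients and infusions).

## Frequentist synthesis

Freeman–Tukey double-arcsine transform with variance `1/(4n+2)`;
inverse-variance fixed-effect pooling; DerSimonian–Laird moment
estimator `τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`; `I² = max(0,
(Q−(k−1))/Q)·100`.  Both truncations are explicit.  95% intervals use
the normal quantile 1.959964 on the transformed scale and are
back-transformed bound-by-bound.

**Back-transformation.**  Two inversions are provided.  Miller's
harmonic-mean inversion (applied to the doubled angle `2t̄`) round-trips
a single study's transform to exactly `y/n` and is the default of
`ft_back_transform`.  For *pooled* values, however, the package
defaults to the plain `sin²(t̄)` inversion: on zero-heavy tables the
harmonic-mean correction with a small `n̄_h` (86.7 here) drags the
pooled estimate below every study with events, and the `sin²` variant
is the one under which the pooled transformed-scale interval agrees
with classically reported results for this dataset (lower bound 1.41%).
Both variants are a keyword away (`back_transform="miller"|"asin"`),
and the Miller pooled numbers are pinned in the tests against an
independent metafor run.

Egger's test is the classic intercept variant: OLS of `t_i/√v_i` on
`1/√v_i`, two-sided p from t with k−2 df.  The "exclude studies with
n < 20" sensitivity selector is implemented although it is a no-op on
the bundled table (smallest study: n = 32).

## Hierarchical logit-normal model

`y_i ~ Binomial(n_i, p_i)`, `logit(p_i) = μ + u_i`, `u_i ~ N(0, τ²)`.
Default priors `μ ~ N(logit 0.02, 1.5²)`, `τ ~ Half-Normal(0, 0.5)`;
named alternatives: `broad_priors` (2.0 / Half-Normal 1.0) and
`abstract_priors` (`μ ~ N(0,1)`, `τ ~ Half-Cauchy(1)`) — the latter two
prior sets circulate for this analysis and both are preserved rather
than reconciled.  "Pooled rate" means `invlogit(μ)`, the rate of a
typical study (`u_i = 0`), not the marginal mean over `u`; credible
intervals are equal-tailed.

**Sampler.**  Adaptive Metropolis-within-Gibbs on the non-centered
parameterization `u_i = τ z_i`, with τ sampled on the log scale
(Jacobian included).  The centered parameterization has an unbounded
density spike at τ → 0 (the usual funnel) that defeats joint-mode
methods on rare-event data, which is why non-centering is not optional
here.  Each stored iteration performs 5 full sweeps; a sweep updates
(a) the whole z-block at once — valid because the `z_i` are
conditionally independent given (μ, τ) — (b) μ, (c) log τ, and (d) two
likelihood-invariant ancillary moves (translate μ compensating in z;
rescale τ compensating in z) that mix the ridge directions which
appear when single large studies dominate.  Proposal scales adapt
toward 44% acceptance during warmup only, so the post-warmup kernel is
a valid fixed MCMC kernel.  Chains start overdispersed around the
prior; the first half of each chain is warmup (the chain-geometry
convention "2,000 iterations" does not specify a warmup split).

Diagnostics are rank-normalized split R̂ and bulk ESS (arviz) per
parameter; sampling raises a non-convergence error carrying the
diagnostics if R̂(μ) or R̂(τ) ≥ 1.01.  On the bundled table the sampler
was verified against an independent numerical-integration oracle
(Gauss–Hermite quadrature over each `u_i`, dense grid over (μ, τ)); the
test suite pins the posterior mean to that oracle's value within MC
tolerance.  The log joint density itself is unit-tested term-by-term
against scipy distributions at 1e-10.

## Empirical-Bayes Beta–Binomial model

Marginal pmf via log-gamma throughout; hyperparameters maximize the
marginal likelihood over `(log a, log b)` (L-BFGS-B, bounds
`[1e-3, 1e6]`, multi-start: method-of-moments plus mean-2% starts at
concentrations 10/100/1000; ties broken by likelihood then smaller a).
Threshold probabilities and credible intervals are computed from the
fitted population Beta(â, b̂) via the regularized incomplete beta —
the reading under which published threshold values (68% below 2%, 99%
below 3%) are reproducible — not from a hyperparameter posterior.
Predictive proportion quantiles use the discrete-CDF convention
(smallest support point reaching the level), which makes "0–5% in a
future study of 100–300 patients" a reproducible ≤ bound.

**Boundary behavior.**  When the counts show no detectable
overdispersion — true of the bundled table, whose Q statistic sits
below its degrees of freedom — the marginal likelihood increases
monotonically in `a+b` and the fit runs to the bounded
no-overdispersion corner with the mean pinned near the crude rate.
This is the honest MLE for such data, and it is why the package treats
externally reported interior hyperparameters as *inputs*
(`BetaBinomFit.from_hyperparameters`) when reproducing published
population summaries, while reporting its own fit as computed.  On
synthetic data with real overdispersion (e.g. truth Beta(16, 900),
K = 100, n_i = 1000) the fit recovers the population mean to within a
few percent, which the tests assert.

**Subgroups.**  Transport assignment: a study is "transport" only if
TRANSPORT is its sole setting tag; multi-setting studies count as
in-hospital.  Catecholamine regimen: the any-exposure rule (any
dopamine/dobutamine count > 0) is available but leaves a single
epi/norepi-only study on the bundled table, so the comparison used in
the consolidated report is predominant-agent (dopamine+dobutamine
patient count exceeds epinephrine+norepinephrine), a 4-vs-7 split.
Comparisons fit each side independently and estimate P(A > B) from
seeded Monte Carlo draws of the two population Betas (default 100,000
draws), checked against a quadrature oracle in the tests.  With
boundary fits the population Betas are nearly degenerate, so the
transport-vs-in-hospital probability saturates near 1 rather than an
interior value; the direction and the subgroup means (~3.0% vs ~1.8%)
are the robust content.

## Synthetic data

`simulate_study_table` draws sizes (fixed list, or log-uniform on
[30, 400] — chosen to mimic the bundled table's 32–369 spread), rates
from the chosen population, and binomial counts; output uses the exact
CSV schema of the real table.  Seeding: `default_rng([seed,
replicate_id])`, so replicates are independently reproducible.
Zero-event tables are legal outputs; the Beta–Binomial fit refuses them
with a boundary error, which the recovery harness records as a failure
rate rather than raising.

What the generator does *not* emulate: publication/selection effects,
reporting differences in adverse-event definitions, within-study
covariates, or infusion-duration/time-to-event structure.  Passing
recovery and coverage tests therefore show correctness of the
estimators *under the assumed sampling models*, not robustness to
those real-data complications.

## Problem sizes used in the checks

Calibration checks run at desk scale: empirical-Bayes recovery at
K = 100 studies of n = 1000 over 20 replicates (relative bias of the
population mean < 5%); MCMC interval coverage at K = 30 studies of
n = 500 over 50 replicates (95% CrI covers the true pooled rate in at
least 90% of replicates); cross-model agreement between the
logit-normal pooled mean and the Beta–Binomial population mean within
0.3 percentage points on the bundled table.

## Known limitations

- The marginal likelihood in `(a, b)` is nearly flat along the
  concentration direction for homogeneous tables; only the mean is
  well identified there, and reported `(â, b̂)` should not be
  over-interpreted in that regime.
- The Metropolis-within-Gibbs sampler is tuned for small-K
  meta-analytic posteriors; very large K or extreme imbalance would
  warrant gradient-based sampling.
- Percentage-derived counts inherit one-decimal printing error; the
  bundled table's two totals conventions (29/1510 vs 31/1575) bracket
  the resulting uncertainty and neither is privileged.
- Wilson intervals are used for all crude proportions, including the
  k = 1 fallback in subgroup pooling; exact (Clopper–Pearson) bounds
  are not offered.
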