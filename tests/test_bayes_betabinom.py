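import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from raremeta import bayes_betabinom as bb
from raremeta import synthetic
from raremeta.errors import BoundaryError, InsufficientStudiesError
from raremeta.study_table import StudyRecord, StudyTable


def _table(counts):
    return StudyTable(
        records=tuple(
            StudyRecord(
                study_id=f"s{i}",
                year=2020,
                n=n,
                events=y,
                event_pct=None,
                settings=frozenset({"PICU"}),
                design="retrospective",
                bias_score=9,
            )
            for i, (y, n) in enumerate(counts)
        )
    )


class TestLogPmf:
    def test_uniform_marginal(self):
        """a = b = 1 gives the discrete uniform on 0..n."""
        for n in (1, 7, 50):
            for y in (0, n // 2, n):
                assert bb.beta_binomial_log_pmf(y, n, 1.0, 1.0) == pytest.approx(
                    -math.log(n + 1), rel=1e-12
                )

    def test_zero_event_reduction(self):
        val = bb.beta_binomial_log_pmf(0, 32, 16.48, 889.29)
        expected = special.betaln(16.48, 921.29) - special.betaln(16.48, 889.29)
        assert val == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "y,n,a,b", [(2, 50, 2.0, 30.0), (0, 100, 16.48, 889.29), (10, 10, 0.5, 0.5)]
    )
    def test_against_scipy_betabinom(self, y, n, a, b):
        assert bb.beta_binomial_log_pmf(y, n, a, b) == pytest.approx(
            stats.betabinom.logpmf(y, n, a, b), rel=1e-10
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bb.beta_binomial_log_pmf(5, 4, 1.0, 1.0)
        with pytest.raises(ValueError):
            bb.beta_binomial_log_pmf(1, 4, -1.0, 1.0)

    @settings(deadline=None, max_examples=40)
    @given(
        st.integers(min_value=1, max_value=200),
        st.floats(min_value=0.05, max_value=50.0),
        st.floats(min_value=0.05, max_value=900.0),
    )
    def test_pmf_normalization(self, n, a, b):
        support = np.arange(n + 1)
        total = np.exp(bb.beta_binomial_log_pmf(support, n, a, b)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_binomial_limit(self):
        """a + b -> inf at fixed mean converges to Binomial(n, p)."""
        n, p, conc = 50, 0.02, 1e6
        support = np.arange(n + 1)
        pmf = np.exp(bb.beta_binomial_log_pmf(support, n, p * conc, (1 - p) * conc))
        tv = 0.5 * np.abs(pmf - stats.binom.pmf(support, n, p)).sum()
        assert tv < 1e-4


class TestMarginalLogLik:
    def test_uniform_case(self):
        table = _table([(1, 10), (3, 25)])
        assert bb.marginal_log_likelihood(1.0, 1.0, table) == pytest.approx(
            -math.log(11) - math.log(26), rel=1e-12
        )

    def test_term_by_term_oracle_on_bundled(self, bundled):
        a, b = 16.48, 889.29
        oracle = sum(
            float(stats.betabinom.logpmf(r.events, r.n, a, b)) for r in bundled
        )
        assert bb.marginal_log_likelihood(a, b, bundled) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_reorder_invariance(self, bundled):
        reordered = StudyTable(records=tuple(reversed(bundled.records)))
        assert bb.marginal_log_likelihood(2.0, 100.0, bundled) == pytest.approx(
            bb.marginal_log_likelihood(2.0, 100.0, reordered), rel=1e-14
        )


class TestFit:
    def test_preconditions(self):
        with pytest.raises(InsufficientStudiesError):
            bb.fit_empirical_bayes(_table([(1, 50)]))
        with pytest.raises(BoundaryError):
            bb.fit_empirical_bayes(_table([(0, 50), (0, 80)]))

    def test_fit_maximizes_over_starts(self, eb_fit):
        best = max(r["loglik"] for r in eb_fit.optimizer_record)
        assert eb_fit.max_marginal_loglik == pytest.approx(best)
        assert eb_fit.a_hat > 0 and eb_fit.b_hat > 0

    def test_bundled_fit_mean_near_crude_rate(self, eb_fit, bundled):
        # this table shows no detectable overdispersion, so the optimizer
        # runs toward the large-concentration boundary; the mean is what
        # remains identified
        assert eb_fit.mean == pytest.approx(bundled.total_events / bundled.total_n, abs=0.002)

    def test_identical_large_studies_push_to_no_overdispersion(self):
        table = _table([(200, 10_000), (200, 10_000)])
        fit = bb.fit_empirical_bayes(table)
        assert fit.a_hat + fit.b_hat > 1e4
        assert fit.mean == pytest.approx(0.02, abs=0.001)

    def test_parameter_recovery_large_sample(self):
        """K=200 studies of n=2000 from Beta(16, 900): mean recovered to 10%."""
        truth = synthetic.BetaPopulation(16.0, 900.0)
        table = synthetic.simulate_study_table(
            synthetic.SyntheticConfig(
                K=200,
                truth=truth,
                size_policy=synthetic.SizePolicy(kind="fixed", sizes=(2000,) * 200),
                seed=42,
            )
        )
        fit = bb.fit_empirical_bayes(table)
        assert fit.mean == pytest.approx(truth.mean, rel=0.10)


class TestPopulationSummary:
    def test_reported_hyperparameters_roundtrip(self, paper_fit):
        pop = bb.population_summary(paper_fit, thresholds=(0.02, 0.03))
        assert round(100 * pop.mean, 1) == 1.8
        assert 100 * pop.quantiles[0.025] == pytest.approx(1.0, abs=0.06)
        assert round(100 * pop.quantiles[0.975], 1) == 2.8
        assert round(100 * pop.threshold_probs[0.02]) == 68
        assert round(100 * pop.threshold_probs[0.03]) == 99

    def test_cdf_monotone_and_inverse(self, paper_fit):
        thresholds = (0.005, 0.01, 0.02, 0.03, 0.05)
        pop = bb.population_summary(paper_fit, thresholds=thresholds)
        vals = [pop.threshold_probs[t] for t in thresholds]
        assert vals == sorted(vals)
        a, b = paper_fit.a_hat, paper_fit.b_hat
        for q, x in pop.quantiles.items():
            assert stats.beta.cdf(x, a, b) == pytest.approx(q, abs=1e-9)

    def test_invalid_threshold(self, paper_fit):
        with pytest.raises(ValueError):
            bb.population_summary(paper_fit, thresholds=(0.0,))


class TestShrinkage:
    def test_zero_event_study_pulled_up(self, paper_fit, bundled):
        df = bb.study_shrinkage_estimates(paper_fit, bundled)
        charbel = df[df.study_id == "Charbel"].iloc[0]
        assert charbel["posterior_mean"] == pytest.approx(16.48 / 937.77, rel=1e-6)
        assert charbel["posterior_mean"] > 0.0

    def test_population_mean_is_fixed_point(self, paper_fit):
        p = paper_fit.mean
        n = 10_000
        y = round(p * n)
        table = _table([(y, n)])
        # choose n so y/n equals the population mean exactly
        assert y / n == pytest.approx(p, abs=1e-4)
        df = bb.study_shrinkage_estimates(paper_fit, table)
        assert df.iloc[0]["posterior_mean"] == pytest.approx(p, abs=1e-4)

    def test_convex_combination_property(self, paper_fit, bundled):
        df = bb.study_shrinkage_estimates(paper_fit, bundled)
        pop_mean = paper_fit.mean
        for _, row in df.iterrows():
            lo, hi = sorted((row["crude_rate"], pop_mean))
            assert lo - 1e-12 <= row["posterior_mean"] <= hi + 1e-12


class TestPredictive:
    def test_pmf_sums_to_one(self, paper_fit):
        pred = bb.predictive_distribution(paper_fit, 250)
        assert pred.pmf.sum() == pytest.approx(1.0, abs=1e-10)
        qs = [pred.quantiles[q] for q in sorted(pred.quantiles)]
        assert qs == sorted(qs)

    def test_upper_quantile_at_most_five_percent(self, paper_fit):
        for n_future in (100, 200, 300):
            pred = bb.predictive_distribution(paper_fit, n_future)
            assert pred.quantiles[0.975] <= 0.05

    def test_mean_independent_of_size(self, paper_fit):
        means = {
            bb.predictive_distribution(paper_fit, n).mean_proportion
            for n in (50, 100, 300)
        }
        assert len(means) == 1

    def test_variance_decreases_with_size(self, paper_fit):
        variances = [
            bb.predictive_distribution(paper_fit, n).variance_proportion()
            for n in (50, 100, 200, 400)
        ]
        assert all(a > b for a, b in zip(variances, variances[1:]))


class TestPPC:
    def test_bundled_counts_inside_their_intervals(self, eb_fit, bundled):
        report = bb.posterior_predictive_check(eb_fit, bundled)
        assert report.fraction_inside == 1.0

    def test_extreme_outlier_flagged(self, paper_fit):
        table = _table([(50, 50), (1, 100)])
        report = bb.posterior_predictive_check(paper_fit, table)
        row = report.table[report.table.study_id == "s0"].iloc[0]
        assert not row["inside"]
        assert row["midp_two_sided"] < 0.001

    def test_calibration_on_simulated_data(self):
        """~95% of counts drawn from the model fall inside their intervals."""
        fit = bb.BetaBinomFit.from_hyperparameters(16.0, 900.0)
        rng = np.random.default_rng(7)
        K = 60
        inside = []
        for rep in range(10):
            n = np.full(K, 300)
            p = rng.beta(16.0, 900.0, K)
            y = rng.binomial(n, p)
            table = _table(list(zip(y.tolist(), n.tolist())))
            inside.append(bb.posterior_predictive_check(fit, table).fraction_inside)
        # discrete intervals over-cover slightly; allow binomial MC slack
        assert np.mean(inside) == pytest.approx(0.96, abs=0.03)


class TestSubgroups:
    def test_catecholamine_partitions(self, bundled):
        exposed = [r.study_id for r in bundled if bb.dopamine_or_dobutamine(r)]
        assert len(exposed) == 10  # any-exposure leaves only Lampin on the other side
        predominant = {r.study_id for r in bundled if bb.dopamine_dobutamine_predominant(r)}
        assert predominant == {"Kumar", "Levy", "Patregnani", "Yeong"}

    def test_transport_policy(self, bundled):
        transport = [r.study_id for r in bundled if bb.transport_only(r)]
        assert transport == ["Charbel", "Peshiman"]
        # multi-setting Patregnani is assigned in-hospital
        patregnani = next(r for r in bundled if r.study_id == "Patregnani")
        assert bb.in_hospital(patregnani)

    def test_transport_vs_in_hospital(self, bundled):
        cmp = bb.compare_subgroups(
            bundled,
            bb.transport_only,
            bb.in_hospital,
            "transport",
            "in_hospital",
            mc_draws=50_000,
            seed=1,
        )
        assert cmp.mean_a == pytest.approx(0.030, abs=0.005)
        assert cmp.mean_b == pytest.approx(0.018, abs=0.004)
        assert cmp.p_a_greater_b > 0.5
        assert cmp.p_a_greater_b + cmp.p_b_greater_a == pytest.approx(1.0)

    def test_identical_sides_symmetric(self, bundled):
        cmp = bb.compare_subgroups(
            bundled, lambda r: True, lambda r: True, "all", "all2",
            mc_draws=100_000, seed=3,
        )
        assert cmp.p_a_greater_b == pytest.approx(0.5, abs=0.02)

    def test_mc_matches_quadrature_oracle(self):
        """P(A > B) by Monte Carlo agrees with numerical integration."""
        a1, b1, a2, b2 = 4.0, 120.0, 6.0, 260.0
        fit_a = bb.BetaBinomFit.from_hyperparameters(a1, b1)
        fit_b = bb.BetaBinomFit.from_hyperparameters(a2, b2)
        mc_draws = 200_000
        rng = np.random.default_rng(9)
        pa = rng.beta(a1, b1, mc_draws)
        pb = rng.beta(a2, b2, mc_draws)
        p_mc = float(np.mean(pa > pb))
        p_quad, _ = integrate.quad(
            lambda x: stats.beta.pdf(x, a1, b1) * stats.beta.cdf(x, a2, b2), 0, 1
        )
        se = math.sqrt(p_quad * (1 - p_quad) / mc_draws)
        assert abs(p_mc - p_quad) < 3 * se

    def test_all_zero_side_rejected(self, bundled):
        with pytest.raises(BoundaryError, match="zero_side"):
            bb.compare_subgroups(
                bundled,
                lambda r: r.events == 0,
                lambda r: r.events > 0,
                "zero_side",
                "rest",
            )
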