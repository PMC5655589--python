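import numpy as np
import pytest

from dlqimap import prediction as pred
from dlqimap.instruments import EQ5D_DOMAINS
from dlqimap.olr import CovariateVector, DomainModel, MappingModel
from dlqimap.synthetic import CohortConfig, generate_cohort


def _forced_model(a1=50.0, a2=60.0):
    """A mapping model whose p1 is ~1 in every domain (or adjustable)."""
    return MappingModel(domains={
        d: DomainModel(domain=d, a1=a1, a2=a2, b_age=0.0, b_sex=0.0, b_items=(0.0,) * 10)
        for d in EQ5D_DOMAINS
    })


class TestSampleDomain:
    def test_degenerate_distributions(self):
        rng = np.random.default_rng(0)
        assert all(pred.sample_domain(1.0, 0.0, 0.0, rng) == 1 for _ in range(20))
        assert all(pred.sample_domain(0.0, 0.0, 1.0, rng) == 3 for _ in range(20))

    def test_empirical_frequencies_match(self):
        rng = np.random.default_rng(123)
        p = (0.5, 0.4, 0.1)
        n = 100_000
        draws = np.array([pred.sample_domain(*p, rng) for _ in range(n)])
        for k, pk in enumerate(p, start=1):
            freq = (draws == k).mean()
            assert abs(freq - pk) < 3 * np.sqrt(pk * (1 - pk) / n)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            pred.sample_domain(-0.1, 0.6, 0.5, np.random.default_rng(0))


class TestMonteCarlo:
    def test_forced_full_health(self, tiny_cohort):
        preds = pred.predict_utility_mc(_forced_model(), tiny_cohort, reps=3, seed=0)
        for p in preds:
            assert np.all(p.utilities == 1.0)
            assert p.mean_utility == 1.0
            assert p.analytic_expected_utility == pytest.approx(1.0, abs=1e-9)

    def test_reproducible_and_order_independent(self, small_cohort, published_model):
        a = pred.predict_utility_mc(published_model, small_cohort, reps=5, seed=9)
        b = pred.predict_utility_mc(published_model, small_cohort, reps=5, seed=9)
        shuffled = small_cohort.sample(frac=1.0, random_state=3).reset_index(drop=True)
        c = {p.subject_id: p for p in pred.predict_utility_mc(published_model, shuffled, reps=5, seed=9)}
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.states, pb.states)
            assert pa.mean_utility == pb.mean_utility
            assert np.array_equal(pa.states, c[pa.subject_id].states)

    def test_cohort_mean_matches_analytic(self, published_model):
        cohort = generate_cohort(CohortConfig(n=400, missing_rate=0.0, seed=21))
        preds = pred.predict_utility_mc(published_model, cohort, reps=100, seed=2)
        mc = np.array([p.mean_utility for p in preds])
        an = np.array([p.analytic_expected_utility for p in preds])
        # SE of the cohort MC mean from per-rep spread
        per_rep_var = np.array(
            [np.var(p.utilities, ddof=1) for p in preds]
        )
        se = np.sqrt(per_rep_var.sum() / 100) / len(preds)
        assert abs(mc.mean() - an.mean()) < 3 * max(se, 1e-6)

    def test_rep_averaging_reduces_variance(self, published_model):
        cohort = generate_cohort(CohortConfig(n=300, missing_rate=0.0, seed=31))
        p1 = pred.predict_utility_mc(published_model, cohort, reps=1, seed=4)
        p5 = pred.predict_utility_mc(published_model, cohort, reps=5, seed=4)
        an = np.array([p.analytic_expected_utility for p in p1])
        err1 = np.array([p.mean_utility for p in p1]) - an
        err5 = np.array([p.mean_utility for p in p5]) - an
        ratio = np.var(err1) / np.var(err5)
        assert 3.0 < ratio < 8.0  # sampling theory: ~5x shrinkage

    def test_full_health_is_reachable(self, published_model, tiny_cohort):
        """The ordinal route can emit a predicted utility of exactly 1."""
        preds = pred.predict_utility_mc(published_model, tiny_cohort, reps=50, seed=0)
        young_healthy = preds[0]  # age 30, all-zero DLQI
        assert np.any(young_healthy.utilities == 1.0)


class TestAnalyticExpectation:
    def test_forced_level3(self, tiny_cohort):
        m = _forced_model(a1=-60.0, a2=-50.0)  # p3 ~ 1 in every domain
        vals = pred.expected_utility_analytic(m, tiny_cohort)
        np.testing.assert_allclose(vals, -0.594, atol=1e-9)

    def test_matches_high_rep_monte_carlo(self, published_model, tiny_cohort):
        cov = CovariateVector(age=55.5, sex=1, items=(2, 1, 0, 3, 0, 0, 1, 0, 0, 1))
        exact = pred.expected_utility_analytic(published_model, cov)
        preds = pred.predict_utility_mc(published_model, tiny_cohort, reps=10_000, seed=8)
        p = preds[1]  # same covariates as cov
        se = np.std(p.utilities, ddof=1) / np.sqrt(p.reps)
        assert p.analytic_expected_utility == pytest.approx(exact, abs=1e-12)
        assert abs(p.mean_utility - exact) < 3 * se


class TestLinearComparator:
    def test_exact_linear_relation_recovered(self):
        totals = np.arange(0, 31)
        m = pred.fit_linear_cc(totals, 0.95 - 0.02 * totals)
        assert m.a == pytest.approx(0.95, abs=1e-12)
        assert m.b == pytest.approx(0.02, abs=1e-12)

    def test_line_through_two_points(self):
        m = pred.fit_linear_cc([0, 30], [1.0, 0.4])
        assert (m.a, m.b) == (pytest.approx(1.0), pytest.approx(0.02))

    @pytest.mark.parametrize(
        "a, b, total, expected",
        [(1.0, 0.02, 0, 1.0), (1.0, 0.02, 30, 0.4), (0.95, 0.03, 10, 0.65)],
    )
    def test_prediction(self, a, b, total, expected):
        assert pred.predict_linear_cc(pred.LinearModel(a, b), total) == pytest.approx(
            expected, abs=1e-12
        )

    def test_bounded_above_by_intercept(self):
        m = pred.LinearModel(a=0.93, b=0.015)
        totals = np.arange(0, 31)
        assert np.all(pred.predict_linear_cc(m, totals) <= m.a)

    def test_constant_totals_rejected(self):
        with pytest.raises(ValueError, match="non-estimable"):
            pred.fit_linear_cc([5, 5, 5], [0.7, 0.8, 0.9])
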