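import numpy as np
import pytest

from dlqimap import validation as val


class TestSplitPlan:
    def test_even_halving(self, small_cohort):
        plan = val.make_split_plan(small_cohort, n_splits=5, seed=0)
        assert plan.n_splits == 5
        for a, b in plan.assignments:
            assert len(a) == len(b) == 300
            assert set(a) | set(b) == set(small_cohort["id"])
            assert not set(a) & set(b)

    def test_odd_cohort_extra_to_a(self, small_cohort):
        plan = val.make_split_plan(small_cohort.head(7), n_splits=2, seed=1)
        for a, b in plan.assignments:
            assert (len(a), len(b)) == (4, 3)

    def test_deterministic(self, small_cohort):
        p1 = val.make_split_plan(small_cohort, 3, seed=5)
        p2 = val.make_split_plan(small_cohort, 3, seed=5)
        assert p1 == p2

    def test_tiny_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            val.make_split_plan(small_cohort.head(1))


class TestEvaluate:
    def test_perfect_prediction(self):
        m = val.evaluate([0.5, 0.7], [0.5, 0.7])
        assert (m.mean_difference, m.mse, m.mae) == (0.0, 0.0, 0.0)
        assert all(v == 100.0 for v in m.pct_within.values())

    def test_constant_offset(self):
        obs = np.array([0.2, 0.4, 0.6])
        m = val.evaluate(obs + 0.1, obs)
        assert m.mean_difference == pytest.approx(0.1, abs=1e-12)
        assert m.mse == pytest.approx(0.01, abs=1e-12)
        assert m.mae == pytest.approx(0.1, abs=1e-12)
        assert m.pct_within[0.1] == 100.0

    def test_hand_computed_spread(self):
        m = val.evaluate([0.3, 0.5, 0.9], [0.5, 0.5, 0.7])  # diffs -0.2, 0, 0.2
        assert m.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert m.mse == pytest.approx(0.08 / 3, abs=1e-12)
        assert m.mae == pytest.approx(0.4 / 3, abs=1e-12)
        assert m.pct_within[0.1] == pytest.approx(100 / 3)

    def test_pct_within_monotone_and_mae_vs_rmse(self):
        rng = np.random.default_rng(2)
        obs = rng.uniform(-0.5, 1.0, 200)
        pred = obs + rng.normal(0, 0.2, 200)
        m = val.evaluate(pred, obs)
        assert m.pct_within[0.1] <= m.pct_within[0.2] <= m.pct_within[0.3]
        assert m.mae <= np.sqrt(m.mse)

    def test_histogram_fixed_bins(self):
        m = val.evaluate([0.05], [0.0])  # diff 0.05 -> bin [0.0, 0.1)
        assert m.histogram.sum() == 1
        assert m.histogram[16] == 1  # 32 bins over [-1.6, 1.6]

    def test_symmetric_under_permutation(self):
        pred, obs = np.array([0.1, 0.5, 0.9]), np.array([0.2, 0.4, 0.8])
        m1 = val.evaluate(pred, obs)
        m2 = val.evaluate(pred[::-1], obs[::-1])
        assert m1.mse == m2.mse and m1.mae == m2.mae

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            val.evaluate([0.1], [0.1, 0.2])


class TestCrossValidate:
    def test_linear_method_schema_and_determinism(self, small_cohort):
        cohort = small_cohort.copy()
        report = val.cross_validate(cohort, method="linear", n_splits=2, seed=3)
        assert len(report.exercises) == 4
        assert all(e.error is None for e in report.exercises)
        again = val.cross_validate(cohort, method="linear", n_splits=2, seed=3)
        assert report.aggregate.mse == again.aggregate.mse

    def test_olr_protocol_structure_and_aggregate(self, medium_cohort):
        report = val.cross_validate(medium_cohort, method="olr", n_splits=1, reps=5, seed=7)
        assert len(report.exercises) == 2  # halves swapped -> two exercises
        ok = [e.metrics for e in report.exercises if e.metrics]
        assert report.aggregate.mse == pytest.approx(np.mean([m.mse for m in ok]))
        assert report.aggregate.mean_difference == pytest.approx(
            np.mean([m.mean_difference for m in ok])
        )
        # halves of a 3000-subject cohort
        assert all(e.n_train == e.n_test == 1500 for e in report.exercises)

    def test_failed_exercise_is_marked_not_fatal(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["eq5d_mo"] = 1  # mobility outcome constant -> every fit fails
        report = val.cross_validate(cohort, method="olr", n_splits=1, seed=0)
        assert all(e.error is not None for e in report.exercises)
        assert report.aggregate is None


class TestSubgroupTransfer:
    def test_transfer_reports_sizes(self, medium_cohort):
        cohort = medium_cohort.copy()
        mask = np.zeros(len(cohort), bool)
        mask[:1200] = True
        res = val.subgroup_transfer(cohort, mask, ~mask, method="olr", seed=1)
        assert (res.n_train, res.n_test) == (1200, 1800)
        assert res.error is None
        assert res.metrics is not None

    def test_degenerate_domain_warning_propagates(self, medium_cohort):
        cohort = medium_cohort.copy()
        mask = np.zeros(len(cohort), bool)
        mask[:800] = True
        # erase all 'extreme' self-care answers in the training subgroup
        sub = cohort.loc[mask, "eq5d_sc"].replace(3, 2)
        cohort.loc[mask, "eq5d_sc"] = sub
        with pytest.warns(Warning):
            res = val.subgroup_transfer(cohort, mask, ~mask, method="olr", seed=1)
        assert any("self_care" in w for w in res.warnings)

    def test_overlapping_filters_rejected(self, small_cohort):
        mask = np.ones(len(small_cohort), bool)
        with pytest.raises(ValueError, match="overlap"):
            val.subgroup_transfer(small_cohort, mask, mask)

    def test_transfer_comparable_to_random_split(self, medium_cohort):
        """Same generating model on both sides: transfer metrics look like a
        random-split exercise of equal size."""
        rng = np.random.default_rng(0)
        mask = rng.random(len(medium_cohort)) < 0.5
        res = val.subgroup_transfer(medium_cohort, mask, ~mask, method="olr", seed=2)
        report = val.cross_validate(medium_cohort, method="olr", n_splits=1, seed=2)
        mse_cv = report.aggregate.mse
        assert res.metrics.mse == pytest.approx(mse_cv, rel=0.25)
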