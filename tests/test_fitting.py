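import numpy as np
import pandas as pd
import pytest

from dlqimap import fitting
from dlqimap.instruments import EQ5D_DOMAINS
from dlqimap.io import DLQI_COLS, EQ5D_COLS
from dlqimap.olr import DomainModel, MappingModel, bundled_model
from dlqimap.synthetic import CohortConfig, generate_cohort


def _counts_cohort(counts, domain="mobility"):
    """Cohort whose chosen domain outcome has the given category counts."""
    y = np.repeat([1, 2, 3], counts)
    n = len(y)
    df = pd.DataFrame({"id": [str(i) for i in range(n)], "age": 40.0, "sex": 0})
    for c in DLQI_COLS:
        df[c] = 0
    for c in EQ5D_COLS.values():
        df[c] = 1
    df[EQ5D_COLS[domain]] = y
    return df


class TestProportionalOddsFit:
    def test_intercept_only_closed_form(self):
        # thresholds = logits of cumulative proportions 0.5 and 0.8
        fr = fitting.fit_proportional_odds(_counts_cohort((50, 30, 20)), "mobility", "none")
        assert fr.params[0] == pytest.approx(0.0, abs=1e-6)
        assert fr.params[1] == pytest.approx(np.log(4), abs=1e-6)
        assert fr.converged

    def test_neg2ll_matches_multinomial_closed_form(self):
        cohort = _counts_cohort((50, 30, 20))
        fr = fitting.fit_proportional_odds(cohort, "mobility", "none")
        brute = -2 * (50 * np.log(0.5) + 30 * np.log(0.3) + 20 * np.log(0.2))
        assert fr.neg2_loglik == pytest.approx(brute, abs=1e-8)
        assert fitting.neg2_loglik(fr.model, cohort, "mobility") == pytest.approx(
            fr.neg2_loglik, abs=1e-8
        )

    def test_matches_statsmodels_ordered_model(self, medium_cohort):
        """Independent oracle: statsmodels' cumulative-logit MLE."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        cohort = medium_cohort
        fr = fitting.fit_proportional_odds(cohort, "pain_discomfort")
        X = cohort[["age", "sex"] + list(DLQI_COLS)].to_numpy(float)
        y = cohort[EQ5D_COLS["pain_discomfort"]].to_numpy(int)
        sm = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False, maxiter=500)
        thresholds = sm.model.transform_threshold_params(sm.params)[1:-1]
        np.testing.assert_allclose(fr.params[2:], sm.params[:12], atol=2e-4)
        np.testing.assert_allclose(fr.params[:2], thresholds, atol=2e-4)
        assert fr.neg2_loglik == pytest.approx(-2 * sm.llf, abs=1e-4)

    def test_parameter_recovery_and_local_optimality(self):
        truth = bundled_model()["usual_activities"]
        cohort = generate_cohort(CohortConfig(n=2000, missing_rate=0.0, seed=11))
        fr = fitting.fit_proportional_odds(cohort, "usual_activities")
        t = np.concatenate(([truth.a1, truth.a2], truth.slopes))
        assert np.all(np.abs(fr.params - t) / fr.se < 4)
        # local optimality probe: perturbing any parameter cannot lower -2LL
        for j in range(len(fr.params)):
            for delta in (-0.05, 0.05):
                p = fr.params.copy()
                p[j] += delta
                bumped = DomainModel(
                    domain="usual_activities", a1=p[0], a2=p[1], b_age=p[2],
                    b_sex=p[3], b_items=tuple(p[4:]),
                )
                assert (
                    fitting.neg2_loglik(bumped, cohort, "usual_activities")
                    >= fr.neg2_loglik - 1e-8
                )

    def test_degenerate_outcome_raises(self):
        with pytest.raises(fitting.DegenerateOutcomeError):
            fitting.fit_proportional_odds(_counts_cohort((100, 0, 0)), "mobility", "none")

    def test_empty_top_category_warns_and_reports_inf_threshold(self):
        cohort = _counts_cohort((60, 40, 0))
        with pytest.warns(fitting.DegenerateThresholdWarning):
            fr = fitting.fit_proportional_odds(cohort, "mobility", "none")
        assert fr.model.a2 == np.inf
        assert fr.model.se_a2 is None
        # the estimable threshold is still the cumulative logit of 0.6
        assert fr.params[0] == pytest.approx(np.log(0.6 / 0.4), abs=1e-6)

    def test_wald_coverage_near_nominal(self):
        """95% intervals cover the true slopes at roughly nominal rate."""
        truth = DomainModel(
            domain="anxiety_depression", a1=0.3, a2=2.0, b_age=0.01, b_sex=0.4,
            b_items=(0.2,) + (0.0,) * 9,
        )
        model = MappingModel(domains={
            d: truth if d == "anxiety_depression" else DomainModel(
                domain=d, a1=0.3, a2=2.0, b_age=0.01, b_sex=0.4, b_items=(0.2,) + (0.0,) * 9
            )
            for d in EQ5D_DOMAINS
        })
        t = np.concatenate(([truth.a1, truth.a2], truth.slopes))
        hits = 0
        trials = 0
        for s in range(120):
            cohort = generate_cohort(
                CohortConfig(n=400, missing_rate=0.0, seed=50_000 + s, generating_model=model)
            )
            fr = fitting.fit_proportional_odds(cohort, "anxiety_depression")
            for j in (0, 1, 3, 4):  # a1, a2, sex, item1
                trials += 1
                hits += abs(fr.params[j] - t[j]) <= 1.96 * fr.se[j]
        rate = hits / trials
        # binomial 3-sigma band around 0.95 (correlated within fits, so generous)
        assert 0.90 <= rate <= 0.99


class TestLrTest:
    def test_identical_models_give_zero(self, small_cohort):
        full = fitting.fit_proportional_odds(small_cohort, "pain_discomfort")
        t = fitting.LrTestResult(chi_square=0.0, df=10, p_value=1.0)
        assert t.p_value == 1.0
        red = fitting.fit_proportional_odds(small_cohort, "pain_discomfort", "age_sex")
        assert red.neg2_loglik >= full.neg2_loglik  # nested likelihoods ordered

    def test_chi_square_quantile(self, small_cohort):
        red = fitting.fit_proportional_odds(small_cohort, "pain_discomfort", "age_sex")
        full = fitting.fit_proportional_odds(small_cohort, "pain_discomfort")
        t = fitting.lr_test(red, full)
        assert t.df == 10
        from scipy.stats import chi2

        assert t.p_value == pytest.approx(chi2.sf(t.chi_square, 10), abs=1e-12)

    def test_df_by_parameter_counting(self, small_cohort):
        dlqi_only = fitting.fit_proportional_odds(small_cohort, "pain_discomfort", "dlqi")
        full = fitting.fit_proportional_odds(small_cohort, "pain_discomfort")
        assert fitting.lr_test(dlqi_only, full).df == 2

    def test_non_nested_rejected(self, small_cohort):
        a = fitting.fit_proportional_odds(small_cohort, "pain_discomfort", "age_sex")
        b = fitting.fit_proportional_odds(small_cohort, "pain_discomfort", "dlqi")
        with pytest.raises(ValueError, match="nested"):
            fitting.lr_test(a, b)

    def test_invariant_to_subject_order(self, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        t1 = fitting.lr_test(
            fitting.fit_proportional_odds(small_cohort, "anxiety_depression", "age_sex"),
            fitting.fit_proportional_odds(small_cohort, "anxiety_depression"),
        )
        t2 = fitting.lr_test(
            fitting.fit_proportional_odds(shuffled, "anxiety_depression", "age_sex"),
            fitting.fit_proportional_odds(shuffled, "anxiety_depression"),
        )
        assert t1.chi_square == pytest.approx(t2.chi_square, abs=1e-6)


class TestParallelism:
    def test_power_against_nonparallel_slopes(self):
        """Separate slope vectors per threshold must be detected."""
        rng = np.random.default_rng(5)
        n = 2000
        age = rng.uniform(18, 95, n)
        sex = rng.integers(0, 2, n)
        x1 = rng.integers(0, 4, n)
        # cumulative logits with slopes differing by 1.0 between thresholds
        z1 = 0.5 * x1
        z2 = 1.5 * x1
        u = rng.random(n)
        c1 = 1 / (1 + np.exp(z1 - 1.0))
        c2 = 1 / (1 + np.exp(z2 - 5.0))
        c2 = np.maximum(c1, c2)
        y = np.where(u < c1, 1, np.where(u < c2, 2, 3))
        df = pd.DataFrame({"id": [str(i) for i in range(n)], "age": age, "sex": sex})
        for c in DLQI_COLS:
            df[c] = 0
        df["dlqi1"] = x1
        for c in EQ5D_COLS.values():
            df[c] = 1
        df[EQ5D_COLS["mobility"]] = y
        res = fitting.test_parallelism(df, "mobility")
        assert res.p_value < 0.05

    def test_reliability_warning_for_sparse_top_category(self):
        cohort = _counts_cohort((300, 89, 11), domain="mobility")
        with pytest.warns(fitting.ParallelismReliabilityWarning, match="11 subjects"):
            res = fitting.test_parallelism(cohort, "mobility", "none")
        assert res.warning is not None

    def test_not_computable_without_top_category(self):
        cohort = _counts_cohort((60, 40, 0))
        with pytest.raises(fitting.NotComputableError):
            fitting.test_parallelism(cohort, "mobility", "none")


class TestItemDomainAssociation:
    def test_perfect_monotone_association(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["dlqi1"] = cohort["eq5d_pd"] - 1  # item mirrors the domain level
        table = fitting.item_domain_association(cohort)
        assert table.statistic.loc["dlqi1", "pain_discomfort"] == pytest.approx(1.0)

    def test_pain_item1_strongest_under_generating_model(self, medium_cohort):
        # item 1 carries by far the largest pain slope in the generating model
        table = fitting.item_domain_association(medium_cohort)
        col = table.statistic["pain_discomfort"]
        assert col.idxmax() == "dlqi1"

    def test_constant_column_reported_nan(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["dlqi5"] = 0
        table = fitting.item_domain_association(cohort)
        assert np.isnan(table.statistic.loc["dlqi5", "mobility"])
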