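"""Statistical surface: impairment rule, group tests vs brute-force oracles,
correlations, and the full study report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cpalps.calibration import study_cohort_spec
from cpalps.stats import (
    benjamini_hochberg,
    chi_square_test,
    classify_impairment,
    impairment_prevalence_pct,
    pearson_corr,
    run_study,
    welch_t_from_summary,
    welch_t_test,
)
from cpalps.synthetic import CohortSpec, GroupModel, generate_cohort

from oracles import chi_square_oracle, pearson_oracle, t_two_sided_p, welch_oracle


def domains(**overrides):
    base = {
        "frontal_executive": {"verbal_fluency_z": 0.0, "trail_making_b_z": 0.0, "stroop_z": 0.0},
        "language": {"boston_naming_z": 0.0},
        "verbal_memory": {
            "word_list_memory_z": 0.0,
            "word_list_recall_z": 0.0,
            "word_list_recognition_z": 0.0,
        },
        "visual_memory": {"constructional_recall_z": 0.0},
        "global": {"mmse_z": 0.0},
    }
    for dom, sub in overrides.items():
        base[dom].update(sub)
    return base


class TestImpairmentRule:
    def test_all_zero_not_impaired(self):
        res = classify_impairment(domains())
        assert not res.impaired and res.affected_domains == []

    def test_two_affected_domains_impaired(self):
        res = classify_impairment(
            domains(
                frontal_executive={"verbal_fluency_z": -2.0},
                verbal_memory={"word_list_recall_z": -1.6},
            )
        )
        assert res.impaired
        assert sorted(res.affected_domains) == ["frontal_executive", "verbal_memory"]

    def test_single_deeply_affected_domain_not_impaired(self):
        """One domain at z=-3.0 is abnormal but does not meet the >=2-domain rule."""
        res = classify_impairment(domains(language={"boston_naming_z": -3.0}))
        assert not res.impaired and res.affected_domains == ["language"]

    def test_threshold_is_strict(self):
        """z exactly -1.5 is not 'more than -1.5 SD below the mean'."""
        res = classify_impairment(
            domains(
                frontal_executive={"stroop_z": -1.5},
                visual_memory={"constructional_recall_z": -1.5},
            )
        )
        assert not res.impaired and res.affected_domains == []

    def test_any_subtest_triggers_domain(self):
        res = classify_impairment(
            domains(verbal_memory={"word_list_memory_z": 0.5, "word_list_recall_z": -1.51})
        )
        assert res.affected_domains == ["verbal_memory"]

    def test_missing_domain_skipped_with_warning(self):
        d = domains()
        d["language"] = {"boston_naming_z": np.nan}
        res = classify_impairment(d)
        assert any("language" in w for w in res.warnings)

    def test_prevalence_identity(self):
        assert impairment_prevalence_pct(29, 40) == 72.5


class TestWelch:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = welch_t_test(x, x.copy())
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_published_group_summaries_significant(self):
        """The ALPS group summaries (1.470±0.239, n=40 vs 1.641±0.266, n=42)
        give p < 0.01, matching the quadrature oracle to 1e-6."""
        res = welch_t_from_summary(1.470, 0.239, 40, 1.641, 0.266, 42)
        assert res.p_value < 0.01
        assert res.p_value == pytest.approx(t_two_sided_p(res.statistic, res.df), abs=1e-6)

    def test_sample_and_summary_variants_agree(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1.6, 31)
        r1 = welch_t_test(a, b)
        r2 = welch_t_from_summary(a.mean(), a.std(ddof=1), 25, b.mean(), b.std(ddof=1), 31)
        assert r1.statistic == r2.statistic and r1.df == r2.df and r1.p_value == r2.p_value

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_group_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 15)
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_oracle_on_random_inputs(self):
        """Statistic, df and p agree with a from-first-principles oracle to 1e-8."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            na, nb = rng.integers(3, 30, 2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            res = welch_t_test(a, b)
            t, df, p = welch_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-8)
            assert res.df == pytest.approx(df, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_zero_variance_convention(self):
        res = welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_pooled_variant_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 22)
        res = welch_t_test(a, b, pooled=True)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t) and res.p_value == pytest.approx(p)


class TestChiSquare:
    def test_proportional_table_null(self):
        res = chi_square_test([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_study_sex_table(self):
        """Male/female counts by group (19/21 vs 20/22): no association, and
        the statistic matches direct summation."""
        table = [[19, 21], [20, 22]]
        res = chi_square_test(table)
        stat, p = chi_square_oracle(table)
        assert res.p_value > 0.9
        assert res.statistic == pytest.approx(stat, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-8)

    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_transpose_invariance(self, cells):
        t = np.array(cells).reshape(2, 2)
        assert chi_square_test(t).statistic == pytest.approx(chi_square_test(t.T).statistic)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 7]])

    def test_matches_scipy_without_correction(self):
        t = [[13, 9], [4, 17]]
        res = chi_square_test(t)
        stat, p, _, _ = sps.chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(stat) and res.p_value == pytest.approx(p)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr(np.ones(5), np.arange(5.0))

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, p = pearson_corr(x, y)
            ro, po = pearson_oracle(x, y)
            assert r == pytest.approx(ro, abs=1e-8)
            assert p == pytest.approx(po, abs=1e-8)

    def test_sampling_distribution_around_negative_rho(self):
        """At rho=-0.428 and n=200, the sample r lands within ±0.15 of rho in
        at least 90% of 500 seeded replicates."""
        rho = -0.428
        rng = np.random.default_rng(19)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        hits = 0
        for _ in range(500):
            xy = rng.multivariate_normal([0, 0], cov, size=200)
            r, _ = pearson_corr(xy[:, 0], xy[:, 1])
            hits += abs(r - rho) <= 0.15
        assert hits / 500 >= 0.90


class TestRunStudy:
    def test_null_cohorts_give_uniform_p_values(self):
        """When both groups share one distribution the comparison p-values are
        approximately U(0,1): Kolmogorov distance < 0.1 over 500 replicates."""
        base = study_cohort_spec()
        g = dict(cp_mean_pct=2.3, cp_sd_pct=0.4, alps_mean=1.5, alps_sd=0.25)
        spec = CohortSpec(
            esrd=GroupModel(n=20, **g),
            control=GroupModel(n=20, **g),
            subtest_means=base.subtest_means,
            subtest_sds=base.subtest_sds,
        )
        rng = np.random.default_rng(23)
        ps_cp, ps_alps = [], []
        for _ in range(500):
            cohort = generate_cohort(spec, seed=int(rng.integers(2**31 - 1)))
            rep = run_study(cohort)
            ps_cp.append(rep["comparisons"]["cp_pct_esrd_vs_control"]["p"])
            ps_alps.append(rep["comparisons"]["alps_esrd_vs_control"]["p"])
        for ps in (ps_cp, ps_alps):
            d = sps.kstest(ps, "uniform").statistic
            assert d < 0.1

    def test_direction_of_group_difference(self):
        """Under the study calibration the patient mean CP% exceeds the
        control mean in >=95% of 200 simulated cohorts."""
        spec = study_cohort_spec()
        rng = np.random.default_rng(29)
        wins = 0
        for _ in range(200):
            cohort = generate_cohort(spec, seed=int(rng.integers(2**31 - 1)))
            m = cohort.groupby("group")["cp_pct"].mean()
            wins += m["ESRD"] > m["control"]
        assert wins / 200 >= 0.95

    def test_report_structure(self):
        cohort = generate_cohort(study_cohort_spec(), seed=3)
        rep = run_study(cohort)
        assert rep["n"] == {"ESRD": 40, "control": 42}
        assert "cp_pct_esrd_vs_control" in rep["comparisons"]
        assert set(rep["correlations"]) == {
            c for c in cohort.columns if c.endswith("_z")
        }
        imp = rep["impairment"]
        assert imp["prevalence_pct"] == 100.0 * imp["n_impaired"] / imp["n_total"]

    def test_single_subject_group_rejected(self):
        cohort = generate_cohort(study_cohort_spec(), seed=3)
        small = pd.concat([cohort[cohort["group"] == "ESRD"], cohort[cohort["group"] == "control"].head(1)])
        with pytest.raises(ValueError):
            run_study(small)

    def test_missing_group_rejected(self):
        cohort = generate_cohort(study_cohort_spec(), seed=3)
        with pytest.raises(ValueError, match="absent"):
            run_study(cohort[cohort["group"] == "ESRD"])

    def test_bh_adjustment_is_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.04, 0.2, 0.8]
        q = benjamini_hochberg(p)
        assert np.all(q >= p) and np.all(q <= 1.0)
        assert np.all(np.diff(q[np.argsort(p)]) >= 0)
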