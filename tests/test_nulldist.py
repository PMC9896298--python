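import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

import popwise as pw
from popwise.nulldist import (
    JointNullModel,
    bivariate_normal_cdf,
    corr_nested_single_treatment,
    corr_two_pop_equal_treatments,
    corr_two_pop_from_counts,
    corr_two_pop_unequal_treatments,
    enumerate_subsets,
    joint_tail,
    marginal_quantile,
    read_correlation_csv,
    two_pop_model,
    umbrella_null_model,
    write_correlation_csv,
)
from popwise.trial_simulator import simulate_two_pop_statistics
from popwise.umbrella import UmbrellaDesign, simulate_subset_statistics


def mc_corr_tolerance(rho, n):
    """Three asymptotic standard errors of a sample correlation."""
    return 3 * (1 - rho**2) / np.sqrt(n)


class TestClosedFormCorrelations:
    @pytest.mark.parametrize(
        "fn, pi12, expected",
        [
            (corr_two_pop_unequal_treatments, 0.0, 0.0),
            (corr_two_pop_unequal_treatments, 0.2, 3 / 14),
            (corr_two_pop_unequal_treatments, 1.0, 0.5),
            (corr_two_pop_equal_treatments, 0.0, 0.0),
            (corr_two_pop_equal_treatments, 0.2, 1 / 3),
            (corr_two_pop_equal_treatments, 1.0, 1.0),
        ],
    )
    def test_formula_values(self, fn, pi12, expected):
        assert fn(pi12) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            corr_two_pop_unequal_treatments(1.2)

    def test_equal_treatment_correlation_dominates(self):
        grid = np.linspace(0, 1, 101)
        eq = np.array([corr_two_pop_equal_treatments(p) for p in grid])
        un = np.array([corr_two_pop_unequal_treatments(p) for p in grid])
        assert np.all(eq >= un - 1e-15)

    def test_monte_carlo_oracle_unequal(self, two_pop_structure):
        # N=120 makes every arm split exact (40/40/40 strata; 20/20, 13.3->
        # no: intersection 24 -> 8/8/8), so the statistics have exactly the
        # closed-form correlation
        Z = simulate_two_pop_statistics(
            two_pop_structure, "two_pop_unequal", n_reps=120_000, N=120, seed=901
        )
        rho = np.corrcoef(Z.T)[0, 1]
        assert abs(rho - 3 / 14) < mc_corr_tolerance(3 / 14, 120_000)
        assert np.allclose(Z.var(axis=0), 1.0, atol=0.02)

    def test_monte_carlo_oracle_equal(self, two_pop_structure):
        Z = simulate_two_pop_statistics(
            two_pop_structure, "two_pop_equal", n_reps=120_000, N=100, seed=902
        )
        rho = np.corrcoef(Z.T)[0, 1]
        assert abs(rho - 1 / 3) < mc_corr_tolerance(1 / 3, 120_000)

    def test_counts_based_correlation_matches_closed_form(self):
        # counts proportional to (0.4, 0.4, 0.2) with equal complements
        assert corr_two_pop_from_counts("two_pop_unequal", 40, 40, 20) == pytest.approx(
            3 / 14
        )
        assert corr_two_pop_from_counts("two_pop_equal", 40, 40, 20) == pytest.approx(
            1 / 3
        )
        assert corr_two_pop_from_counts("two_pop_equal", 0, 0, 30) == pytest.approx(1.0)
        assert corr_two_pop_from_counts("two_pop_unequal", 30, 30, 0) == 0.0

    def test_counts_based_correlation_undefined_population(self):
        with pytest.raises(ValueError):
            corr_two_pop_from_counts("two_pop_equal", 0, 30, 0)


class TestNestedCorrelations:
    def test_worked_example(self, nested_structure):
        R = corr_nested_single_treatment(nested_structure)
        assert R[0, 1] == pytest.approx(0.5)
        assert R[0, 2] == pytest.approx(0.1)
        assert R[1, 2] == pytest.approx(0.2)

    def test_single_population_identity(self):
        s = pw.build_structure({(1,): 1.0})
        assert corr_nested_single_treatment(s) == pytest.approx(np.eye(1))

    def test_two_level_chain_value(self):
        s = pw.build_structure({(1,): 0.5, (1, 2): 0.5})
        R = corr_nested_single_treatment(s)
        assert R[0, 1] == pytest.approx(np.sqrt(0.5))

    def test_two_level_chain_monte_carlo(self):
        # pooled z-statistics on nested samples: outer statistic pools the
        # inner sample, inner statistic uses it alone
        rng = np.random.default_rng(77)
        reps, n_out, n_in = 60_000, 20, 20  # per-arm sizes in the two strata
        y = rng.standard_normal((reps, 2 * (n_out + n_in), 1))[..., 0]
        to, co = y[:, :n_out].mean(1), y[:, n_out : 2 * n_out].mean(1)
        ti, ci = (
            y[:, 2 * n_out : 2 * n_out + n_in].mean(1),
            y[:, 2 * n_out + n_in :].mean(1),
        )
        n1 = n_out + n_in
        z1 = ((n_out * to + n_in * ti) / n1 - (n_out * co + n_in * ci) / n1) / np.sqrt(
            2 / n1
        )
        z2 = (ti - ci) / np.sqrt(2 / n_in)
        rho = np.corrcoef(z1, z2)[0, 1]
        assert abs(rho - np.sqrt(0.5)) < mc_corr_tolerance(np.sqrt(0.5), reps)

    def test_non_nested_rejected(self, two_pop_structure):
        with pytest.raises(ValueError):
            corr_nested_single_treatment(two_pop_structure)


class TestJointNullModelValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            JointNullModel(correlation=[[1, 0.5], [0.2, 1]], labels=((1,), (2,)))

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            JointNullModel(
                correlation=[[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]],
                labels=((1,), (2,), (3,)),
            )

    def test_t_needs_df(self):
        with pytest.raises(ValueError):
            JointNullModel(correlation=np.eye(2), labels=((1,), (2,)), family="student_t")

    def test_csv_round_trip(self, tmp_path, two_pop_model_unequal):
        path = tmp_path / "corr.csv"
        write_correlation_csv(two_pop_model_unequal, path)
        back = read_correlation_csv(path)
        assert np.allclose(back.correlation, two_pop_model_unequal.correlation)
        assert back.labels == two_pop_model_unequal.labels


class TestJointTail:
    def test_marginal_quantile(self):
        m = JointNullModel(correlation=np.eye(1), labels=((1,),))
        assert joint_tail(m, [0], 1.959964) == pytest.approx(0.025, abs=1e-6)

    def test_infinite_threshold(self, two_pop_model_unequal):
        assert joint_tail(two_pop_model_unequal, [0, 1], np.inf) == 0.0

    def test_nested_worked_value(self, nested_model):
        assert joint_tail(nested_model, [0, 1, 2], 2.037) == pytest.approx(
            0.0572, abs=2e-4
        )

    def test_monotone_and_bonferroni_bounded(self, nested_model):
        grid = [1.0, 1.5, 2.0, 2.5]
        m = dataclasses.replace(nested_model, quad_abseps=1e-7, quad_maxpts=2_000_000)
        tails = [joint_tail(m, [0, 1, 2], c) for c in grid]
        assert all(a >= b - 1e-7 for a, b in zip(tails, tails[1:]))
        for c, t in zip(grid, tails):
            marg = norm.sf(c)
            assert marg - 1e-7 <= t <= 3 * marg + 1e-7

    def test_student_t_converges_to_normal(self):
        R = [[1, 0.3], [0.3, 1]]
        mt = JointNullModel(correlation=R, labels=((1,), (2,)), family="student_t", df=10**6)
        mn = JointNullModel(correlation=R, labels=((1,), (2,)))
        assert joint_tail(mt, [0, 1], 2.0) == pytest.approx(
            joint_tail(mn, [0, 1], 2.0), abs=1e-6
        )

    def test_deterministic_repeat(self, nested_model):
        a = joint_tail(nested_model, [0, 1, 2], 2.1)
        b = joint_tail(nested_model, [0, 1, 2], 2.1)
        assert a == b

    def test_empty_subset_rejected(self, nested_model):
        with pytest.raises(ValueError):
            joint_tail(nested_model, [], 2.0)


class TestBivariateNormal:
    def test_independence_factorizes(self):
        assert bivariate_normal_cdf(1.0, -0.5, 0.0) == pytest.approx(
            norm.cdf(1.0) * norm.cdf(-0.5), abs=1e-14
        )

    def test_against_qmc(self):
        from scipy.stats import multivariate_normal

        for h, k, rho in [(2.03, 2.03, 3 / 14), (-1.0, 0.5, -0.6), (0.0, 1.2, 0.8)]:
            ref = multivariate_normal.cdf(
                [h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]],
                maxpts=4_000_000, abseps=1e-10, releps=0,
                rng=np.random.default_rng(1),
            )
            assert bivariate_normal_cdf(h, k, rho) == pytest.approx(ref, abs=5e-9)

    def test_perfect_correlation_limits(self):
        assert bivariate_normal_cdf(1.0, 2.0, 1.0) == pytest.approx(norm.cdf(1.0))
        assert bivariate_normal_cdf(0.5, 0.5, -1.0) == pytest.approx(
            2 * norm.cdf(0.5) - 1
        )


class TestUmbrellaModel:
    def test_worked_dimensions(self):
        m = umbrella_null_model(UmbrellaDesign(l=2, N=1056))
        assert m.k == 3 and m.df == 1052 and m.family == "student_t"
        assert m.labels == ((1,), (2,), (1, 2))

    def test_single_stratum(self):
        m = umbrella_null_model(UmbrellaDesign(l=1, N=30))
        assert m.correlation == pytest.approx(np.eye(1)) and m.df == 28

    def test_equal_prevalence_union_correlation(self):
        # T_{1,2} = (T_1 + T_2)/sqrt(2) for equal arms: correlation 1/sqrt(2)
        m = umbrella_null_model(UmbrellaDesign(l=2, N=1056))
        assert m.correlation[0, 2] == pytest.approx(1 / np.sqrt(2))
        assert m.correlation[0, 1] == pytest.approx(0.0)

    def test_correlation_against_simulated_fits(self):
        design = UmbrellaDesign(l=2, N=80)
        m = umbrella_null_model(design)
        rng = np.random.default_rng(5150)
        T = simulate_subset_statistics(design, np.zeros(2), 60_000, rng)
        emp = np.corrcoef(T.T)
        for i in range(3):
            for j in range(i + 1, 3):
                tol = mc_corr_tolerance(m.correlation[i, j], 60_000)
                assert abs(emp[i, j] - m.correlation[i, j]) < tol

    def test_subset_enumeration_order(self):
        assert enumerate_subsets(3) == [
            (1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3),
        ]

    def test_infeasible_designs_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaDesign(l=2, N=4)  # no residual degrees of freedom
        with pytest.raises(ValueError):
            umbrella_null_model(UmbrellaDesign(l=13, N=1000))  # 2^l guard

    def test_marginal_quantiles(self):
        m = umbrella_null_model(UmbrellaDesign(l=1, N=30))
        from scipy.stats import t as student_t

        assert marginal_quantile(m, 0.975) == pytest.approx(student_t.ppf(0.975, 28))
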