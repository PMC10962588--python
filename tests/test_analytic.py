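"""Analytic operating characteristics: path enumeration and MVN rectangles."""

import numpy as np
import pytest
from scipy.stats import norm

from bmams import (
    ConfigError,
    DesignSpec,
    PriorSpec,
    Scenario,
    enumerate_paths,
    oc_analytic,
    thresholds_from_z,
    triangular_thresholds,
)
from bmams import case_study as cs
from bmams.analytic import (
    ArmFate,
    CoefficientEngine,
    accrual_history,
    joint_covariance,
    path_probability,
    stat_law,
)


class TestEnumeratePaths:
    @pytest.mark.parametrize(
        "K, J, mode, count",
        [(3, 2, "failure", 4), (3, 2, "success", 4), (2, 1, "failure", 1),
         (2, 1, "success", 1), (3, 3, "all", 36), (3, 2, "all", 16)],
    )
    def test_counts(self, K, J, mode, count):
        assert len(enumerate_paths(K, J, mode)) == count

    def test_combinatorial_guard(self):
        with pytest.raises(ConfigError):
            enumerate_paths(K=7, J=3, mode="all")


class TestAccrualHistory:
    def test_both_drop_first_stage(self, design3x2):
        acc = accrual_history((ArmFate(False, 1), ArmFate(False, 1)), design3x2)
        np.testing.assert_allclose(acc.n_active[0], [102, 102])
        assert acc.n_ctrl[0] == 102
        assert acc.total == 306

    def test_one_freezes_one_continues(self, design3x2):
        acc = accrual_history((ArmFate(True, 1), ArmFate(False, 2)), design3x2)
        np.testing.assert_allclose(acc.n_active[1], [102, 204])
        assert acc.n_ctrl[1] == 204
        assert acc.total == 510

    def test_full_trial_reaches_max(self, design3x2):
        acc = accrual_history((ArmFate(True, 2), ArmFate(True, 2)), design3x2)
        assert acc.total == design3x2.max_ss == 612


class TestStatLaw:
    def test_vague_prior_reduces_to_z_statistic(self, design3x2, prior_vague, global_null):
        """Coefficients -> identity; thresholds -> z_q * sigma * sqrt(2/n)."""
        eng = CoefficientEngine(design3x2, prior_vague)
        acc = accrual_history((ArmFate(False, 2), ArmFate(False, 2)), design3x2)
        # prior precision 1e-6 against data precision n/sigma^2 ~ 9e-4:
        # coefficients sit within ~2.5e-3 of their flat-prior limits
        for j, n in ((1, 102.0), (2, 204.0)):
            law = stat_law(1, j, acc, eng, global_null)
            np.testing.assert_allclose(law.c, [1.0, 0.0], atol=5e-3)
            assert law.c0 == pytest.approx(1.0, abs=5e-3)
            u = law.u(1.96)
            expected = 1.96 * 340.0 * np.sqrt(2.0 / n)
            assert u == pytest.approx(expected, rel=5e-3)

    def test_zero_prior_mean_zero_offset(self):
        d = DesignSpec(K=3, J=1, t=(1.0,), n_stage=10, sigma=(1.0,) * 3)
        prior = PriorSpec(mu0_ctrl=0.0, tau00=0.5, mu0_1=0.0, tau01=0.5,
                          delta0=(0.0,), tau_d=(0.5,))
        eng = CoefficientEngine(d, prior)
        acc = accrual_history((ArmFate(False, 1), ArmFate(False, 1)), d)
        law = stat_law(1, 1, acc, eng, Scenario((0.0, 0.0, 0.0)))
        assert law.gamma == pytest.approx(0.0, abs=1e-12)

    def test_resolved_arm_rejected(self, design3x2, prior_vague, global_null):
        eng = CoefficientEngine(design3x2, prior_vague)
        acc = accrual_history((ArmFate(False, 1), ArmFate(False, 2)), design3x2)
        with pytest.raises(ConfigError):
            stat_law(1, 2, acc, eng, global_null)


class TestJointCovariance:
    def test_single_law_variance(self, design3x2, prior_vague, global_null):
        eng = CoefficientEngine(design3x2, prior_vague)
        acc = accrual_history((ArmFate(False, 1), ArmFate(False, 1)), design3x2)
        law = stat_law(1, 1, acc, eng, global_null)
        cov = joint_covariance([law], acc, design3x2)
        assert cov[0, 0] == pytest.approx(law.var, rel=1e-12)

    def test_cross_stage_correlation_sqrt_half(self, design3x2, prior_vague, global_null):
        """Same arm at stages 1 and 2, vague prior: classic sqrt(t1) correlation."""
        eng = CoefficientEngine(design3x2, prior_vague)
        acc = accrual_history((ArmFate(False, 2), ArmFate(False, 2)), design3x2)
        laws = [stat_law(1, 1, acc, eng, global_null), stat_law(1, 2, acc, eng, global_null)]
        cov = joint_covariance(laws, acc, design3x2)
        corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert corr == pytest.approx(np.sqrt(0.5), abs=1e-3)

    def test_empirical_covariance_matches(self, design3x2, prior_vague):
        """Simulated (S_{1,1}, S_{1,2}) over no-stopping replicates."""
        scen = Scenario.from_effects(489.0, (60.0, 0.0))
        eng = CoefficientEngine(design3x2, prior_vague)
        acc = accrual_history((ArmFate(False, 2), ArmFate(False, 2)), design3x2)
        laws = [stat_law(1, j, acc, eng, scen) for j in (1, 2)]
        cov = joint_covariance(laws, acc, design3x2)

        rng = np.random.default_rng(7)
        nrep = 40_000
        n = 102
        means = np.array([scen.mu_active[0], scen.mu_active[1], scen.mu_ctrl])
        draws = rng.standard_normal((nrep, 2, 3)) * 340.0 / np.sqrt(n) + means
        cum1 = draws[:, 0, :]
        cum2 = draws.mean(axis=1)
        S = np.empty((nrep, 2))
        for col, (law, cum) in enumerate(zip(laws, (cum1, cum2))):
            S[:, col] = cum[:, :2] @ law.c - law.c0 * cum[:, 2]
        emp = np.cov(S.T)
        se = np.abs(cov) * np.sqrt(2.0 / nrep) + 1e-4
        np.testing.assert_allclose(emp, cov, atol=float(3 * se.max()))
        np.testing.assert_allclose(S.mean(axis=0), [l.mean for l in laws],
                                   atol=3 * 340 / np.sqrt(n * nrep) * 2)


class TestOCAnalytic:
    def test_partition_sums_to_one(self, variant_u, alt_scenario):
        design, prior, th = variant_u
        eng = CoefficientEngine(design, prior)
        total = sum(
            path_probability(a, design, th, alt_scenario, eng)
            for a in enumerate_paths(3, 2, "all")
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_global_null_fwer_near_alpha(self, variant_u, global_null):
        design, prior, th = variant_u
        oc = oc_analytic(design, prior, th, global_null)
        assert oc.p_reject_any == pytest.approx(0.025, abs=1.5e-3)

    def test_per_arm_power_brackets_reject_all(self, variant_u, alt_scenario):
        design, prior, th = variant_u
        oc = oc_analytic(design, prior, th, alt_scenario, per_arm=True)
        assert oc.p_reject_all <= min(oc.p_reject_arm) + 1e-9
        assert max(oc.p_reject_arm) <= oc.p_reject_any + 1e-9

    def test_limits_in_eta1(self, design3x2, prior_vague, global_null):
        """Strict bounds kill rejections; liberal bounds saturate them."""
        strict = triangular_thresholds(1.0 - 1e-9, (0.5, 1.0))
        oc = oc_analytic(design3x2, prior_vague, strict, global_null)
        assert oc.p_reject_any == pytest.approx(0.0, abs=1e-6)

    def test_fwer_monotone_in_eta1(self, design3x2, prior_vague, global_null):
        vals = [
            oc_analytic(
                design3x2, prior_vague, triangular_thresholds(e, (0.5, 1.0)), global_null
            ).p_reject_any
            for e in (0.985, 0.99, 0.9934, 0.996)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_power_monotone_in_n(self, prior_vague, alt_scenario):
        th = triangular_thresholds(0.9934, (0.5, 1.0))
        vals = [
            oc_analytic(cs.design_spec(n), prior_vague, th, alt_scenario).p_reject_all
            for n in (60, 90, 120)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_vague_prior_equals_frequentist_machinery(self, design3x2, prior_vague, global_null):
        """Matched z-bounds: Bayesian analytic FWER equals the frequentist one.

        The frequentist value is obtained from the same enumeration applied
        with an essentially flat prior (precisions 1e-12), where the decision
        statistics are exactly the two-sample z-statistics.
        """
        th = thresholds_from_z(cs.FREQ_MAMS["u"], cs.FREQ_MAMS["l"])
        bayes = oc_analytic(design3x2, prior_vague, th, global_null).p_reject_any
        flat = prior_vague.replace(tau00=1e-12, tau01=1e-12, tau_d=(1e-12,))
        freq = oc_analytic(design3x2, flat, th, global_null).p_reject_any
        assert bayes == pytest.approx(freq, abs=1e-3)

    def test_fwer_increases_with_control_mean_informative_prior(self, variant_c):
        """Control-prior misspecification inflates the global-null error rate."""
        design, prior, th = variant_c
        vals = [
            oc_analytic(
                design, prior, th, Scenario.from_effects(mu0, (0.0, 0.0))
            ).p_reject_any
            for mu0 in (489.0, 556.0, 656.0)
        ]
        assert vals[0] < vals[1] < vals[2]
        assert vals[0] == pytest.approx(0.025, abs=1.5e-3)
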