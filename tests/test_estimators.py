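import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import estimators as est
from mrmediate.estimators import InsufficientInstrumentsError

from conftest import make_hset


class TestWaldRatio:
    def test_arithmetic(self):
        theta, se = est.wald_ratio(0.1, 0.01, 0.2, 0.05)
        assert theta == pytest.approx(2.0)
        assert se == pytest.approx(0.5)

    def test_null_outcome(self):
        theta, se = est.wald_ratio(0.1, 0.01, 0.0, 0.05)
        assert theta == 0.0
        assert se == pytest.approx(0.5)

    def test_sign_antisymmetry_in_gamma(self):
        t1, _ = est.wald_ratio(0.1, 0.01, 0.2, 0.05)
        t2, _ = est.wald_ratio(-0.1, 0.01, 0.2, 0.05)
        assert t1 == -t2

    def test_zero_gamma_raises(self):
        with pytest.raises(ZeroDivisionError):
            est.wald_ratio(0.0, 0.01, 0.2, 0.05)


class TestIVW:
    def test_two_snp_closed_form(self):
        # ratios 1 and 2, both se 0.5: weighted mean 1.5, Q = 2
        h = make_hset([0.1, 0.1], [0.001, 0.001], [0.1, 0.2], [0.05, 0.05])
        e_fix, het = est.ivw(h, model="fixed")
        assert e_fix.theta == pytest.approx(1.5)
        assert e_fix.se == pytest.approx(np.sqrt(1 / 8), rel=1e-9)  # 0.35355
        assert het.q == pytest.approx(2.0)
        e_mult, _ = est.ivw(h, model="multiplicative_random")
        assert e_mult.theta == pytest.approx(1.5)
        assert e_mult.se == pytest.approx(0.5)

    def test_homogeneous_set_q_zero(self):
        h = make_hset([0.1, 0.2], [0.001, 0.001], [0.05, 0.10], [0.05, 0.05])
        e_mult, het = est.ivw(h)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        e_fix, _ = est.ivw(h, model="fixed")
        assert e_mult.se == pytest.approx(e_fix.se)

    def test_per_snp_q_sums_to_q(self, rng):
        theta = rng.normal(0.3, 0.5, 20)
        se = rng.uniform(0.1, 0.5, 20)
        _, het = est.ivw_arrays(theta, se)
        assert sum(het.per_snp_q.values()) == pytest.approx(het.q, rel=1e-9)

    def test_single_snp_falls_back_to_wald_ratio(self):
        h = make_hset([0.1], [0.001], [0.2], [0.05])
        e, _ = est.ivw(h)
        assert e.theta == pytest.approx(2.0)
        assert e.se == pytest.approx(0.5)

    def test_empty_set_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            est.ivw_arrays(np.array([]), np.array([]))

    def test_mult_theta_equals_fixed_theta_se_never_smaller(self, rng):
        for _ in range(20):
            theta = rng.normal(0, 1, 10)
            se = rng.uniform(0.05, 0.5, 10)
            e_f, _ = est.ivw_arrays(theta, se, "fixed")
            e_m, _ = est.ivw_arrays(theta, se, "multiplicative_random")
            assert e_m.theta == e_f.theta
            assert e_m.se >= e_f.se


class TestEgger:
    def test_exact_fit_recovered(self):
        gamma = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_hset(gamma, [0.001] * 4, 0.5 * gamma, [0.05] * 4)
        r = est.egger(h)
        assert r.slope.theta == pytest.approx(0.5, abs=1e-10)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_moves_intercept_only(self):
        gamma = np.array([0.05, 0.1, 0.2, 0.3])
        G = 0.5 * gamma + np.array([0.01, -0.02, 0.015, 0.005])
        r0 = est.egger_arrays(gamma, np.full(4, 1e-3), G, np.full(4, 0.05))
        r1 = est.egger_arrays(gamma, np.full(4, 1e-3), G + 0.03, np.full(4, 0.05))
        assert r1.slope.theta == pytest.approx(r0.slope.theta, abs=1e-12)
        assert r1.intercept == pytest.approx(r0.intercept + 0.03, abs=1e-12)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm

        n = 20
        gamma = rng.uniform(0.02, 0.3, n)
        se_y = rng.uniform(0.02, 0.1, n)
        G = 0.4 * gamma + 0.01 + rng.normal(0, se_y)
        r = est.egger_arrays(gamma, np.full(n, 1e-3), G, se_y)
        fit = sm.WLS(G, sm.add_constant(gamma), weights=se_y**-2).fit()
        assert r.intercept == pytest.approx(fit.params[0], abs=1e-8)
        assert r.slope.theta == pytest.approx(fit.params[1], abs=1e-8)

    def test_i2_gx_near_one_for_precise_instruments(self, rng):
        gamma = rng.uniform(0.05, 0.3, 30)
        r = est.egger_arrays(gamma, np.full(30, 1e-4), 0.5 * gamma, np.full(30, 0.05))
        assert r.heterogeneity.i2_gx > 0.99

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            est.egger_arrays(np.ones(2), np.ones(2), np.ones(2), np.ones(2))


class TestWeightedMedian:
    def test_symmetric_three_ratios(self):
        e = est.weighted_median_arrays(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]), n_boot=200, seed=1
        )
        assert e.theta == pytest.approx(2.0)

    def test_outlier_resistant_unlike_mean(self):
        theta = np.array([0.5] * 9 + [5.0]) + np.linspace(-0.02, 0.02, 10)
        se = np.ones(10)
        e = est.weighted_median_arrays(theta, se, n_boot=200, seed=1)
        assert 0.45 <= e.theta <= 0.55
        assert abs(np.mean(theta) - 0.5) > 0.4  # the mean is dragged away

    def test_interpolated_percentile_matches_direct_computation(self, rng):
        theta = rng.normal(0.3, 0.2, 15)
        w = rng.uniform(0.5, 2.0, 15)
        # direct oracle: explicit cumulative-weight interpolation
        order = np.argsort(theta)
        t, ww = theta[order], w[order]
        s = (np.cumsum(ww) - ww / 2) / ww.sum()
        k = np.searchsorted(s, 0.5)
        oracle = t[k - 1] + (t[k] - t[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1])
        e = est.weighted_median_arrays(theta, np.sqrt(1 / w), n_boot=200, seed=1)
        assert e.theta == pytest.approx(oracle, rel=1e-10)

    def test_penalization_downweights_outlier(self):
        theta = np.concatenate([np.linspace(0.45, 0.55, 9), [8.0]])
        se = np.concatenate([np.full(9, 0.5), [0.1]])  # outlier carries >50% weight
        plain = est.weighted_median_arrays(theta, se, penalized=False, n_boot=200, seed=2)
        pen = est.weighted_median_arrays(theta, se, penalized=True, n_boot=200, seed=2)
        assert abs(pen.theta - 0.5) < abs(plain.theta - 0.5)

    def test_bootstrap_se_stable_across_seeds(self, rng):
        theta = rng.normal(0.4, 0.3, 30)
        se = rng.uniform(0.1, 0.4, 30)
        e1 = est.weighted_median_arrays(theta, se, n_boot=5000, seed=1)
        e2 = est.weighted_median_arrays(theta, se, n_boot=5000, seed=99)
        assert e1.se == pytest.approx(e2.se, rel=0.10)


class TestRadialIVW:
    def test_slope_identity_with_ivw(self, rng):
        theta = rng.normal(0.5, 0.8, 25)
        se = rng.uniform(0.05, 0.6, 25)
        r, _ = est.radial_ivw_arrays(theta, se)
        f, _ = est.ivw_arrays(theta, se, "fixed")
        assert r.theta == pytest.approx(f.theta, abs=1e-10)

    def test_homogeneous_set_no_flags(self):
        theta = np.full(10, 0.5)
        se = np.full(10, 0.1)
        _, het = est.radial_ivw_arrays(theta, se)
        assert est.radial_outliers(het) == []

    def test_injected_outlier_flagged(self):
        theta = np.concatenate([np.full(19, 0.5), [0.5 + 10 * 0.1]])
        se = np.full(20, 0.1)
        ids = np.array([f"rs{i}" for i in range(20)], dtype=object)
        _, het = est.radial_ivw_arrays(theta, se, ids)
        assert est.radial_outliers(het) == ["rs19"]


class TestPresso:
    def _homogeneous(self, rng, n=20, theta0=0.4):
        gamma = rng.uniform(0.05, 0.3, n)
        se_x = np.full(n, 1e-3)
        se_y = np.full(n, 0.02)
        G = theta0 * gamma + rng.normal(0, se_y)
        return gamma, se_x, G, se_y

    def test_global_p_bounds_and_no_outliers(self, rng):
        gamma, se_x, G, se_y = self._homogeneous(rng)
        r = est.mr_presso_arrays(gamma, se_x, G, se_y, n_sim=1000, seed=3)
        assert 1 / 1001 <= r.global_p <= 1.0
        assert r.global_p > 0.05
        assert r.outlier_ids == []
        assert r.corrected is None

    def test_outlier_flagged_and_corrected(self, rng):
        gamma, se_x, G, se_y = self._homogeneous(rng)
        G = G.copy()
        G[5] += 10 * se_y[5]
        ids = np.array([f"rs{i}" for i in range(20)], dtype=object)
        r = est.mr_presso_arrays(gamma, se_x, G, se_y, ids=ids, n_sim=1000, seed=3)
        assert "rs5" in r.outlier_ids
        assert r.corrected is not None
        assert r.corrected.n_snp == 20 - len(r.outlier_ids)
        assert r.distortion_p is not None

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            est.mr_presso_arrays(np.ones(3), np.ones(3), np.ones(3), np.ones(3))


class TestLeaveOneOut:
    def test_identical_snps_all_equal_full(self):
        h = make_hset([0.1] * 5, [0.001] * 5, [0.05] * 5, [0.05] * 5)
        full, _ = est.ivw(h)
        loo = est.leave_one_out(h)
        assert len(loo) == 5
        for _, e in loo:
            assert e.theta == pytest.approx(full.theta)
            assert e.n_snp == 4

    def test_removing_outlier_moves_estimate_to_consensus(self, rng):
        gamma = np.full(10, 0.1)
        G = 0.5 * gamma + rng.normal(0, 0.001, 10)
        G[0] = 0.5 * gamma[0] + 0.5  # gross outlier
        h = make_hset(gamma, [1e-4] * 10, G, [0.01] * 10)
        loo = dict(est.leave_one_out(h))
        assert loo["rs1"].theta == pytest.approx(0.5, abs=0.05)
        full, _ = est.ivw(h)
        assert abs(loo["rs1"].theta - 0.5) < abs(full.theta - 0.5)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_sign_flip_invariance(seed):
    """Simultaneously flipping every (γⱼ, Γⱼ) pair leaves all estimators'
    effect estimates unchanged."""
    rng = np.random.default_rng(seed)
    n = 10
    gamma = rng.uniform(0.02, 0.3, n) * rng.choice([-1, 1], n)
    se_x = np.full(n, 1e-3)
    se_y = rng.uniform(0.02, 0.1, n)
    G = 0.4 * gamma + rng.normal(0, se_y)
    theta, se = G / gamma, se_y / np.abs(gamma)
    e1, _ = est.ivw_arrays(theta, se)
    e2, _ = est.ivw_arrays(-G / -gamma, se)
    assert e1.theta == pytest.approx(e2.theta, abs=1e-12)
    g1 = est.egger_arrays(gamma, se_x, G, se_y)
    g2 = est.egger_arrays(-gamma, se_x, -G, se_y)
    assert g1.slope.theta == pytest.approx(g2.slope.theta, abs=1e-12)
    assert g1.intercept == pytest.approx(g2.intercept, abs=1e-12)
    m1 = est.weighted_median_arrays(theta, se, n_boot=100, seed=0)
    m2 = est.weighted_median_arrays(-G / -gamma, se, n_boot=100, seed=0)
    assert m1.theta == pytest.approx(m2.theta, abs=1e-12)
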