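"""Closed-form stationary laws vs the brute-force master-equation oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from burstfish.telegraph import (
    CellObservation,
    PmfTruncation,
    TelegraphParams,
    TruncationError,
    active_fraction,
    cme_stationary_oracle,
    default_truncation,
    kummer_m,
    marginal_pmf,
    marginal_pmf_direct,
    partial_pmf_off,
    partial_pmf_on,
    polyploid_joint_pmf,
)
from burstfish.telegraph import _log_partial_pmfs

GRID = [
    (lam, gam, rho)
    for lam in (0.1, 1.0, 10.0)
    for gam in (0.1, 1.0, 10.0)
    for rho in (1.0, 5.0, 20.0)
]


def _params(lam, gam, rho, delta=1.0):
    return TelegraphParams(lam=lam, gam=gam, mu=rho * delta, delta=delta, beta=1.0)


@pytest.mark.parametrize(
    "lam,gam,expected", [(1.0, 1.0, 0.5), (3.0, 1.0, 0.75), (1.0, 3.0, 0.25)]
)
def test_active_fraction(lam, gam, expected):
    assert active_fraction(_params(lam, gam, 1.0)) == pytest.approx(expected, abs=1e-12)


class TestKummer:
    def test_unit_at_zero(self):
        for a, b in [(0.3, 1.7), (2.0, 5.0), (1.5, 0.5)]:
            assert kummer_m(a, b, 0.0) == pytest.approx(1.0, abs=1e-10)

    def test_exponential_identity(self):
        assert kummer_m(1.0, 1.0, 2.0) == pytest.approx(math.exp(2.0), rel=1e-10)
        assert kummer_m(1.0, 1.0, -3.0) == pytest.approx(math.exp(-3.0), rel=1e-10)

    def test_expm1_identity(self):
        assert kummer_m(1.0, 2.0, 1.0) == pytest.approx(math.expm1(1.0), rel=1e-10)

    def test_negative_argument_uses_cancellation_safe_route(self):
        # direct alternating series at this magnitude loses all precision;
        # compare against the transformed evaluation at modest size instead
        val = kummer_m(2.5, 7.0, -30.0)
        ref = math.exp(-30.0) * kummer_m(7.0 - 2.5, 7.0, 30.0)
        assert val == pytest.approx(ref, rel=1e-10)
        assert val > 0

    def test_invalid_b(self):
        with pytest.raises(ValueError):
            kummer_m(1.0, -2.0, 1.0)


class TestPartialPmfs:
    def test_no_transcription_limit(self):
        p = partial_pmf_on(_params(2.0, 1.0, 1e-12))
        q = partial_pmf_off(_params(2.0, 1.0, 1e-12))
        assert p[0] == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert q[0] == pytest.approx(1.0 / 3.0, abs=1e-9)
        assert p[1:].max() < 1e-9 and q[1:].max() < 1e-9

    @pytest.mark.parametrize("lam,gam,rho", GRID)
    def test_partial_sums_are_state_probabilities(self, lam, gam, rho):
        params = _params(lam, gam, rho)
        f = active_fraction(params)
        p, q = partial_pmf_on(params), partial_pmf_off(params)
        assert abs(p.sum() - f) < 1e-8
        assert abs(q.sum() - (1 - f)) < 1e-8
        assert p.min() >= 0 and q.min() >= 0

    @pytest.mark.parametrize("lam,gam,rho", [(1, 1, 10), (0.1, 1, 20), (10, 0.1, 5)])
    def test_matches_cme_oracle(self, lam, gam, rho):
        params = _params(lam, gam, rho)
        m_max = 200
        oracle = cme_stationary_oracle(params, 1, m_max)
        p, q = partial_pmf_on(params), partial_pmf_off(params)
        n = min(len(p), m_max + 1)
        assert np.abs(p[:n] - oracle[1, :n]).max() < 1e-8
        assert np.abs(q[:n] - oracle[0, :n]).max() < 1e-8

    def test_conditional_mean_ordering(self):
        # the ON-conditioned mean count exceeds the OFF-conditioned mean
        for lam, gam, rho in GRID:
            params = _params(lam, gam, rho)
            p, q = partial_pmf_on(params), partial_pmf_off(params)
            m = np.arange(len(p))
            assert (m * p).sum() / p.sum() > (m * q).sum() / q.sum()

    def test_explicit_truncation_failure(self):
        with pytest.raises(TruncationError):
            partial_pmf_on(_params(1, 1, 20), PmfTruncation(m_max=5, tail_tol=1e-10))


class TestMarginal:
    def test_stationary_mean(self):
        P = marginal_pmf(_params(2.0, 1.0, 9.0))
        mean = (np.arange(len(P)) * P).sum()
        assert mean == pytest.approx(6.0, abs=1e-6)

    def test_always_on_poisson_limit(self):
        from scipy import stats

        P = marginal_pmf(TelegraphParams(1.0, 1e-6, 5.0, 1.0, 1.0))
        pois = stats.poisson.pmf(np.arange(len(P)), 5.0)
        assert 0.5 * np.abs(P - pois).sum() < 1e-4

    @pytest.mark.parametrize("lam,gam,rho", [(1, 1, 10), (0.1, 10, 20), (10, 0.1, 1)])
    def test_dual_route_closed_forms_agree(self, lam, gam, rho):
        params = _params(lam, gam, rho)
        P = marginal_pmf(params)
        P2 = marginal_pmf_direct(params, len(P) - 1)
        assert np.abs(P - P2).max() < 1e-10

    @given(
        lam=st.floats(0.1, 10.0),
        gam=st.floats(0.1, 10.0),
        rho=st.floats(0.5, 40.0),
    )
    def test_normalization_property(self, lam, gam, rho):
        P = marginal_pmf(_params(lam, gam, rho))
        assert abs(P.sum() - 1.0) < 1e-8
        assert P.min() >= 0


class TestPolyploid:
    def test_K1_reduction(self, params_std):
        joint = polyploid_joint_pmf(params_std, 1)
        np.testing.assert_allclose(joint[0], partial_pmf_off(params_std), atol=1e-14)
        np.testing.assert_allclose(joint[1], partial_pmf_on(params_std), atol=1e-14)

    def test_row_sums_binomial(self, params_std):
        joint = polyploid_joint_pmf(params_std, 3, full_support=True)
        np.testing.assert_allclose(
            joint.sum(axis=1), [1 / 8, 3 / 8, 3 / 8, 1 / 8], atol=1e-8
        )

    def test_K2_matches_two_allele_cme(self, params_std):
        m_max = 150
        oracle = cme_stationary_oracle(params_std, 2, m_max)
        joint = polyploid_joint_pmf(params_std, 2, full_support=True)
        n = min(joint.shape[1], m_max + 1)
        assert np.abs(joint[:, :n] - oracle[:, :n]).max() < 1e-8

    def test_K3_matches_three_allele_cme(self, params_std):
        m_max = 180
        oracle = cme_stationary_oracle(params_std, 3, m_max)
        joint = polyploid_joint_pmf(params_std, 3, full_support=True)
        n = min(joint.shape[1], m_max + 1)
        assert np.abs(joint[:, :n] - oracle[:, :n]).max() < 1e-8

    def test_total_mass(self, params_std):
        joint = polyploid_joint_pmf(params_std, 3, full_support=True)
        assert abs(joint.sum() - 1.0) < 3e-10

    def test_invalid_K(self, params_std):
        with pytest.raises(ValueError):
            polyploid_joint_pmf(params_std, 0)


class TestOracle:
    def test_degenerate_no_transcription(self):
        params = TelegraphParams(1.0, 1.0, 1e-9, 1.0, 1.0)
        pi = cme_stationary_oracle(params, 2, 10)
        assert pi[:, 0].sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(pi[:, 0], [0.25, 0.5, 0.25], atol=1e-6)

    def test_mean_rna(self, params_std):
        pi = cme_stationary_oracle(params_std, 1, 200)
        mean = (pi.sum(axis=0) * np.arange(201)).sum()
        assert mean == pytest.approx(5.0, abs=1e-6)

    def test_truncation_stability(self, params_std):
        a = cme_stationary_oracle(params_std, 1, 120)
        b = cme_stationary_oracle(params_std, 1, 160)
        assert np.abs(a - b[:, :121]).max() < 1e-10


class TestNumericalStability:
    def test_log_pmfs_finite_at_extremes(self):
        params = TelegraphParams(1.0, 1.0, 100.0, 1.0, 1.0)
        log_p, log_q = _log_partial_pmfs(params, 500)
        assert np.all(np.isfinite(log_p)) and np.all(np.isfinite(log_q))

    def test_large_argument_log_series_fallback(self):
        # rho beyond scipy's hyp1f1 overflow threshold still yields a valid pmf
        params = TelegraphParams(1.0, 1.0, 900.0, 1.0, 1.0)
        trunc = default_truncation(params, 1e-8)
        P = marginal_pmf(params, trunc)
        assert abs(P.sum() - 1.0) < 1e-6
        mean = (np.arange(len(P)) * P).sum()
        assert mean == pytest.approx(450.0, rel=1e-4)


class TestValidation:
    @pytest.mark.parametrize("bad", [(-1, 1, 1, 1, 1), (1, 0, 1, 1, 1), (1, 1, 1, 1, np.inf)])
    def test_invalid_params(self, bad):
        with pytest.raises(ValueError):
            TelegraphParams(*bad)

    def test_cell_observation_invariants(self):
        with pytest.raises(ValueError):
            CellObservation("c", K=2, k=3, m=0)
        with pytest.raises(ValueError):
            CellObservation("c", K=0, k=0, m=0)

    def test_truncation_invariants(self):
        with pytest.raises(ValueError):
            PmfTruncation(m_max=0)
        with pytest.raises(ValueError):
            PmfTruncation(m_max=10, tail_tol=1e-3)
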