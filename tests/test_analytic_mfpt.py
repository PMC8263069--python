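import math

import numpy as np
import pytest

from burstdyn.analytic_mfpt import (A0_EMPIRICAL, A0_FIRST_STEP,
                                    continuous_mfpt, correction_constants,
                                    cubic_burst_duration,
                                    discrete_burst_duration,
                                    ou_burst_duration,
                                    ou_burst_duration_percentile,
                                    ou_percentile_to_threshold,
                                    rayleigh_burst_duration)
from burstdyn.envelope_models import rayleigh_drift_duration


def ou_discrete_oracle(theta, zeta, dt, L):
    """Exact mean supra-threshold run length of the discretized OU process.

    For a stationary Gaussian AR(1) sequence with lag-1 correlation
    rho = exp(-theta dt), the mean run duration above L is
    dt * P(x > L) / P(x_t <= L, x_{t+1} > L); the joint orthant probability
    follows from the bivariate normal distribution. Fully independent of the
    first-passage machinery under test.
    """
    from scipy.stats import multivariate_normal, norm
    rho = math.exp(-theta * dt)
    sd = zeta / math.sqrt(2 * theta)
    z = L / sd
    p_above = norm.sf(z)
    # P(x1 <= z, x2 <= z) for standard bivariate normal with correlation rho
    p_bb = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([z, z])
    p_up = norm.cdf(z) - p_bb  # P(x1 <= z, x2 > z)
    return dt * p_above / p_up


class TestCorrectionConstants:
    def test_printed_values(self):
        c = correction_constants(1.0, 0.001)
        assert c.gamma_bar == pytest.approx(0.025231, abs=1e-6)
        assert c.delta_bar == pytest.approx(0.019816, abs=1e-6)

    def test_a0_constants(self):
        assert A0_FIRST_STEP == pytest.approx(1 / math.pi - 0.5)
        assert A0_FIRST_STEP == pytest.approx(-0.18, abs=0.005)
        assert A0_EMPIRICAL == pytest.approx((math.pi - 4) / (math.pi + 4))
        assert A0_EMPIRICAL == pytest.approx(-0.12, abs=0.005)

    def test_prefactor_identity(self):
        # (Delta + Gamma) * (a0_emp + 1) == zeta * sqrt(pi dt / 2) exactly
        for zeta, dt in [(1.0, 1e-3), (0.3, 1e-4), (2.5, 0.01)]:
            c = correction_constants(zeta, dt)
            assert c.prefactor == pytest.approx(zeta * math.sqrt(math.pi * dt / 2),
                                                rel=1e-12)


class TestOUBurstDuration:
    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("pct", [0.3, 0.5, 0.8])
    def test_against_ar1_orthant_oracle(self, theta, pct):
        zeta, dt = 1.0, 1e-3
        L = ou_percentile_to_threshold(theta, zeta, pct)
        closed = ou_burst_duration(theta, zeta, dt, L)
        oracle = ou_discrete_oracle(theta, zeta, dt, L)
        # the closed form is first order in dt
        assert closed == pytest.approx(oracle, rel=0.005)

    def test_frozen_reference_value(self):
        # theta = zeta = 1, dt = 1 ms, threshold at the stationary mean:
        # pi * sqrt(dt/2) (the orthant oracle gives 0.070266 s)
        assert ou_burst_duration(1.0, 1.0, 1e-3, 0.0) == \
            pytest.approx(math.pi * math.sqrt(5e-4), rel=1e-12)
        assert ou_burst_duration(1.0, 1.0, 1e-3, 0.0) == \
            pytest.approx(0.070266, rel=3e-3)

    def test_percentile_form_equivalence(self):
        # Eq in threshold units == Eq in percentile units through the
        # stationary CDF map, to float precision
        for theta, zeta in [(0.5, 1.0), (1.0, 0.3), (2.0, 2.0)]:
            pct = np.linspace(0.05, 0.95, 19)
            L = ou_percentile_to_threshold(theta, zeta, pct)
            a = ou_burst_duration(theta, zeta, 1e-3, L)
            b = ou_burst_duration_percentile(theta, 1e-3, pct)
            assert np.allclose(a, b, rtol=1e-12)

    def test_zeta_invariance_of_percentile_form(self):
        pct = np.array([0.25, 0.5, 0.75])
        for zeta in (0.1, 10.0):
            L = ou_percentile_to_threshold(1.0, zeta, pct)
            assert np.allclose(ou_burst_duration(1.0, zeta, 1e-3, L),
                               ou_burst_duration_percentile(1.0, 1e-3, pct),
                               rtol=1e-12)

    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0])
    def test_quadrature_agrees_with_closed_form(self, theta):
        for L in (0.0, 0.5, 1.2):
            quad = discrete_burst_duration([0.0, -theta], 1.0, 1e-3, L)
            assert quad == pytest.approx(ou_burst_duration(theta, 1.0, 1e-3, L),
                                         rel=1e-3)


class TestDiscreteBurstDuration:
    def test_sqrt_dt_scaling(self):
        base = discrete_burst_duration([0.0, -1.0], 1.0, 1e-3, 0.5)
        quarter = discrete_burst_duration([0.0, -1.0], 1.0, 4e-3, 0.5)
        assert quarter == pytest.approx(2 * base, rel=1e-9)

    def test_rayleigh_closed_form(self):
        theta, zeta, dt = 1.3, 0.8, 1e-3
        mu = rayleigh_drift_duration(theta, zeta)
        for L in (0.3, 0.8, 1.5):
            quad = discrete_burst_duration(mu, zeta, dt, L)
            assert quad == pytest.approx(
                rayleigh_burst_duration(theta, zeta, dt, L), rel=1e-6)

    def test_nonintegrable_drift_rejected(self):
        with pytest.raises(ValueError):
            discrete_burst_duration([0.0, 1.0], 1.0, 1e-3, 0.5)


class TestContinuousMFPT:
    def test_boundary_condition(self):
        assert continuous_mfpt([0.0, -1.0], 1.0, 0.7, 0.7) == 0.0

    def test_monotone_in_start(self):
        taus = [continuous_mfpt([0.0, -1.0], 1.0, x0, 0.0)
                for x0 in (0.2, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(taus, taus[1:]))

    def test_ou_against_markov_chain_oracle(self):
        # fine-grid absorbing Markov chain: tridiagonal linear solve for the
        # MFPT of the continuous OU generator (independent discretization)
        theta = zeta = 1.0
        L, x0 = 0.0, 1.0
        hi = 6.0
        n = 4000
        x = np.linspace(L, hi, n)
        h = x[1] - x[0]
        mu = -theta * x
        # upwind-free central scheme: L tau = mu tau' + (zeta^2/2) tau'' = -1
        main = np.full(n, -zeta ** 2 / h ** 2)
        upper = zeta ** 2 / (2 * h ** 2) + mu[:-1] / (2 * h)
        lower = zeta ** 2 / (2 * h ** 2) - mu[1:] / (2 * h)
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla
        A = sp.diags([lower, main, upper], [-1, 0, 1], format="lil")
        A[0, :] = 0
        A[0, 0] = 1.0  # absorbing at L
        A[-1, -1] = -zeta ** 2 / (2 * h ** 2) + mu[-1] / (2 * h)  # reflecting
        rhs = np.full(n, -1.0)
        rhs[0] = 0.0
        tau = spla.spsolve(A.tocsr(), rhs)
        mc = np.interp(x0, x, tau)
        quad = continuous_mfpt([0.0, -theta], zeta, x0, L)
        assert quad == pytest.approx(mc, rel=0.01)


class TestCubic:
    def test_limit_reduces_to_linear(self):
        theta = 1.0
        near_linear = cubic_burst_duration([0.0, -theta, 0.0, -1e-10], 1.0,
                                           1e-3, 0.8)
        assert near_linear == pytest.approx(
            ou_burst_duration(theta, 1.0, 1e-3, 0.8), rel=0.005)

    def test_monotone_decreasing_for_plain_monostable_drift(self):
        # strongly attracting cubic without a shoulder: profile decays in L
        coeffs = [0.2, -1.5, 0.1, -0.5]
        Ls = np.linspace(0.3, 2.5, 15)
        taus = cubic_burst_duration(coeffs, 0.5, 1e-3, Ls)
        assert np.all(np.diff(taus) < 0)

    def test_shoulder_drift_gives_non_monotone_profile(self):
        # near-zero drift around x ~ 1.9 lengthens mid-threshold bursts:
        # the profile is locally increasing there (the shoulder signature)
        coeffs = [0.8784, -2.376, 1.76, -0.4]
        Ls = np.linspace(0.8, 2.8, 15)
        taus = cubic_burst_duration(coeffs, 0.5, 1e-3, Ls)
        assert np.any(np.diff(taus) > 0)
        assert taus[-1] < taus[0]

    def test_wrong_sign_rejected(self):
        with pytest.raises(ValueError):
            cubic_burst_duration([0.0, -1.0, 0.0, 0.1], 1.0, 1e-3, 0.5)
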