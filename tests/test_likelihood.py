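import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from poolfish.likelihood import (FAMILIES, ModelParameters, N_PHI,
                                 PoolCovariates, SampleCovariates,
                                 abundance_linpred, capture_prob,
                                 catchability_linpred, choose_n_max,
                                 detection_prob, fourth_corner_logprior,
                                 marginal_loglik_unit, peak_depth)


class TestAbundanceLinpred:
    def test_reference_values(self):
        b = np.zeros(10)
        assert abundance_linpred(b, PoolCovariates(D=1.0)) == pytest.approx(-1.0)
        assert abundance_linpred(b, PoolCovariates(D=0.5)) == pytest.approx(
            np.log(0.5) - 0.5)
        b2 = np.zeros(10)
        b2[2] = 1.0
        assert abundance_linpred(b2, PoolCovariates(D=1.0, M=1)) == pytest.approx(0.0)

    def test_zero_depth_limit(self):
        assert abundance_linpred(np.zeros(10), PoolCovariates(D=0.0)) == -np.inf
        with pytest.raises(ValueError):
            abundance_linpred(np.zeros(10), PoolCovariates(D=-0.1))

    @given(b2=st.floats(-1.2, 2), b4=st.floats(-1.2, 1.2), M=st.integers(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_unimodal_with_peak_at_closed_form(self, b2, b4, M):
        """λ(D) is unimodal; grid argmax matches exp(−(β2+β4·M))."""
        b = np.zeros(10)
        b[1], b[3] = b2, b4
        grid = np.linspace(1e-6, 20.0, 40001)
        vals = np.log(grid) - np.exp(b2 + b4 * M) * grid
        d_star = peak_depth(b2, b4, M)
        assert grid[np.argmax(vals)] == pytest.approx(float(d_star), abs=1e-3)
        # single sign change of the finite differences => unimodal
        sign_changes = np.diff(np.sign(np.diff(vals)))
        assert (sign_changes < 0).sum() <= 1


def test_peak_depth_reference_values():
    assert peak_depth(0.0) == pytest.approx(1.0)
    assert peak_depth(np.log(2.0)) == pytest.approx(0.5)
    assert peak_depth(-0.5, 0.5, M=1) == pytest.approx(1.0)


class TestCatchability:
    def test_reference_values(self):
        p6 = np.zeros(6)
        s = SampleCovariates(D=1.0, C=0.0)
        assert catchability_linpred(p6, s, "boat_EF") == pytest.approx(-1.0)
        p = np.array([0.0, 0.0, 1.0, -1.0, 0.0, 0.0])
        assert catchability_linpred(p, SampleCovariates(D=1.0, T=1.0, C=0.0),
                                    "boat_EF") == pytest.approx(-1.0)

    def test_conductivity_only_for_electrofishing(self):
        with pytest.raises(ValueError, match="electrofishing"):
            catchability_linpred(np.zeros(5), SampleCovariates(D=1.0, C=0.5),
                                 "seine_SM")
        with pytest.raises(ValueError):
            # seine gears take 5 coefficients, never a 6th conductivity slot
            catchability_linpred(np.zeros(6), SampleCovariates(D=1.0), "seine_SM")


class TestCaptureProb:
    def test_effort_exponent_limits(self):
        lq = np.log(0.22314)
        r_low = capture_prob(lq, 0.1, upsilon=0.0)
        r_high = capture_prob(lq, 1.0, upsilon=0.0)
        assert r_low == pytest.approx(r_high, rel=1e-14)
        assert capture_prob(lq, 1.0, upsilon=1.0) == pytest.approx(0.2, rel=1e-4)
        assert capture_prob(lq, 0.25, upsilon=0.5) == pytest.approx(0.1, rel=1e-4)

    def test_seine_scalar_multiplies(self):
        base = capture_prob(0.3, 0.7, 0.5)
        assert capture_prob(0.3, 0.7, 0.5, lm_scalar=0.6) == pytest.approx(0.6 * base)

    @given(lq=st.floats(-4, 3), E=st.floats(0.01, 1.0), u=st.floats(0, 1),
           sc=st.floats(0.05, 1.0))
    @settings(max_examples=80, deadline=None)
    def test_bounds_and_monotonicity(self, lq, E, u, sc):
        r = capture_prob(lq, E, u, sc)
        assert 0 <= r <= sc + 1e-12
        if u > 0:
            assert capture_prob(lq, min(E * 1.5, 1.0), u, sc) >= r - 1e-12


class TestDetectionProb:
    def test_reference_values(self):
        assert detection_prob(0.7, 0) == 0.0
        assert detection_prob(1.0, 3) == pytest.approx(1.0)
        assert detection_prob(0.2, 3) == pytest.approx(0.488)

    @given(r=st.floats(0, 1), N=st.integers(0, 200))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_n_and_r(self, r, N):
        p = detection_prob(r, N)
        assert 0 <= p <= 1
        assert detection_prob(r, N + 1) >= p - 1e-12
        assert detection_prob(min(r + 0.1, 1.0), max(N, 1)) >= detection_prob(
            r, max(N, 1)) - 1e-12


def brute_force_unit(lam, r, y, n_max=500):
    """Independent oracle: direct enumeration of the Poisson mixture."""
    total = 0.0
    for n in range(n_max + 1):
        like = stats.poisson.pmf(n, lam)
        for rk, yk in zip(np.atleast_1d(r), np.atleast_1d(y)):
            p = 1.0 - (1.0 - rk) ** n
            like *= p if yk else (1.0 - p)
        total += like
    return np.log(total)


class TestMarginalLoglik:
    def test_degenerate_cases(self):
        # y=0 with r=1: only N=0 survives -> logL = -λ
        assert marginal_loglik_unit(2.5, [1.0], [0]) == pytest.approx(-2.5)
        # y=1 with r=1, λ=1 -> log(1 − e^{−1})
        assert marginal_loglik_unit(1.0, [1.0], [1]) == pytest.approx(
            np.log(1 - np.exp(-1)), abs=1e-10)
        assert marginal_loglik_unit(0.0, [0.5], [0]) == 0.0
        assert marginal_loglik_unit(0.0, [0.5], [1]) == -np.inf

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            lam = rng.uniform(0.05, 10)
            K = rng.integers(1, 4)
            r = rng.uniform(0.01, 0.95, K)
            y = rng.integers(0, 2, K)
            got = marginal_loglik_unit(lam, r, y)
            want = brute_force_unit(lam, r, y)
            assert got == pytest.approx(want, abs=1e-8)

    def test_truncation_converged(self):
        rng = np.random.default_rng(3)
        lam, r = 8.0, rng.uniform(0.05, 0.6, 3)
        y = np.array([1, 0, 1])
        auto = marginal_loglik_unit(lam, r, y)
        assert marginal_loglik_unit(lam, r, y, n_max=2000) == pytest.approx(
            auto, abs=1e-8)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        lam = 3.0
        r = rng.uniform(0.05, 0.8, 4)
        y = np.array([1, 0, 0, 1])
        base = marginal_loglik_unit(lam, r, y)
        for _ in range(5):
            perm = rng.permutation(4)
            assert marginal_loglik_unit(lam, r[perm], y[perm]) == pytest.approx(base)

    def test_royle_nichols_single_sample(self):
        """K=1, υ=0 reduces to the Royle–Nichols detection form."""
        lam, r = 2.0, 0.3
        got = marginal_loglik_unit(lam, [r], [1])
        n = np.arange(choose_n_max(lam) + 1)
        want = np.log((stats.poisson.pmf(n, lam) * (1 - (1 - r) ** n)).sum())
        assert got == pytest.approx(want, abs=1e-10)


def test_choose_n_max_floor_and_growth():
    assert choose_n_max(0.1) == 50
    assert choose_n_max(400) > 400
    assert choose_n_max(1e9, cap=5000) == 5000


class TestFourthCorner:
    def test_constant_coefficients(self):
        n = 7
        got = fourth_corner_logprior(np.zeros(n), eta1=0.0, eta2=0.0,
                                     sigma=1.0, length_std=np.zeros(n))
        assert got == pytest.approx(n * stats.norm.logpdf(0.0))

    def test_matches_independent_sum(self):
        rng = np.random.default_rng(9)
        L = np.array([-1.0, 0.0, 1.0])
        c = rng.normal(size=3)
        eta1, eta2, sig = 0.4, -0.3, 0.7
        want = sum(stats.norm.logpdf(ci, eta1 + eta2 * li, sig)
                   for ci, li in zip(c, L))
        assert fourth_corner_logprior(c, eta1, eta2, sig, L) == pytest.approx(want)
        # Eq. μ = η1 + η2·L identity at the reference lengths
        assert np.allclose(eta1 + eta2 * L, [0.7, 0.4, 0.1])

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            fourth_corner_logprior([0.0], 0.0, 0.0, 0.0, [0.0])


def test_family_bookkeeping():
    assert len(FAMILIES) == 32
    assert sum(N_PHI.values()) == 22
    assert N_PHI["backpack_EF"] == 6 and N_PHI["seine_SM"] == 5
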