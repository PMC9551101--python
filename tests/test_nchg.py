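"""Distribution kernel: central/noncentral hypergeometric and BH adjustment."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircross.nchg import (
    HypergeomParams,
    NoncentralParams,
    PValueVector,
    bh_adjust,
    fnch_pmf,
    fnch_pmf_exact,
    fnch_sf,
    fnch_sf_exact,
    hypergeom_cdf,
    hypergeom_pmf,
    hypergeom_pmf_exact,
    hypergeom_sf,
    hypergeom_sf_exact,
)


@st.composite
def urn_params(draw, max_n=200):
    N = draw(st.integers(min_value=1, max_value=max_n))
    K = draw(st.integers(min_value=0, max_value=N))
    n = draw(st.integers(min_value=0, max_value=N))
    kmin, kmax = max(0, n + K - N), min(n, K)
    k = draw(st.integers(min_value=kmin, max_value=kmax))
    return HypergeomParams(N, K, n, k)


class TestCentralHypergeom:
    @pytest.mark.parametrize(
        "params, expected",
        [
            ((4, 2, 2, 1), 2 / 3),
            ((56, 43, 11, 11), 0.0386294074818),
            ((10, 0, 5, 0), 1.0),
        ],
    )
    def test_pmf_known_values(self, params, expected):
        assert hypergeom_pmf(HypergeomParams(*params)) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize(
        "params, expected",
        [
            ((56, 34, 11, 10), 0.0212952966082),
            ((56, 15, 11, 5), 0.1207362043486),
        ],
    )
    def test_sf_known_values(self, params, expected):
        assert hypergeom_sf(HypergeomParams(*params)) == pytest.approx(expected, rel=1e-10)

    def test_pmf_outside_support_is_zero(self):
        assert hypergeom_pmf(HypergeomParams(10, 4, 3, 4)) == 0.0
        assert hypergeom_pmf(HypergeomParams(10, 9, 8, 5)) == 0.0  # below support min 7

    def test_sf_at_support_minimum_is_one(self):
        assert hypergeom_sf(HypergeomParams(10, 9, 8, 7)) == 1.0
        assert hypergeom_sf(HypergeomParams(30, 5, 4, 0)) == 1.0

    def test_invalid_urn_raises(self):
        with pytest.raises(ValueError):
            HypergeomParams(5, 6, 2, 1)
        with pytest.raises(ValueError):
            HypergeomParams(5, 2, 6, 1)

    @settings(max_examples=150, derandomize=True)
    @given(urn_params(max_n=120))
    def test_sf_plus_cdf_identity_exact(self, p):
        """P(X >= k) + P(X <= k-1) = 1, in rational arithmetic."""
        sf = hypergeom_sf_exact(p)
        cdf_below = sum(
            hypergeom_pmf_exact(HypergeomParams(p.N, p.K, p.n, j))
            for j in range(p.support_min, p.k)
        )
        assert sf + cdf_below == Fraction(1)

    @settings(max_examples=150, derandomize=True)
    @given(urn_params(max_n=150))
    def test_float_path_matches_rational_oracle(self, p):
        exact = float(hypergeom_pmf_exact(p))
        assert hypergeom_pmf(p) == pytest.approx(exact, rel=1e-9, abs=1e-300)
        assert hypergeom_sf(p) == pytest.approx(float(hypergeom_sf_exact(p)), rel=1e-9)

    def test_cdf_bounds(self):
        p = HypergeomParams(20, 8, 6, 3)
        assert 0.0 < hypergeom_cdf(p) < 1.0
        assert hypergeom_cdf(HypergeomParams(20, 8, 6, 6)) == 1.0


class TestFisherNoncentral:
    def test_enumeration_example(self):
        p = NoncentralParams(HypergeomParams(4, 2, 2, 2), 2.0)
        assert fnch_pmf(p) == pytest.approx(4 / 13, rel=1e-12)
        p1 = NoncentralParams(HypergeomParams(4, 2, 2, 1), 2.0)
        assert fnch_sf(p1) == pytest.approx(12 / 13, rel=1e-12)

    def test_large_omega_saturates_successes(self):
        p = NoncentralParams(HypergeomParams(4, 2, 2, 2), 1e12)
        assert fnch_pmf(p) == pytest.approx(1.0, abs=1e-10)

    def test_omega_must_be_positive(self):
        with pytest.raises(ValueError):
            NoncentralParams(HypergeomParams(4, 2, 2, 1), 0.0)
        with pytest.raises(ValueError):
            NoncentralParams(HypergeomParams(4, 2, 2, 1), -1.5)

    def test_sf_at_support_minimum_is_one(self):
        assert fnch_sf(NoncentralParams(HypergeomParams(10, 9, 8, 7), 3.0)) == 1.0

    @settings(max_examples=120, derandomize=True)
    @given(urn_params(max_n=80))
    def test_central_reduction_at_omega_one(self, p):
        nc = NoncentralParams(p, 1.0)
        assert abs(fnch_pmf(nc) - hypergeom_pmf(p)) <= 1e-12
        assert abs(fnch_sf(nc) - hypergeom_sf(p)) <= 1e-11

    @settings(max_examples=100, derandomize=True)
    @given(urn_params(max_n=80), st.floats(min_value=0.1, max_value=10.0))
    def test_pmf_sums_to_one(self, p, omega):
        total = sum(
            fnch_pmf(NoncentralParams(HypergeomParams(p.N, p.K, p.n, j), omega))
            for j in range(p.support_min, p.support_max + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=100, derandomize=True)
    @given(urn_params(max_n=120), st.floats(min_value=0.1, max_value=10.0))
    def test_float_path_matches_rational_oracle(self, p, omega):
        nc = NoncentralParams(p, omega)
        exact = float(fnch_pmf_exact(nc))
        assert fnch_pmf(nc) == pytest.approx(exact, rel=1e-9, abs=1e-300)
        assert fnch_sf(nc) == pytest.approx(float(fnch_sf_exact(nc)), rel=1e-9)

    def test_sf_nondecreasing_in_omega(self, rng):
        """More bias toward successes gives a fatter upper tail."""
        for _ in range(50):
            N = int(rng.integers(5, 100))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            kmin, kmax = max(0, n + K - N), min(n, K)
            k = int(rng.integers(kmin, kmax + 1))
            omegas = np.sort(rng.uniform(0.2, 5.0, 4))
            sfs = [
                fnch_sf(NoncentralParams(HypergeomParams(N, K, n, k), w)) for w in omegas
            ]
            assert all(b >= a - 1e-12 for a, b in zip(sfs, sfs[1:]))

    def test_numerically_stable_at_large_population(self):
        p = NoncentralParams(HypergeomParams(25_000, 1_200, 800, 60), 1.7)
        v = fnch_sf(p)
        assert 0.0 < v < 1.0 and np.isfinite(v)

    def test_matches_conditioned_bernoulli_monte_carlo(self, rng):
        """Independent MC oracle: Bernoulli draws conditioned on the total.

        Successes ~ Bernoulli(w p /(1 + w p)), failures ~ Bernoulli(p/(1+p));
        conditioning on total = n by rejection yields Fisher's noncentral
        law, so the empirical upper tail must match fnch_sf within 3 SE.
        """
        N, K, n, k, omega = 40, 15, 12, 7, 1.8
        pbase = n / N
        target = 100_000
        hits = accepted = 0
        while accepted < target:
            ks = rng.binomial(K, omega * pbase / (1 + omega * pbase), 400_000)
            fs = rng.binomial(N - K, pbase / (1 + pbase), 400_000)
            sel = ks[(ks + fs) == n]
            take = min(target - accepted, sel.size)
            hits += int((sel[:take] >= k).sum())
            accepted += take
        est = hits / target
        se = np.sqrt(est * (1 - est) / target)
        assert abs(est - fnch_sf(NoncentralParams(HypergeomParams(N, K, n, k), omega))) <= 3 * se


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([1.0, 0.001], [1.0, 0.002]),
        ],
    )
    def test_step_up_examples(self, raw, expected):
        assert bh_adjust(raw).adjusted == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_step_up_definition(self, rng):
        """Oracle: direct min_{j>=i} (m p_(j) / j) computation."""
        raw = rng.uniform(0, 1, 37)
        order = np.argsort(raw)
        m = len(raw)
        adj_sorted = np.minimum.accumulate(
            (m * raw[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert bh_adjust(raw).adjusted == pytest.approx(expected.tolist())

    def test_values_in_unit_interval_and_order_preserved(self, rng):
        raw = rng.uniform(0, 1, 101)
        out = bh_adjust(raw)
        assert isinstance(out, PValueVector)
        assert out.raw == pytest.approx(raw.tolist())
        assert all(0.0 <= a <= 1.0 for a in out.adjusted)

    def test_empty_input(self):
        assert bh_adjust([]).adjusted == ()
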