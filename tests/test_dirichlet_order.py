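"""Numerical core: symmetric Dirichlet order statistics.

Closed forms used as oracles: at β = 1 the gamma representation is
exponential, so f̂_r = (1/n) Σ_{k=r}^n 1/k exactly; for n = 2, β = 1 the
simplex integrals give ⟨θ_(1)⟩ = 3/4, ⟨θ_(1)²⟩ = 7/12, ⟨θ_(2)²⟩ = 1/12.
"""

import numpy as np
import pytest
from scipy import integrate

from phonorank import (
    DirichletSpec,
    approx_curve,
    chi_density,
    expected_curve,
    flat_closed_form,
    incomplete_gamma_phi,
    mean_curve,
    ordered_moment,
    relative_fluctuation,
    sample_ordered,
)


class TestIncompleteGammaPhi:
    def test_endpoints_and_monotonicity(self):
        assert incomplete_gamma_phi(0.0, 0.7) == 0.0
        y = np.linspace(0, 30, 200)
        vals = incomplete_gamma_phi(y, 0.7)
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] == pytest.approx(1.0, abs=1e-9)

    def test_beta_one_is_exponential_cdf(self):
        assert incomplete_gamma_phi(1.0, 1.0) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_matches_direct_quadrature(self):
        # independent oracle: adaptive quadrature of the defining integrand
        from scipy.special import gamma

        direct, _ = integrate.quad(lambda x: x ** (0.8 - 1) * np.exp(-x) / gamma(0.8), 0, 0.5)
        assert incomplete_gamma_phi(0.5, 0.8) == pytest.approx(direct, abs=1e-10)

    def test_invalid_beta_raises(self):
        with pytest.raises(ValueError):
            incomplete_gamma_phi(1.0, 0.0)


class TestChiDensity:
    @pytest.mark.parametrize("m", [0, 1, 2])
    def test_single_category_moments_are_unity(self, m):
        # n = 1 forces θ = 1, so ∫ y^m χ_1(y; m) dy = 1 for every m
        spec = DirichletSpec(1, 0.9)
        val, _ = integrate.quad(lambda y: y**m * chi_density(y, 1, m, spec), 0, 60)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_first_moments_sum_to_one(self):
        spec = DirichletSpec(7, 0.65)
        total = sum(ordered_moment(r, 1, spec) for r in range(1, 8))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_density_matches_monte_carlo_histogram(self):
        # m = 0 form is the density of the 2nd largest of 5 Gamma(0.7) draws
        spec = DirichletSpec(5, 0.7)
        rng = np.random.default_rng(42)
        g = np.sort(rng.gamma(0.7, size=(10**6, 5)), axis=1)
        second_largest = g[:, -2]
        lo, hi = 0.9, 1.1
        p_mc = np.mean((second_largest >= lo) & (second_largest < hi))
        p_quad, _ = integrate.quad(lambda y: chi_density(y, 2, 0, spec), lo, hi)
        se = np.sqrt(p_mc * (1 - p_mc) / g.shape[0])
        assert abs(p_quad - p_mc) < 3 * se

    def test_rank_out_of_range_raises(self):
        with pytest.raises(ValueError):
            chi_density(1.0, 6, 1, DirichletSpec(5, 0.7))


class TestOrderedMoments:
    def test_flat_two_category_closed_forms(self):
        spec = DirichletSpec(2, 1.0)
        assert ordered_moment(1, 1, spec) == pytest.approx(0.75, abs=1e-10)
        m2 = ordered_moment(1, 2, spec) + ordered_moment(2, 2, spec)
        assert m2 == pytest.approx(2 / 3, abs=1e-10)

    def test_flat_three_category_means(self):
        spec = DirichletSpec(3, 1.0)
        means = [ordered_moment(r, 1, spec) for r in (1, 2, 3)]
        assert means == pytest.approx([11 / 18, 5 / 18, 2 / 18], abs=1e-10)

    @pytest.mark.parametrize("n", [5, 17, 50])
    def test_flat_case_equals_harmonic_closed_form(self, n):
        spec = DirichletSpec(n, 1.0)
        for r in range(1, n + 1, max(1, n // 7)):
            assert ordered_moment(r, 1, spec) == pytest.approx(
                flat_closed_form(n, r), abs=1e-8
            )

    def test_fast_curve_agrees_with_adaptive_quadrature(self):
        spec = DirichletSpec(44, 0.77)
        fast = mean_curve(44, 0.77)
        adaptive = np.array([ordered_moment(r, 1, spec) for r in range(1, 45)])
        assert np.max(np.abs(fast - adaptive)) < 1e-9


class TestExpectedCurve:
    @pytest.mark.parametrize("n,beta", [(2, 0.5), (10, 0.8), (44, 1.2)])
    def test_table_invariants(self, n, beta):
        tab = expected_curve(DirichletSpec(n, beta))
        assert np.all(np.diff(tab.mean) < 0) or n == 1
        assert tab.mean[-1] > 0
        assert tab.mean.sum() == pytest.approx(1.0, abs=1e-8)
        assert tab.second_moment.sum() == pytest.approx(
            (beta + 1) / (n * beta + 1), abs=1e-8
        )

    def test_single_category(self):
        tab = expected_curve(DirichletSpec(1, 0.8))
        assert tab.mean[0] == pytest.approx(1.0, abs=1e-10)

    def test_top_rank_decreases_with_beta(self):
        # larger β → more homogeneous density → smaller top frequency
        f1 = [mean_curve(44, b)[0] for b in (0.4, 0.8, 1.2)]
        assert f1[0] > f1[1] > f1[2]

    def test_matches_monte_carlo_ranked_means(self):
        spec = DirichletSpec(44, 0.8)
        draws = sample_ordered(spec, 10**5, seed=0)
        mc_mean = draws.mean(axis=0)
        mc_se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(mean_curve(44, 0.8) - mc_mean) < 3 * mc_se + 1e-12)


class TestApproxCurve:
    def test_flat_case_is_logarithmic(self):
        n = 20
        expected = np.log(n / np.arange(1, n + 1)) / n
        assert approx_curve(DirichletSpec(n, 1.0)) == pytest.approx(expected, abs=1e-10)

    def test_last_rank_is_zero(self):
        assert approx_curve(DirichletSpec(44, 0.8))[-1] == 0.0

    def test_near_overlap_with_exact_curve(self):
        # closed-form approximation tracks the exact means for almost all
        # ranks; the known exception is the very top rank (~15% of f̂_1)
        spec = DirichletSpec(44, 0.8)
        exact = mean_curve(44, 0.8)
        rel = np.abs(approx_curve(spec) - exact) / exact[0]
        assert rel.max() < 0.2
        assert rel[6:].max() < 0.03


class TestRelativeFluctuation:
    def test_two_category_closed_form(self):
        # (7/12 − 9/16)/(9/16) = 1/27
        assert relative_fluctuation(1, DirichletSpec(2, 1.0)) == pytest.approx(
            1 / 27, abs=1e-9
        )

    def test_single_category_has_no_fluctuation(self):
        assert relative_fluctuation(1, DirichletSpec(1, 0.8)) == pytest.approx(0.0, abs=1e-9)

    def test_profile_is_nonmonotonic_with_middle_minimum(self):
        # ε_r dips at middle ranks and blows up for the rarest ranks
        tab = expected_curve(DirichletSpec(44, 0.8), tol=1e-11)
        mid = int(np.argmin(tab.eps))
        assert 3 < mid < 20
        assert tab.eps[0] > tab.eps[mid]
        assert tab.eps[-1] > 0.5


class TestSampleOrdered:
    def test_rows_are_sorted_probability_vectors(self):
        s = sample_ordered(DirichletSpec(6, 0.7), 500, seed=1)
        assert s.shape == (500, 6)
        assert np.allclose(s.sum(axis=1), 1.0)
        assert np.all(np.diff(s, axis=1) <= 0)

    def test_deterministic_under_seed(self):
        a = sample_ordered(DirichletSpec(5, 0.9), 100, seed=7)
        b = sample_ordered(DirichletSpec(5, 0.9), 100, seed=7)
        assert np.array_equal(a, b)

    def test_flat_three_category_column_means(self):
        s = sample_ordered(DirichletSpec(3, 1.0), 10**5, seed=2)
        se = s.std(axis=0) / np.sqrt(s.shape[0])
        target = np.array([11 / 18, 5 / 18, 2 / 18])
        assert np.all(np.abs(s.mean(axis=0) - target) < 3 * se)


def test_neutrality_under_subsetting():
    """Dropping components and renormalizing leaves a Dirichlet with the
    same concentration: moments of the kept, renormalized, sorted parts
    match the smaller model's expected table."""
    n, m_keep, beta = 10, 6, 0.7
    rng = np.random.default_rng(11)
    g = rng.gamma(beta, size=(10**5, n))
    kept = g[:, :m_keep]
    theta = kept / kept.sum(axis=1, keepdims=True)
    ordered = -np.sort(-theta, axis=1)
    tab = expected_curve(DirichletSpec(m_keep, beta))
    se1 = ordered.std(axis=0) / np.sqrt(ordered.shape[0])
    assert np.all(np.abs(ordered.mean(axis=0) - tab.mean) < 3 * se1 + 1e-12)
    sq = ordered**2
    se2 = sq.std(axis=0) / np.sqrt(sq.shape[0])
    assert np.all(np.abs(sq.mean(axis=0) - tab.second_moment) < 3 * se2 + 1e-12)
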