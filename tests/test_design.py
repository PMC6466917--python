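"""Unit tests for the design module: information components, the size
cap, sorting, PSV, fixed-size chunking and the optimal single size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from varpool import (
    AssaySpec,
    CovariateMatrix,
    DesignConfig,
    LOGIT,
    PHI0_DEFAULT,
    fisher_information,
    fixed_size_assign,
    individual_risk,
    optimal_single_size,
    pool_C,
    pool_G,
    pool_H,
    pool_statistics,
    psv_assign,
    reduced_fisher_information,
    size_cap,
    solve_phi0,
    sort_by_risk,
)

from conftest import brute_force_psv_sizes, naive_pool_cost


def _rows(*xs):
    return np.column_stack([np.ones(len(xs)), np.array(xs)])


BETA = np.array([0.0, 1.0])  # with rows (1, logit(p)) risks are p exactly


def _rows_for_risks(risks):
    return _rows(*LOGIT.inverse(np.asarray(risks)) - 0.0)


# ---------------------------------------------------------------------------
# H, G, C
# ---------------------------------------------------------------------------

def test_pool_H_examples():
    rows = _rows_for_risks([0.1, 0.2])
    expected = -(math.log(0.9) + math.log(0.8)) / 2
    assert pool_H(BETA, rows) == pytest.approx(expected, rel=1e-12)
    same = _rows_for_risks([0.3, 0.3, 0.3])
    assert pool_H(BETA, same) == pytest.approx(-math.log(0.7), rel=1e-12)


@pytest.mark.parametrize("risks", [[0.1], [0.05, 0.4, 0.7], [0.2, 0.2]])
def test_pool_H_survival_identity(risks):
    """exp(-k H) equals the pool survival product."""
    rows = _rows_for_risks(risks)
    k = len(risks)
    q = math.prod(1 - p for p in risks)
    assert math.exp(-k * pool_H(BETA, rows)) == pytest.approx(q, rel=1e-12)


def test_pool_H_rejects_certain_infection():
    with pytest.raises(ValueError):
        pool_H([0.0, 1.0], np.array([[1.0, 60.0]]))


def test_pool_G_matches_finite_differences():
    rng = np.random.default_rng(2)
    rows = np.column_stack([np.ones(4), rng.normal(0, 1, 4),
                            rng.normal(0, 1, 4)])
    beta = np.array([-0.5, 0.8, -0.3])
    g = pool_G(beta, rows)
    h = 1e-6
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        fd = (pool_H(beta + e, rows) - pool_H(beta - e, rows)) / (2 * h)
        assert g[j] == pytest.approx(fd, rel=1e-6, abs=1e-9)


def test_pool_G_single_member_logistic_identity():
    """For one member under the logistic link g'/(1-g) = g, so G = p x."""
    row = np.array([[1.0, 1.3]])
    beta = np.array([-0.7, 0.9])
    p = LOGIT.evaluate(row @ beta)[0]
    np.testing.assert_allclose(pool_G(beta, row), p * row[0], rtol=1e-12)


def test_pool_C_examples():
    # size-1 pool, perfect assay: C = p/(1-p)
    row = _rows_for_risks([0.3])
    assert pool_C(BETA, row, AssaySpec(1, 1)) == pytest.approx(0.3 / 0.7,
                                                               rel=1e-10)
    # worked two-member example: Q=0.72, P1=0.302
    rows = _rows_for_risks([0.1, 0.2])
    expected = 0.302 * 0.698 / (0.81 * 4 * 0.72**2)
    assert pool_C(BETA, rows, AssaySpec(0.95, 0.95)) == pytest.approx(
        expected, rel=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 0.9), min_size=1, max_size=6))
def test_pool_C_probability_form_identity(risks):
    """The H-based cost equals P1*P0/(r^2 k^2 Q^2) to 1e-12."""
    rows = _rows_for_risks(risks)
    a = AssaySpec(0.93, 0.96)
    c = pool_C(BETA, rows, a)
    q = math.prod(1 - p for p in risks)
    p1 = a.sensitivity - a.r * q
    prob_form = p1 * (1 - p1) / (a.r**2 * len(risks) ** 2 * q**2)
    assert c == pytest.approx(prob_form, rel=1e-12)


# ---------------------------------------------------------------------------
# Fisher information
# ---------------------------------------------------------------------------

def _chunk_assignment(n, k):
    from varpool import PoolAssignment

    sizes = [k] * (n // k)
    return PoolAssignment(np.arange(n), sizes)


def test_fisher_information_reduces_to_logistic():
    """Size-1 pools, perfect assay: I = sum p(1-p) x x' (textbook)."""
    rng = np.random.default_rng(4)
    X = CovariateMatrix.from_raw(rng.normal(0, 1, (50, 2)))
    beta = np.array([-1.0, 0.5, -0.2])
    asn = _chunk_assignment(50, 1)
    info = fisher_information(beta, asn, X, AssaySpec(1, 1))
    p = individual_risk(X, beta)
    w = p * (1 - p)
    expected = (X.values * w[:, None]).T @ X.values
    np.testing.assert_allclose(info, expected, rtol=1e-8)


def test_fisher_information_symmetric_psd_additive():
    rng = np.random.default_rng(9)
    X = CovariateMatrix.from_raw(rng.normal(0, 1.2, (24, 1)))
    beta = np.array([-1.5, 0.6])
    a = AssaySpec(0.95, 0.97)
    asn = _chunk_assignment(24, 3)
    info = fisher_information(beta, asn, X, a)
    np.testing.assert_allclose(info, info.T)
    assert np.linalg.eigvalsh(info).min() >= -1e-10
    # doubling identical pools doubles the information
    X2 = CovariateMatrix.from_raw(np.vstack([X.values[:, 1:]] * 2))
    asn2 = _chunk_assignment(48, 3)
    info2 = fisher_information(beta, asn2, X2, a)
    np.testing.assert_allclose(info2, 2 * info, rtol=1e-10)


def test_reduced_information_exact_for_singletons_and_identical():
    a = AssaySpec(0.95, 0.95)
    beta = np.array([-1.0, 0.8])
    rng = np.random.default_rng(12)
    X = CovariateMatrix.from_raw(rng.normal(0, 1, (10, 1)))
    asn1 = _chunk_assignment(10, 1)
    np.testing.assert_allclose(
        reduced_fisher_information(beta, asn1, X, a),
        fisher_information(beta, asn1, X, a), rtol=1e-12)
    # pools of identical members: xbar is the common row, so Z = G and
    # the reduced form equals the full form exactly
    Xi = CovariateMatrix.from_raw(np.repeat(rng.normal(0, 1, (4, 1)), 3,
                                            axis=0))
    asn3 = _chunk_assignment(12, 3)
    np.testing.assert_allclose(
        reduced_fisher_information(beta, asn3, Xi, a),
        fisher_information(beta, asn3, Xi, a), rtol=1e-10)
    stats = pool_statistics(beta, Xi.values[:3], a)
    np.testing.assert_allclose(stats.Z, stats.G, rtol=1e-12)


def test_reduced_information_close_after_risk_sorting():
    """On the benchmark scenario, risk-sorted pools are homogeneous
    enough that the reduced form tracks the full form within 5%
    (relative Frobenius gap)."""
    import varpool as vp

    rng = np.random.default_rng(3)
    X = vp.SINGLE_NORMAL.sample(2000, rng)
    beta = np.array([-3.0, 0.4])
    a = AssaySpec(0.99, 0.99)
    asn = fixed_size_assign(X, 10, beta_init=beta, sort=True)
    full = fisher_information(beta, asn, X, a)
    red = reduced_fisher_information(beta, asn, X, a)
    gap = np.linalg.norm(red - full) / np.linalg.norm(full)
    assert gap < 0.05


# ---------------------------------------------------------------------------
# phi0 and the size cap
# ---------------------------------------------------------------------------

def test_solve_phi0_satisfies_equation():
    a = AssaySpec(0.95, 0.95)
    phi = solve_phi0(a)
    se, r = 0.95, 0.9
    f = (2 * se * (1 - se) * (phi - 1) * math.exp(2 * phi)
         + r * (2 * se - 1) * (phi - 2) * math.exp(phi) + 2 * r**2)
    assert abs(f) < 1e-8


def test_solve_phi0_perfect_assay_reduced_equation():
    """Se=Sp=1 collapses the equation to (phi-2)e^phi + 2 = 0."""
    phi = solve_phi0(AssaySpec(1, 1))
    independent = bisect(lambda x: (x - 2) * math.exp(x) + 2, 0.5, 5.0,
                         xtol=1e-12)
    assert phi == pytest.approx(independent, abs=1e-8)


def test_phi0_default_is_published_constant():
    assert PHI0_DEFAULT == 1.8414
    assert DesignConfig(k_max=5, beta_init=[0.0]).phi0 == 1.8414


def test_size_cap_examples():
    k_max = 4
    # boundary: risk chosen so that c0 == k_max exactly -> capped by <=
    p_star = 1 - math.exp(-PHI0_DEFAULT / k_max)
    dec = size_cap([1.0, LOGIT.inverse(p_star)], BETA, k_max)
    assert dec.c0 == pytest.approx(k_max, rel=1e-10)
    assert dec.capped and dec.chosen_k == k_max
    # risk 0 (underflow): W = 0, c0 = inf, capped by convention
    dec0 = size_cap([1.0, -800.0], BETA, k_max)
    assert dec0.capped and np.isinf(dec0.c0)
    # c0 strictly decreasing in the leading risk
    c0s = [size_cap([1.0, LOGIT.inverse(p)], BETA, k_max).c0
           for p in (0.05, 0.2, 0.5, 0.8)]
    assert np.all(np.diff(c0s) < 0)
    with pytest.raises(ValueError):
        size_cap([1.0, 80.0], BETA, k_max)


# ---------------------------------------------------------------------------
# Sorting and assignment
# ---------------------------------------------------------------------------

def test_sort_by_risk_properties():
    # descending input: identity permutation
    X = CovariateMatrix.from_raw([[3.0], [2.0], [1.0]])
    np.testing.assert_array_equal(
        sort_by_risk(X, [0.0, 1.0]).permutation, [0, 1, 2])
    # stability under ties
    Xt = CovariateMatrix.from_raw([[1.0], [1.0], [1.0]])
    np.testing.assert_array_equal(
        sort_by_risk(Xt, [0.0, 1.0]).permutation, [0, 1, 2])
    # random input: output risks are the sorted input risks
    rng = np.random.default_rng(8)
    Xr = CovariateMatrix.from_raw(rng.normal(0, 2, (40, 1)))
    ordering = sort_by_risk(Xr, [-0.5, 0.8])
    risks = individual_risk(Xr, [-0.5, 0.8])
    np.testing.assert_allclose(ordering.risks, np.sort(risks)[::-1])


def test_psv_six_specimen_fixture(six_specimen_cohort, assay95):
    """Printed-risk cohort, k_max=3: sizes equal the brute-force
    sequential oracle's."""
    X, beta0, risks = six_specimen_cohort
    config = DesignConfig(k_max=3, beta_init=beta0)
    asn = psv_assign(X, config, assay95)
    expected = brute_force_psv_sizes(list(risks), assay95, 3)
    np.testing.assert_array_equal(asn.group_sizes, expected)
    assert asn.n_assigned == 6


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("k_max", [2, 3, 4])
def test_psv_matches_brute_force_oracle(seed, k_max):
    """Random cohorts with N <= 12: the vectorised PSV agrees with a
    naive step-by-step implementation of the same rules."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    X = CovariateMatrix.from_raw(rng.normal(0.5, 1.5, (n, 1)))
    beta0 = np.array([-0.5, 0.8])
    a = AssaySpec(0.95, 0.95)
    config = DesignConfig(k_max=k_max, beta_init=beta0)
    asn = psv_assign(X, config, a)
    risks_sorted = np.sort(individual_risk(X, beta0))[::-1]
    expected = brute_force_psv_sizes(list(risks_sorted), a, k_max)
    np.testing.assert_array_equal(asn.group_sizes, expected)
    # partition invariants
    assert asn.n_assigned == n
    assert asn.group_sizes.max() <= k_max


def test_psv_identical_specimens_give_equal_sizes():
    X = CovariateMatrix.from_raw(np.full((12, 1), 1.3))
    config = DesignConfig(k_max=3, beta_init=[-2.0, 0.5])
    asn = psv_assign(X, config, AssaySpec(0.95, 0.95))
    assert len(set(asn.group_sizes[:-1].tolist())) <= 1


def test_psv_kmax_one_gives_singletons():
    X = CovariateMatrix.from_raw(np.arange(5, dtype=float)[:, None])
    config = DesignConfig(k_max=1, beta_init=[0.0, 0.3])
    asn = psv_assign(X, config, AssaySpec(0.95, 0.95))
    np.testing.assert_array_equal(asn.group_sizes, np.ones(5, int))


def test_psv_sizes_nondecreasing_for_decreasing_risks():
    """Empirical property: as risk falls along the sorted cohort the
    chosen sizes never shrink (final, possibly truncated pool aside)."""
    risks = np.linspace(0.55, 0.02, 60)
    X = CovariateMatrix.from_raw(LOGIT.inverse(risks)[:, None])
    config = DesignConfig(k_max=8, beta_init=[0.0, 1.0])
    asn = psv_assign(X, config, AssaySpec(0.95, 0.95))
    sizes = asn.group_sizes[:-1]
    assert np.all(np.diff(sizes) >= 0)


def test_psv_rejects_empty_and_bad_assay():
    with pytest.raises(ValueError):
        CovariateMatrix(np.empty((0, 1)))


def test_fixed_size_assign_examples():
    X = CovariateMatrix.from_raw(np.arange(10, dtype=float)[:, None])
    asn = fixed_size_assign(X, 5, beta_init=[0.0, 1.0])
    np.testing.assert_array_equal(asn.group_sizes, [5, 5])
    X11 = CovariateMatrix.from_raw(np.arange(11, dtype=float)[:, None])
    asn11 = fixed_size_assign(X11, 5, beta_init=[0.0, 1.0])
    np.testing.assert_array_equal(asn11.group_sizes, [5, 5, 1])


def test_fixed_size_assign_428_by_11():
    """A 428-specimen cohort at size 11 yields 39 pools, the last one
    holding the 10 leftover specimens."""
    rng = np.random.default_rng(0)
    X = CovariateMatrix.from_raw(rng.normal(25, 5, (428, 1)))
    asn = fixed_size_assign(X, 11, beta_init=[-2.0, -0.05])
    assert asn.m == 39
    assert asn.group_sizes[-1] == 10
    assert asn.n_assigned == 428


# ---------------------------------------------------------------------------
# Optimal single size
# ---------------------------------------------------------------------------

def test_optimal_single_size_k1_is_individual_testing_variance():
    a = AssaySpec(0.95, 0.95)
    choice = optimal_single_size(0.2, a, 5)
    pi1 = a.sensitivity - a.r * 0.8
    assert choice.objective_curve[0] == pytest.approx(pi1 * (1 - pi1) / a.r**2)


def test_optimal_single_size_matches_exhaustive_scan():
    a = AssaySpec(0.97, 0.93)
    p_bar = 0.07
    choice = optimal_single_size(p_bar, a, 30)

    def variance(k):
        pik = a.sensitivity - a.r * (1 - p_bar) ** k
        return pik * (1 - pik) / (a.r**2 * k**2 * (1 - p_bar) ** (2 * k - 2))

    best = min(range(1, 31), key=variance)
    assert choice.k_star == best
    assert choice.objective_curve[choice.k_star - 1] == pytest.approx(
        variance(choice.k_star))


@pytest.mark.parametrize("se,expected_range", [
    (0.99, (12, 14)),   # reported "mostly 13"
    (0.95, (12, 14)),   # reported "mostly 12"
    (0.90, (10, 12)),   # reported "mostly 11"
])
def test_optimal_single_size_near_reported(se, expected_range):
    """At the benchmark prevalence ~0.0997 the optimal size lands in the
    reported neighbourhood (11-13, varying with assay accuracy)."""
    choice = optimal_single_size(0.0997, AssaySpec(se, se), 25)
    assert expected_range[0] <= choice.k_star <= expected_range[1]


def test_optimal_single_size_rejects_degenerate_prevalence():
    with pytest.raises(ValueError):
        optimal_single_size(0.0, AssaySpec(0.95, 0.95), 10)
    with pytest.raises(ValueError):
        optimal_single_size(1.0, AssaySpec(0.95, 0.95), 10)
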