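"""Log-likelihood, gradient, and coordinate binary-search optimization."""

import math

import numpy as np
import pytest
from scipy import stats

from pynurd import (
    binary_search_root,
    closed_form_single_isoform,
    coordinate_ascent,
    coordinate_binary_search,
    gradient_component,
    log_likelihood,
    theta_to_rpkm,
)
from conftest import random_instance

L2 = np.array([100.0, 100.0])
B1 = np.ones((1, 2))
X2 = np.array([10.0, 10.0])
W = 1000


def test_loglik_two_poisson_segments():
    # lambda_j = 100 * 1000 * 1e-4 = 10 per segment
    ll = log_likelihood([1e-4], X2, L2, B1, W)
    assert ll == pytest.approx(-4.15712, abs=1e-4)


def test_loglik_zero_theta_with_counts_is_minus_inf():
    assert log_likelihood([0.0], X2, L2, B1, W) == -math.inf


def test_loglik_zero_count_segment_contributes_only_rate_penalty():
    ll = log_likelihood([1e-4], [0.0, 10.0], L2, B1, W)
    lam = 10.0
    expected = -lam + stats.poisson.logpmf(10, lam)  # zero-count segment adds -lam
    assert ll == pytest.approx(expected, rel=1e-12)


def test_loglik_negative_theta_rejected():
    with pytest.raises(ValueError):
        log_likelihood([-1e-5], X2, L2, B1, W)


def test_loglik_matches_poisson_pmf_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        x, lengths, b, w, theta = random_instance(rng)
        lam = lengths * w * (theta @ b)
        expected = stats.poisson.logpmf(x, lam).sum()
        assert log_likelihood(theta, x, lengths, b, w) == pytest.approx(expected, rel=1e-10)


def test_gradient_closed_form_values():
    # at theta = sum(x) / (w * sum(l)) the m=1 gradient vanishes
    assert gradient_component([1e-4], 0, X2, L2, B1, W) == pytest.approx(0.0, abs=1e-9)
    assert gradient_component([2e-4], 0, X2, L2, B1, W) == pytest.approx(-100_000.0)


def test_gradient_all_zero_counts_is_negative_constant():
    x = np.zeros(2)
    for theta in ([1e-6], [5e-4], [1.0]):
        g = gradient_component(theta, 0, x, L2, B1, W)
        assert g == pytest.approx(-W * L2.sum())


def test_gradient_zero_rate_with_counts_is_plus_inf():
    assert gradient_component([0.0], 0, X2, L2, B1, W) == math.inf


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(12)
    for _ in range(50):
        x, lengths, b, w, theta = random_instance(rng)
        h = 1e-5 * max(theta.max(), 1e-6)  # balances truncation vs. cancellation
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] = max(tm[i] - h, 0)
            fd = (
                log_likelihood(tp, x, lengths, b, w)
                - log_likelihood(tm, x, lengths, b, w)
            ) / (tp[i] - tm[i])
            g = gradient_component(theta, i, x, lengths, b, w)
            assert g == pytest.approx(fd, rel=1e-4, abs=abs(fd) * 1e-4 + 1e-3)


def test_binary_search_linear_root_and_iteration_cap():
    root, iters = binary_search_root(lambda t: 3 - t, 0, 10, 1e-6, return_iterations=True)
    assert root == pytest.approx(3.0, abs=1e-6)
    assert iters <= math.ceil(math.log2(10 / 1e-6)) == 24


def test_binary_search_boundary_cases():
    assert binary_search_root(lambda t: -1.0, 0, 10, 1e-6) == 0
    assert binary_search_root(lambda t: 1.0, 0, 10, 1e-6) == 10
    with pytest.raises(ValueError):
        binary_search_root(lambda t: math.nan, 0, 1, 1e-6)


def test_binary_search_on_single_isoform_gradient_matches_closed_form():
    rng = np.random.default_rng(13)
    for _ in range(20):
        n = rng.integers(2, 8)
        lengths = rng.integers(50, 400, n).astype(float)
        b = rng.uniform(0.3, 1.5, (1, n))
        w = 50_000
        x = rng.poisson(lengths * w * 5e-5 * b[0])
        closed = closed_form_single_isoform(x, lengths, b[0], w)
        g = lambda t: gradient_component([t], 0, x, lengths, b, w)
        root = binary_search_root(g, 0.0, max(closed * 4, 1e-6), 1e-14)
        assert root == pytest.approx(closed, abs=1e-13 + closed * 1e-6)


def test_coordinate_search_single_isoform_equals_closed_form():
    rng = np.random.default_rng(14)
    for _ in range(20):
        x, lengths, b, w, _ = random_instance(rng, m_max=1)
        est = coordinate_binary_search(x, lengths, b, w)
        closed = closed_form_single_isoform(x, lengths, b[0], w)
        assert est.theta[0] == pytest.approx(closed, rel=1e-6)
        assert est.converged


def test_coordinate_search_zero_counts_gene():
    est = coordinate_binary_search(np.zeros(3), [100, 200, 300], np.ones((2, 3)), 1000)
    assert np.all(est.theta == 0) and est.converged
    assert est.loglik == 0.0  # all rates zero, all counts zero


def test_coordinate_search_flags_identical_rows():
    b = np.array([[1.0, 1.0], [1.0, 1.0]])
    est = coordinate_binary_search([10, 10], [100, 100], b, 1000)
    assert est.unidentifiable


def test_monotone_ascent_trace():
    rng = np.random.default_rng(15)
    for _ in range(30):
        x, lengths, b, w, _ = random_instance(rng)
        est = coordinate_binary_search(x, lengths, b, w)
        trace = np.array(est.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)


def test_concavity_of_log_likelihood():
    rng = np.random.default_rng(16)
    checks = 0
    while checks < 1000:
        x, lengths, b, w, _ = random_instance(rng)
        m = b.shape[0]
        for _ in range(25):
            ta = rng.uniform(0, 3e-4, m)
            tb = rng.uniform(0, 3e-4, m)
            lam = rng.random()
            mid = lam * ta + (1 - lam) * tb
            f_mid = log_likelihood(mid, x, lengths, b, w)
            f_comb = lam * log_likelihood(ta, x, lengths, b, w) + (1 - lam) * log_likelihood(tb, x, lengths, b, w)
            if not math.isfinite(f_comb):
                continue
            assert f_mid >= f_comb - 1e-9 * max(1.0, abs(f_comb))
            checks += 1


def test_oracle_equivalence_small_instances():
    """Achieved log-likelihood matches scipy's constrained maximizer."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(17)
    for _ in range(40):
        x, lengths, b, w, theta_true = random_instance(rng)
        m = b.shape[0]
        est = coordinate_binary_search(x, lengths, b, w)

        def neg(t):
            return -log_likelihood(np.maximum(t, 0), x, lengths, b, w)

        res = minimize(
            neg, theta_true, method="L-BFGS-B",
            bounds=[(1e-12, None)] * m,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 2000},
        )
        assert est.loglik >= -res.fun - 1e-6


def test_coordinate_ascent_separable_quadratic_toy():
    """Bivariate concave toy with maximum at (1, 2), started at (2.5, 0.5),
    first search direction along y."""
    grads = [lambda p: -2 * (p[0] - 1), lambda p: -2 * (p[1] - 2)]
    x, trace, inner, converged = coordinate_ascent(
        grads,
        np.array([2.5, 0.5]),
        lower=np.array([-10.0, -10.0]),
        upper=np.array([10.0, 10.0]),
        eps=1e-10,
        value_fn=lambda p: -((p[0] - 1) ** 2) - (p[1] - 2) ** 2,
        tol=1e-12,
        order=[1, 0],  # y first
    )
    assert converged
    assert np.allclose(x, [1.0, 2.0], atol=1e-6)
    assert np.all(np.diff(trace) >= -1e-12)


def test_theta_to_rpkm():
    assert theta_to_rpkm(1e-4) == pytest.approx(1e5)
    assert theta_to_rpkm(0.0) == 0.0
    # 500 reads on a 1 kb single-isoform gene in a 1e6-read library -> 500 RPKM
    x, lengths, b, w = np.array([500.0]), np.array([1000.0]), np.ones((1, 1)), 1_000_000
    theta = closed_form_single_isoform(x, lengths, b[0], w)
    assert theta == pytest.approx(5e-7)
    direct_rpkm = 500 / ((1000 / 1e3) * (w / 1e6))
    assert theta_to_rpkm(theta) == pytest.approx(direct_rpkm)


from hypothesis import given, settings, strategies as st


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    root=st.floats(0.01, 9.99),
    slope=st.floats(0.01, 100),
    eps=st.floats(1e-10, 1e-3),
)
def test_binary_search_property(root, slope, eps):
    """Bisection on any decreasing linear function finds the root within eps
    and inside the guaranteed iteration bound."""
    found, iters = binary_search_root(
        lambda t: slope * (root - t), 0.0, 10.0, eps, return_iterations=True
    )
    assert abs(found - root) <= eps
    assert iters <= math.ceil(math.log2(10.0 / eps))
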