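"""WKD moment matching and BKE propagation: oracles and hand-worked cases."""

import numpy as np
import pytest

from cssl_ct.autodiff import Tensor
from cssl_ct.distill import (
    FDConfig,
    GaussianStats,
    bke_affinity,
    bke_closed_form,
    bke_iterate,
    compute_stats,
    fd_loss,
    propagation_matrix,
    wkd_loss,
)
from cssl_ct.exceptions import ConfigurationError, InvalidInputError, ShapeError


# -- channel statistics --------------------------------------------------------

def test_stats_two_point_example():
    p = np.array([[[0.0, 0.0]], [[2.0, 2.0]]])  # B=2, T=1, E=2
    stats = compute_stats(p)
    np.testing.assert_allclose(stats.mu, [1.0, 1.0])
    np.testing.assert_allclose(stats.delta, [1.0, 1.0])  # population divisor d=2
    assert stats.d == 2 and stats.l == 2


def test_stats_identical_samples_zero_spread(rng):
    v = rng.normal(size=6)
    p = np.tile(v, (3, 5, 1))
    stats = compute_stats(p)
    np.testing.assert_allclose(stats.delta, 0.0, atol=1e-12)
    np.testing.assert_allclose(stats.mu, v)


def test_stats_match_two_pass_oracle(rng):
    p = rng.normal(size=(4, 8, 16))
    stats = compute_stats(p)
    flat = p.reshape(32, 16)
    mu = np.array([flat[:, j].sum() / 32 for j in range(16)])
    var = np.array([((flat[:, j] - mu[j]) ** 2).sum() / 32 for j in range(16)])
    np.testing.assert_allclose(stats.mu, mu, atol=1e-10)
    np.testing.assert_allclose(stats.delta, np.sqrt(var), atol=1e-10)


def test_stats_insufficient_samples():
    with pytest.raises(InvalidInputError):
        compute_stats(np.zeros((1, 1, 4)))


# -- WKD loss ------------------------------------------------------------------

def test_wkd_zero_on_identical_stats(rng):
    p = rng.normal(size=(2, 4, 8))
    s = compute_stats(p)
    for gamma in (0.0, 1.0, 5.0):
        assert wkd_loss(s, s, gamma) == 0.0


def test_wkd_hand_value_two_sqrt_two():
    t = GaussianStats(mu=np.array([1.0, 1.0]), delta=np.array([0.5, 0.5]), l=2, d=4)
    s = GaussianStats(mu=np.array([0.0, 0.0]), delta=np.array([0.5, 0.5]), l=2, d=4)
    assert wkd_loss(t, s, 2.0) == pytest.approx(2 * np.sqrt(2), abs=1e-12)


def test_wkd_gamma_linearity_of_mean_term(rng):
    mu_t, mu_s = rng.normal(size=5), rng.normal(size=5)
    delta = np.abs(rng.normal(size=5))
    t = GaussianStats(mu=mu_t, delta=delta, l=5, d=10)
    s = GaussianStats(mu=mu_s, delta=delta.copy(), l=5, d=10)
    assert wkd_loss(t, s, 4.0) == pytest.approx(2 * wkd_loss(t, s, 2.0), rel=1e-12)


def test_wkd_symmetric_and_matches_norm_oracle(rng):
    a = compute_stats(rng.normal(size=(2, 6, 8)))
    b = compute_stats(rng.normal(size=(2, 6, 8)))
    gamma = 2.0
    oracle = gamma * np.sqrt(((np.asarray(a.mu) - b.mu) ** 2).sum()) + np.sqrt(
        ((np.asarray(a.delta) - b.delta) ** 2).sum()
    )
    assert wkd_loss(a, b, gamma) == pytest.approx(oracle, abs=1e-10)
    assert wkd_loss(a, b, gamma) == pytest.approx(wkd_loss(b, a, gamma), abs=1e-12)


def test_wkd_dimension_mismatch():
    a = GaussianStats(mu=np.zeros(3), delta=np.ones(3), l=3, d=4)
    b = GaussianStats(mu=np.zeros(4), delta=np.ones(4), l=4, d=4)
    with pytest.raises(ShapeError):
        wkd_loss(a, b, 1.0)


# -- BKE affinity --------------------------------------------------------------

def test_affinity_t2_is_antidiagonal(rng):
    p_t = rng.normal(size=(3, 2, 5))
    p_s = rng.normal(size=(3, 2, 5))
    a_hat = bke_affinity(p_t, p_s)
    # with one off-diagonal entry per row the softmax is exactly 1
    for b in range(3):
        np.testing.assert_allclose(a_hat[b], [[0.0, 1.0], [1.0, 0.0]], atol=1e-12)


def test_affinity_identical_tokens_uniform(rng):
    v = rng.normal(size=6)
    p = np.tile(v, (2, 5, 1))
    a_hat = bke_affinity(p, p)
    idx = np.arange(5)
    assert np.all(a_hat[:, idx, idx] == 0)
    off = a_hat[0][~np.eye(5, dtype=bool)]
    np.testing.assert_allclose(off, 1.0 / 4.0, atol=1e-12)


def test_affinity_structural_invariants(rng):
    p_t = rng.normal(size=(2, 16, 8))
    p_s = rng.normal(size=(2, 16, 8))
    a_hat = bke_affinity(p_t, p_s)
    assert np.all(a_hat >= 0)
    idx = np.arange(16)
    assert np.all(a_hat[:, idx, idx] == 0)
    np.testing.assert_allclose(a_hat.sum(axis=-1), 1.0, atol=1e-8)


def test_affinity_zero_norm_token_rejected(rng):
    p_t = rng.normal(size=(1, 4, 3))
    p_t[0, 2] = 0.0
    with pytest.raises(InvalidInputError):
        bke_affinity(p_t, rng.normal(size=(1, 4, 3)))


# -- BKE propagation -----------------------------------------------------------

def test_iterate_base_cases(rng):
    p_t = rng.normal(size=(2, 4, 3))
    a_hat = bke_affinity(p_t, rng.normal(size=(2, 4, 3)))
    np.testing.assert_array_equal(bke_iterate(a_hat, p_t, 0.5, 0), p_t)
    np.testing.assert_allclose(bke_iterate(a_hat, p_t, 0.0, 7), p_t, atol=1e-15)


def test_hand_worked_propagation_matrix():
    a_hat = np.array([[[0.0, 1.0], [1.0, 0.0]]])
    m = propagation_matrix(a_hat, 0.5)
    np.testing.assert_allclose(
        m[0], [[2.0 / 3.0, 1.0 / 3.0], [1.0 / 3.0, 2.0 / 3.0]], atol=1e-12
    )
    p_t = np.array([[[1.0, 0.0], [0.0, 3.0]]])
    q = bke_closed_form(a_hat, p_t, 0.5)
    np.testing.assert_allclose(q, m @ p_t, atol=1e-12)


@pytest.mark.parametrize("t_tokens", [4, 64])
def test_closed_form_equals_iterative_limit(t_tokens, rng):
    p_t = rng.normal(size=(2, t_tokens, 3))
    p_s = rng.normal(size=(2, t_tokens, 3))
    a_hat = bke_affinity(p_t, p_s)
    q_inf = bke_closed_form(a_hat, p_t, 0.5)
    q_60 = bke_iterate(a_hat, p_t, 0.5, 60)
    assert np.max(np.abs(q_60 - q_inf)) < 1e-6


def test_propagation_matrix_is_convex_combination(rng):
    p_t = rng.normal(size=(3, 8, 4))
    a_hat = bke_affinity(p_t, rng.normal(size=(3, 8, 4)))
    for omega in (0.0, 0.3, 0.5, 0.9):
        m = propagation_matrix(a_hat, omega)
        assert np.all(m >= -1e-12)
        np.testing.assert_allclose(m.sum(axis=-1), 1.0, atol=1e-8)


def test_closed_form_omega_zero_is_identity(rng):
    p_t = rng.normal(size=(1, 5, 2))
    a_hat = bke_affinity(p_t, rng.normal(size=(1, 5, 2)))
    np.testing.assert_allclose(bke_closed_form(a_hat, p_t, 0.0), p_t, atol=1e-12)


def test_omega_out_of_range_rejected(rng):
    p_t = rng.normal(size=(1, 4, 2))
    a_hat = bke_affinity(p_t, p_t)
    with pytest.raises(ConfigurationError):
        bke_closed_form(a_hat, p_t, 1.0)
    with pytest.raises(ConfigurationError):
        FDConfig(omega=1.0)


# -- combined loss -------------------------------------------------------------

def test_fd_loss_zero_when_student_equals_teacher(rng):
    p = rng.normal(size=(2, 6, 4))
    assert fd_loss(p, p.copy(), FDConfig(mode="mse")) == pytest.approx(0.0, abs=1e-12)
    assert fd_loss(p, p.copy(), FDConfig(mode="wkd")) == pytest.approx(0.0, abs=1e-12)


def test_fd_loss_wkd_bke_nonnegative_and_mixing(rng):
    p = rng.normal(size=(2, 6, 4))
    val = fd_loss(p, p.copy(), FDConfig(mode="wkd_bke", omega=0.5))
    assert val >= 0
    # propagation mixes tokens, so the ensembled teacher differs from P_T
    a_hat = bke_affinity(p, p)
    q = bke_closed_form(a_hat, p, 0.5)
    assert not np.allclose(q, p)


def test_fd_loss_unknown_mode():
    with pytest.raises(ConfigurationError):
        FDConfig(mode="nonsense")


def test_fd_loss_shape_mismatch(rng):
    with pytest.raises(ShapeError):
        fd_loss(rng.normal(size=(2, 4, 3)), rng.normal(size=(2, 5, 3)), FDConfig())


@pytest.mark.parametrize("mode", ["mse", "wkd", "bke_mse", "wkd_bke"])
def test_fd_loss_differentiable_wrt_student(mode, rng):
    """Finite-difference gradient check through every distillation mode.

    Teacher quantities (P_T, Â, Q_T) are constants of the iteration, so the
    finite-difference oracle perturbs the student while holding the ensembled
    teacher fixed — matching the loss's semantics where the gradient flows
    into the student features only.
    """
    p_t = rng.normal(size=(2, 3, 4))
    s0 = rng.normal(size=(2, 3, 4))
    cfg = FDConfig(mode=mode, gamma=2.0, omega=0.5)

    student = Tensor(s0.copy(), requires_grad=True)
    out = fd_loss(p_t, student, cfg)
    out.backward()
    assert student.grad is not None

    if mode in ("bke_mse", "wkd_bke"):
        teacher_const = bke_closed_form(bke_affinity(p_t, s0), p_t, cfg.omega)
    else:
        teacher_const = p_t

    def value(arr):
        if mode in ("mse", "bke_mse"):
            return float(np.mean((arr - teacher_const) ** 2))
        v = wkd_loss(compute_stats(teacher_const), compute_stats(arr), cfg.gamma)
        return v

    for i in (0, 7, 20):
        eps = 1e-6
        up, dn = s0.copy(), s0.copy()
        up.flat[i] += eps
        dn.flat[i] -= eps
        num = (value(up) - value(dn)) / (2 * eps)
        assert student.grad.flat[i] == pytest.approx(num, abs=1e-4)
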