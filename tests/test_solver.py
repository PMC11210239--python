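"""Solver unit tests: initialization, updates, objective, full component fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrspls.hypergraph import build_knn_hypergraph
from hrspls.io import standardize_columns
from hrspls.solver import (
    DegenerateComponentError,
    SolverConfig,
    fit_component,
    objective,
    pls_initialize,
    soft_threshold,
    update_d,
    update_g,
)


# ---------------------------------------------------------------- soft threshold

@pytest.mark.parametrize(
    "z,lam,expected",
    [(0.3, 0.5, 0.0), (-2.0, 0.5, -1.5), (1.7, 0.0, 1.7), (-0.2, 0.2, 0.0)],
)
def test_soft_threshold_values(z, lam, expected):
    assert soft_threshold(z, lam) == pytest.approx(expected)


@given(st.floats(-1e6, 1e6), st.floats(0, 1e6))
@settings(max_examples=50, deadline=None)
def test_soft_threshold_shrinks_toward_zero(z, lam):
    out = soft_threshold(z, lam)
    assert abs(out) <= abs(z)
    assert out * z >= 0  # sign preserved or zero


def test_soft_threshold_rejects_negative_lambda():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)


# ---------------------------------------------------------------- initialization

def test_pls_initialize_rank_one_fixed_point(rng):
    u0 = rng.standard_normal(8)
    a = rng.standard_normal(5)
    b = rng.standard_normal(4)
    X = np.outer(u0, a)
    Y = np.outer(u0, b)
    g, d, u, v = pls_initialize(X, Y, seed=0)
    assert abs(g @ (a / np.linalg.norm(a))) >= 0.9999
    assert abs(d @ (b / np.linalg.norm(b))) >= 0.9999


def test_pls_initialize_matches_leading_singular_pair(rng):
    X = rng.standard_normal((6, 4))
    Y = rng.standard_normal((6, 3))
    g, d, u, v = pls_initialize(X, Y, seed=1)
    U, _, Vt = np.linalg.svd(X.T @ Y)
    assert abs(g @ U[:, 0]) >= 0.999
    assert abs(d @ Vt[0]) >= 0.999
    assert np.linalg.norm(g) == pytest.approx(1.0)
    assert np.linalg.norm(d) == pytest.approx(1.0)
    assert np.allclose(u, X @ g)
    assert np.allclose(v, Y @ d)


def test_pls_initialize_all_degenerate_raises():
    X = np.zeros((5, 3))
    Y = np.zeros((5, 2))
    with pytest.raises(ValueError, match="degenerate"):
        pls_initialize(X, Y, seed=0)


# ---------------------------------------------------------------- block updates

def test_update_g_hand_example():
    # crafted so t_g = (1/p) X^T Y d = (1.0, 0.1); beta=0, lambda=0.4,
    # delta=0.5 gives pre-normalization (0.6, 0) and unit-norm (1, 0)
    X = np.zeros((3, 2))
    X[0] = [2.0, 0.2]
    Y = np.zeros((3, 1))
    Y[0, 0] = 1.0
    d = np.array([1.0])
    cfg = SolverConfig(lambda1=0.4, beta1=0.0, gamma1=0.0, delta1=0.5)
    g = update_g(X, Y, d, np.array([0.7, 0.7]), None, cfg)
    assert np.allclose(g, [1.0, 0.0])


def test_update_full_shrinkage_returns_zero(small_blocks):
    X, Y = small_blocks
    cfg = SolverConfig(lambda1=1e6, beta1=0.0)
    g = update_g(X, Y, np.ones(Y.shape[1]) / np.sqrt(Y.shape[1]),
                 np.ones(X.shape[1]) / np.sqrt(X.shape[1]), None, cfg)
    assert not g.any()


def test_update_penalty_free_limit_is_pls_step(small_blocks):
    X, Y = small_blocks
    d = np.ones(Y.shape[1]) / np.sqrt(Y.shape[1])
    cfg = SolverConfig(lambda1=0.0, beta1=0.0, gamma1=0.0, delta1=0.5)
    g = update_g(X, Y, d, np.zeros(X.shape[1]), None, cfg)
    direction = X.T @ (Y @ d)
    assert abs(g @ (direction / np.linalg.norm(direction))) == pytest.approx(1.0)


def test_update_d_mirrors_update_g():
    Y = np.zeros((3, 2))
    Y[0] = [2.0, 0.2]
    X = np.zeros((3, 1))
    X[0, 0] = 1.0
    g = np.array([1.0])
    # cov_scale is 1/p with p = X's width = 1, so t_d = Y^T u = (2, 0.2);
    # lambda=0.8 delta=0.5 -> pre-normalization (1.2, 0) -> (1, 0)
    cfg = SolverConfig(lambda2=0.8, beta2=0.0, gamma2=0.0, delta2=0.5)
    d = update_d(X, Y, g, np.array([0.7, 0.7]), None, cfg)
    assert np.allclose(d, [1.0, 0.0])


# ---------------------------------------------------------------- objective

def test_objective_zero_weights_vanish(small_blocks):
    X, Y = small_blocks
    cfg = SolverConfig()
    h1 = build_knn_hypergraph(X.T, 2)
    h2 = build_knn_hypergraph(Y.T, 2)
    assert objective(X, Y, np.zeros(X.shape[1]), np.zeros(Y.shape[1]), h1, h2, cfg) == 0.0


def test_objective_reduces_to_spls_without_graph(small_blocks, rng):
    X, Y = small_blocks
    g = rng.standard_normal(X.shape[1])
    g /= np.linalg.norm(g)
    d = rng.standard_normal(Y.shape[1])
    d /= np.linalg.norm(d)
    cfg = SolverConfig(lambda1=0.3, lambda2=0.2, beta1=0.0, beta2=0.0)
    expected = (
        -(1 / X.shape[1]) * g @ X.T @ Y @ d
        + 0.3 * np.abs(g).sum()
        + 0.2 * np.abs(d).sum()
    )
    assert objective(X, Y, g, d, None, None, cfg) == pytest.approx(expected, abs=1e-12)


def _pairwise_graph_penalty(S, Dv, w):
    """Independent oracle: explicit normalized pairwise sum over i < j."""
    n = len(w)
    li = np.sqrt(Dv)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += S[i, j] * (w[i] / li[i] - w[j] / li[j]) ** 2
    return total


def test_graph_term_matches_pairwise_oracle(rng):
    X, _ = standardize_columns(rng.standard_normal((5, 4)))
    Y, _ = standardize_columns(rng.standard_normal((5, 3)))
    h1 = build_knn_hypergraph(X.T, 2)
    h2 = build_knn_hypergraph(Y.T, 2)
    g = rng.standard_normal(4)
    g /= np.linalg.norm(g)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    cfg = SolverConfig(lambda1=0.0, lambda2=0.0, beta1=0.7, beta2=0.4)
    got = objective(X, Y, g, d, h1, h2, cfg)
    expected = (
        -(1 / 4) * g @ X.T @ Y @ d
        + 0.7 * _pairwise_graph_penalty(h1.similarity, h1.vertex_degrees, g)
        + 0.4 * _pairwise_graph_penalty(h2.similarity, h2.vertex_degrees, d)
    )
    assert got == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------- full fit

def test_fit_component_pls_limit_matches_svd(rng):
    X, _ = standardize_columns(rng.standard_normal((20, 30)))
    Y, _ = standardize_columns(rng.standard_normal((20, 25)))
    cfg = SolverConfig(lambda1=1e-6, lambda2=1e-6, beta1=0.0, beta2=0.0,
                       tol=1e-10, max_iter=500)
    fit = fit_component(X, Y, None, None, cfg)
    U, _, Vt = np.linalg.svd(X.T @ Y)
    assert abs(fit.g @ U[:, 0]) >= 0.999
    assert abs(fit.d @ Vt[0]) >= 0.999
    assert np.allclose(fit.u, X @ fit.g)
    assert np.allclose(fit.v, Y @ fit.d)


def test_fit_component_trace_non_increasing(small_blocks):
    X, Y = small_blocks
    h1 = build_knn_hypergraph(X.T, 2)
    h2 = build_knn_hypergraph(Y.T, 2)
    for seed in range(10):
        cfg = SolverConfig(lambda1=0.1, lambda2=0.1, beta1=0.5, beta2=0.5, seed=seed)
        fit = fit_component(X, Y, h1, h2, cfg)
        assert (np.diff(fit.objective_trace) <= 1e-8).all()


def test_fit_component_degenerate_raises(small_blocks):
    X, Y = small_blocks
    cfg = SolverConfig(lambda1=1e6, lambda2=1e6, beta1=0.0, beta2=0.0)
    with pytest.raises(DegenerateComponentError, match="decrease lambda"):
        fit_component(X, Y, None, None, cfg)


def test_sign_invariance_of_pcc_and_objective(small_blocks):
    # the objective and |PCC(u, v)| are invariant under joint negation of
    # (g, u) and (d, v); different seeds may flip signs but not quality
    X, Y = small_blocks
    cfg = SolverConfig(lambda1=0.1, lambda2=0.1, beta1=0.0, beta2=0.0, seed=0)
    fit = fit_component(X, Y, None, None, cfg)
    negated = objective(X, Y, -fit.g, -fit.d, None, None, cfg)
    assert negated == pytest.approx(fit.objective_trace[-1], abs=1e-12)
    pcc = np.corrcoef(fit.u, fit.v)[0, 1]
    pcc_neg = np.corrcoef(-fit.u, -fit.v)[0, 1]
    assert abs(pcc) == pytest.approx(abs(pcc_neg))


def test_sparsity_monotone_in_lambda(planted_blocks):
    X, Y, _ = planted_blocks
    h1 = build_knn_hypergraph(X.T, 2)
    h2 = build_knn_hypergraph(Y.T, 2)
    nnz = []
    for lam in (0.01, 0.05, 0.1, 0.5, 1.0):
        cfg = SolverConfig(lambda1=lam, lambda2=0.1, beta1=0.1, beta2=0.1, seed=3)
        try:
            fit = fit_component(X, Y, h1, h2, cfg)
            nnz.append(int(np.count_nonzero(fit.g)))
        except DegenerateComponentError:
            nnz.append(0)
    assert all(a >= b for a, b in zip(nnz, nnz[1:])), nnz


def test_scale_invariance_after_standardization(rng):
    # affine rescaling of raw columns does not change the standardized fit
    raw_X = rng.standard_normal((15, 6))
    raw_Y = rng.standard_normal((15, 5))
    scales_x = rng.uniform(0.1, 10, 6)
    X1, _ = standardize_columns(raw_X)
    X2, _ = standardize_columns(raw_X * scales_x + 3.0)
    Y1, _ = standardize_columns(raw_Y)
    cfg = SolverConfig(lambda1=0.1, lambda2=0.1, beta1=0.0, beta2=0.0, seed=2)
    f1 = fit_component(X1, Y1, None, None, cfg)
    f2 = fit_component(X2, Y1, None, None, cfg)
    assert np.allclose(f1.g, f2.g, atol=1e-10)


def test_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(lambda1=-0.1)
    with pytest.raises(ValueError):
        SolverConfig(delta1=0.0)
    with pytest.raises(ValueError):
        SolverConfig(cov_scale="bogus")
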