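"""Alternating coordinate-descent solver for one HR-SPLS component.

The model couples two column-standardized blocks X (n x p) and Y (n x q)
through unit-norm weight vectors g, d maximizing cov(Xg, Yd), penalized by
l1 sparsity on g and d and by the hypergraph Laplacian quadratic forms
g^T L1 g and d^T L2 d.  In minimization form the objective is

    f(g, d) = -c g^T X^T Y d
              + beta1 g^T L1 g + beta2 d^T L2 d
              + lambda1 ||g||_1 + lambda2 ||d||_1
              + gamma1 ||g||_2^2 + gamma2 ||d||_2^2,     ||g|| = ||d|| = 1,

with c the covariance scale (1/p by default).  Setting beta = gamma = 0
recovers sparse PLS; additionally lambda -> 0 recovers plain PLS, whose
solution is the leading singular pair of X^T Y.

Each block update is one Gauss-Seidel sweep of soft-threshold coordinate
updates followed by projection back to the unit sphere; a fixed point of
that sweep satisfies the KKT conditions of the sphere-constrained problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .hypergraph import Hypergraph

__all__ = [
    "SolverConfig",
    "ComponentFit",
    "DegenerateComponentError",
    "soft_threshold",
    "pls_initialize",
    "update_g",
    "update_d",
    "objective",
    "fit_component",
]


class DegenerateComponentError(RuntimeError):
    """Both weight vectors were shrunk entirely to zero."""


@dataclass
class SolverConfig:
    """All tuning constants of the solver and the downstream pipeline.

    Penalties: ``lambda1/2`` (l1), ``beta1/2`` (hypergraph), ``gamma1/2``
    (l2, elastic-net variant, default off).  ``delta1/2`` are the positive
    stabilizers in the coordinate-update denominator; any positive value
    only rescales the pre-normalization coordinates because the sweep ends
    with projection to unit norm.  ``cov_scale`` selects the covariance
    normalizer c: ``"p"`` (1/p, the default) or ``"n"`` (1/n).

    ``n_restarts`` controls multi-start for the non-convex objective: the
    first start is the PLS warm start, additional starts are seeded random
    unit vectors; the run with the lowest final objective wins.
    """

    lambda1: float = 0.5
    lambda2: float = 0.5
    beta1: float = 0.5
    beta2: float = 0.5
    gamma1: float = 0.0
    gamma2: float = 0.0
    delta1: float = 1.0
    delta2: float = 1.0
    cov_scale: str = "p"
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    threshold: float = 1.0
    n_modules: int = 20
    knn_k: int = 2
    n_restarts: int = 1
    one_sided: bool = False
    sample_rule: str = "zscore"  # or "raw": threshold (u*+v*) without z-scoring
    error_scale: str = "printed"  # (p/n, p/n) as printed, or "symmetric" (p/n, q/n)
    literal_printed_coupling: bool = False  # use lambda, not beta, in z_g/z_d
    rebuild_laplacians: bool = False

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "beta1", "beta2", "gamma1", "gamma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta1 <= 0 or self.delta2 <= 0:
            raise ValueError("delta1, delta2 must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1 or self.n_modules < 1 or self.n_restarts < 1:
            raise ValueError("max_iter, n_modules and n_restarts must be >= 1")
        if self.cov_scale not in ("p", "n"):
            raise ValueError("cov_scale must be 'p' or '1/n' alias 'n'")
        if self.sample_rule not in ("zscore", "raw"):
            raise ValueError("sample_rule must be 'zscore' or 'raw'")
        if self.error_scale not in ("printed", "symmetric"):
            raise ValueError("error_scale must be 'printed' or 'symmetric'")

    def replace(self, **kw) -> "SolverConfig":
        return replace(self, **kw)

    def cov_constant(self, n: int, p: int) -> float:
        return 1.0 / p if self.cov_scale == "p" else 1.0 / n


@dataclass
class ComponentFit:
    """One extracted component: weights, latent scores, loadings, trace."""

    g: np.ndarray
    d: np.ndarray
    u: np.ndarray
    v: np.ndarray
    x_loading: np.ndarray
    y_loading: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def degenerate(self) -> bool:
        return not (np.any(self.g) and np.any(self.d))


def soft_threshold(z, lam):
    """Proximal operator of the l1 norm: sign(z) * max(|z| - lam, 0)."""
    if np.any(np.asarray(lam) < 0):
        raise ValueError("threshold must be >= 0")
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def _unit(x: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(x)
    return x / nrm if nrm > 0 else x


def pls_initialize(
    X: np.ndarray, Y: np.ndarray, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unpenalized PLS power iteration used as the solver's warm start.

    Starts from a randomly selected column of Y as v, then repeats
    ``g := X^T v / v^T v`` (normalized), ``u := Xg``,
    ``d := Y^T u / u^T u`` (normalized), ``v := Yd``
    until the direction change drops below 1e-8 or 500 sweeps.  Converges
    to the leading singular pair of X^T Y.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the sample dimension")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = Y.shape[1]
    cols = rng.permutation(q)
    for start_col in cols:
        v = Y[:, start_col].astype(float).copy()
        if v @ v == 0:
            continue
        g = d = None
        for _ in range(500):
            g_new = _unit(X.T @ v / (v @ v))
            u = X @ g_new
            if u @ u == 0:
                break
            d_new = _unit(Y.T @ u / (u @ u))
            v = Y @ d_new
            if v @ v == 0:
                break
            if (
                g is not None
                and np.max(np.abs(g_new - g)) < 1e-8
                and np.max(np.abs(d_new - d)) < 1e-8
            ):
                g, d = g_new, d_new
                break
            g, d = g_new, d_new
        if g is not None and (X @ g) @ (X @ g) > 0 and (Y @ d) @ (Y @ d) > 0:
            return g, d, X @ g, Y @ d
    raise ValueError("all columns of Y give degenerate latent scores")


def _sweep(
    t: np.ndarray,
    w: np.ndarray,
    S_norm: np.ndarray | None,
    lam: float,
    beta: float,
    gamma: float,
    delta: float,
    coupling: float,
    mm_shift: float = 0.0,
) -> np.ndarray:
    """One full coordinate sweep followed by unit-norm projection.

    ``z_j = t_j + 2 * coupling * sum_i S_norm[i, j] * w_i`` evaluated at
    the incoming block vector for every coordinate (ascending order), then
    ``w_j = soft(z_j, lam) / (2 (beta + gamma + delta))`` and projection
    to the unit sphere.

    Evaluating every ``z_j`` at the same incoming ``w`` makes the sweep an
    exact majorize-minimize step of the sphere-constrained block problem
    whenever the Laplacian spectrum is bounded by 1 (true for the
    hypergraph Laplacian, whose normalized similarity is PSD): the sweep
    minimizes the linear-plus-l1 majorizer exactly, so the block objective
    cannot increase.  ``mm_shift`` = max(0, lambda_max(L) - 1) extends the
    guarantee to graphs with larger curvature (the simple-graph Laplacian
    of the SNPLS baseline, bounded by 2).
    """
    denom = 2.0 * (beta + gamma + delta)
    if S_norm is None or coupling == 0.0:
        z = t
    else:
        z = t + 2.0 * coupling * (S_norm @ w + mm_shift * w)
    if not np.all(np.isfinite(z)):
        bad = int(np.flatnonzero(~np.isfinite(z))[0])
        raise FloatingPointError(f"non-finite coordinate update at index {bad}")
    w = soft_threshold(z, lam) / denom
    nrm = np.linalg.norm(w)
    return w / nrm if nrm > 0 else w


def update_g(
    X: np.ndarray,
    Y: np.ndarray,
    d: np.ndarray,
    g: np.ndarray,
    hg1: Hypergraph | None,
    cfg: SolverConfig,
) -> np.ndarray:
    """One coordinate sweep of g with d fixed; returns the new unit-norm g."""
    c = cfg.cov_constant(X.shape[0], X.shape[1])
    t = c * (X.T @ (Y @ d))
    coupling = cfg.lambda1 if cfg.literal_printed_coupling else cfg.beta1
    S = hg1.normalized_similarity if hg1 is not None else None
    shift = getattr(hg1, "mm_shift", 0.0) if hg1 is not None else 0.0
    return _sweep(t, np.asarray(g, float), S, cfg.lambda1, cfg.beta1, cfg.gamma1, cfg.delta1, coupling, shift)


def update_d(
    X: np.ndarray,
    Y: np.ndarray,
    g: np.ndarray,
    d: np.ndarray,
    hg2: Hypergraph | None,
    cfg: SolverConfig,
) -> np.ndarray:
    """One coordinate sweep of d with g fixed; mirrors :func:`update_g`."""
    c = cfg.cov_constant(X.shape[0], X.shape[1])
    t = c * (Y.T @ (X @ g))
    coupling = cfg.lambda2 if cfg.literal_printed_coupling else cfg.beta2
    S = hg2.normalized_similarity if hg2 is not None else None
    shift = getattr(hg2, "mm_shift", 0.0) if hg2 is not None else 0.0
    return _sweep(t, np.asarray(d, float), S, cfg.lambda2, cfg.beta2, cfg.gamma2, cfg.delta2, coupling, shift)


def objective(
    X: np.ndarray,
    Y: np.ndarray,
    g: np.ndarray,
    d: np.ndarray,
    hg1: Hypergraph | None,
    hg2: Hypergraph | None,
    cfg: SolverConfig,
) -> float:
    """Minimization-form objective f(g, d); see the module docstring.

    The graph penalties are evaluated through the Laplacian quadratic form
    ``g^T L g``, which equals the normalized pairwise sum
    ``sum_{i<j} S_ij (g_i / sqrt(Dv_i) - g_j / sqrt(Dv_j))^2`` exactly.
    """
    g = np.asarray(g, float)
    d = np.asarray(d, float)
    c = cfg.cov_constant(X.shape[0], X.shape[1])
    val = -c * (g @ (X.T @ (Y @ d)))
    if hg1 is not None and cfg.beta1:
        val += cfg.beta1 * (g @ (hg1.laplacian @ g))
    if hg2 is not None and cfg.beta2:
        val += cfg.beta2 * (d @ (hg2.laplacian @ d))
    val += cfg.lambda1 * np.abs(g).sum() + cfg.lambda2 * np.abs(d).sum()
    val += cfg.gamma1 * (g @ g) + cfg.gamma2 * (d @ d)
    return float(val)


def _backtrack(w_old, w_cand, eval_obj, obj_old):
    """Shrink the step toward ``w_cand`` on the sphere until the objective
    no longer increases; returns (w, obj, improved)."""
    tau = 1.0
    for _ in range(12):
        w = w_old + tau * (w_cand - w_old)
        nrm = np.linalg.norm(w)
        w = w / nrm if nrm > 0 else w
        obj = eval_obj(w)
        if obj <= obj_old:
            return w, obj, obj < obj_old
        tau *= 0.5
    return w_old, obj_old, False


def _alternate(X, Y, g, d, hg1, hg2, cfg):
    obj = objective(X, Y, g, d, hg1, hg2, cfg)
    trace = [obj]
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        improved = False
        g_cand = update_g(X, Y, d, g, hg1, cfg)
        if not np.any(g_cand):  # full shrinkage: accept only if it helps
            cand_obj = objective(X, Y, g_cand, d, hg1, hg2, cfg)
            if cand_obj <= obj:
                g, obj, improved = g_cand, cand_obj, improved or cand_obj < obj
        else:
            g, obj, step = _backtrack(
                g, g_cand, lambda w: objective(X, Y, w, d, hg1, hg2, cfg), obj
            )
            improved = improved or step
        d_cand = update_d(X, Y, g, d, hg2, cfg)
        if not np.any(d_cand):
            cand_obj = objective(X, Y, g, d_cand, hg1, hg2, cfg)
            if cand_obj <= obj:
                d, obj, improved = d_cand, cand_obj, improved or cand_obj < obj
        else:
            d, obj, step = _backtrack(
                d, d_cand, lambda w: objective(X, Y, g, w, hg1, hg2, cfg), obj
            )
            improved = improved or step
        trace.append(obj)
        if not (np.any(g) or np.any(d)):
            break
        if not improved or abs(trace[-2] - obj) / (abs(obj) + 1e-12) < cfg.tol:
            converged = True
            break
    return g, d, trace, converged, n_iter


def fit_component(
    X: np.ndarray,
    Y: np.ndarray,
    hg1: Hypergraph | None,
    hg2: Hypergraph | None,
    cfg: SolverConfig,
    seed: int | np.random.Generator | None = None,
) -> ComponentFit:
    """Fit one component by alternating g / d sweeps from a PLS warm start.

    Stops when the relative objective change falls below ``cfg.tol`` or
    after ``cfg.max_iter`` sweeps.  Each block sweep is monotone-guarded:
    a candidate update is kept as is when it lowers the objective, and is
    otherwise backtracked toward the current iterate along the sphere (the
    raw sweep is a fixed-point, not a descent-guaranteed, step because of
    the unit-norm projection); when neither block can improve, the
    iteration has converged.  The objective trace is therefore
    non-increasing by construction.

    With ``cfg.n_restarts > 1`` additional seeded random starts are run
    and the lowest final objective wins (the problem is non-convex; the
    PLS warm start is always the first candidate).  Raises
    :class:`DegenerateComponentError` if both g and d are fully shrunk to
    zero (the l1 penalties dominate every coordinate); a one-sided zero is
    returned with ``degenerate = True``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    rng_or_seed = cfg.seed if seed is None else seed
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    g0, d0, _, _ = pls_initialize(X, Y, rng)

    best: tuple[float, np.ndarray, np.ndarray, list, bool, int] | None = None
    for restart in range(cfg.n_restarts):
        if restart == 0:
            g, d = g0, d0
        else:
            g = _unit(rng.standard_normal(X.shape[1]))
            d = _unit(rng.standard_normal(Y.shape[1]))
        g, d, trace, converged, n_iter = _alternate(X, Y, g, d, hg1, hg2, cfg)
        # a feasible (nonzero) solution always beats a fully shrunk one;
        # among feasible runs the lowest final objective wins
        key = (not (np.any(g) and np.any(d)), trace[-1])
        if best is None or key < best[0]:
            best = (key, g, d, trace, converged, n_iter)
    assert best is not None
    _, g, d, trace, converged, n_iter = best

    if not (np.any(g) or np.any(d)):
        raise DegenerateComponentError(
            "both weight vectors shrunk to zero; decrease lambda1/lambda2"
        )
    if not converged:
        warnings.warn(
            f"component did not converge within {cfg.max_iter} sweeps", stacklevel=2
        )
    u = X @ g
    v = Y @ d
    uu = u @ u
    vv = v @ v
    x_loading = X.T @ u / uu if uu > 0 else np.zeros(X.shape[1])
    y_loading = Y.T @ v / vv if vv > 0 else np.zeros(Y.shape[1])
    return ComponentFit(
        g=g,
        d=d,
        u=u,
        v=v,
        x_loading=x_loading,
        y_loading=y_loading,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )
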