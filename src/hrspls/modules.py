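"""Co-module extraction: fit, Z-score membership, deflation, diagnostics.

A co-module is a triple (X-feature subset, Y-feature subset, sample
subset) supported by one fitted component.  Features enter a module when
the Z-score of their weight exceeds the threshold T (default 1); samples
enter when the z-scored sum of the l2-normalized latent scores u* + v*
exceeds T.  After each module the rank-one signal u p^T (resp. v q^T) is
deflated from the block, so successive latent scores are orthogonal and
the blocks telescope into rank-one terms plus a final residual.

Module quality is summarized by the Pearson correlation of (u, v) and the
module error, a weighted sum of squared reconstruction residuals of both
blocks.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypergraph import Hypergraph, build_knn_hypergraph
from .solver import (
    ComponentFit,
    DegenerateComponentError,
    SolverConfig,
    fit_component,
    objective,
)

__all__ = [
    "Module",
    "select_features",
    "select_samples",
    "deflate",
    "module_pcc",
    "module_error",
    "extract_modules",
    "grid_search",
    "modules_to_frames",
    "write_module_tables",
]

logger = logging.getLogger(__name__)

DEFAULT_PENALTY_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class Module:
    """One extracted co-module (1-based ``index``)."""

    index: int
    x_indices: np.ndarray
    x_zscores: np.ndarray
    y_indices: np.ndarray
    y_zscores: np.ndarray
    sample_indices: np.ndarray
    sample_scores: np.ndarray
    pcc: float
    module_error: float
    objective: float
    component: ComponentFit | None
    degenerate: bool = False
    x_ids: list = field(default_factory=list)
    y_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    @property
    def n_x_features(self) -> int:
        return len(self.x_indices)

    @property
    def n_y_features(self) -> int:
        return len(self.y_indices)

    @property
    def n_samples(self) -> int:
        return len(self.sample_indices)


def _zscore(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, float)
    sd = w.std(ddof=1)
    if sd == 0:
        return np.zeros_like(w)
    return (w - w.mean()) / sd


def select_features(weights: np.ndarray, T: float = 1.0, one_sided: bool = False):
    """Z-score a weight vector and return indices exceeding the threshold.

    Returns ``(indices, zscores)`` where ``zscores`` covers all features.
    A constant weight vector yields an empty selection with a warning.
    """
    if T <= 0:
        raise ValueError("threshold T must be > 0")
    weights = np.asarray(weights, float)
    if weights.size < 2:
        raise ValueError("need at least 2 weights")
    z = _zscore(weights)
    if not z.any():
        warnings.warn("constant weight vector: empty feature selection", stacklevel=2)
        return np.array([], dtype=int), z
    mask = (z > T) if one_sided else (np.abs(z) > T)
    return np.flatnonzero(mask), z


def select_samples(
    u: np.ndarray,
    v: np.ndarray,
    T: float = 1.0,
    one_sided: bool = False,
    rule: str = "zscore",
):
    """Select supporting samples from the combined normalized latent scores.

    ``u* = u / ||u||``, ``v* = v / ||v||``, ``s = u* + v*``; with
    ``rule="zscore"`` (default) s is z-scored and samples with |z| > T
    (z > T when one-sided) are selected; ``rule="raw"`` thresholds s
    directly.  Returns ``(indices, scores)`` with the per-sample score
    vector used for thresholding.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape or u.size < 2:
        raise ValueError("u and v must be equal-length vectors of length >= 2")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("zero latent score vector: empty sample selection", stacklevel=2)
        return np.array([], dtype=int), np.zeros_like(u)
    s = u / nu + v / nv
    if rule == "zscore":
        score = _zscore(s)
        if not score.any():
            warnings.warn("constant combined score: empty sample selection", stacklevel=2)
            return np.array([], dtype=int), score
    elif rule == "raw":
        score = s
    else:
        raise ValueError("rule must be 'zscore' or 'raw'")
    mask = (score > T) if one_sided else (np.abs(score) > T)
    return np.flatnonzero(mask), score


def deflate(X: np.ndarray, u: np.ndarray):
    """Remove the rank-one signal of u from X.

    ``loading = X^T u / (u^T u)``; the residual ``X - u loading^T`` is
    exactly orthogonal to u.  Returns ``(residual, loading)``.
    """
    u = np.asarray(u, float)
    uu = u @ u
    if uu == 0:
        raise ValueError("cannot deflate with a zero latent score vector")
    loading = X.T @ u / uu
    return X - np.outer(u, loading), loading


def module_pcc(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of the two latent score vectors, NaN if undefined."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if u.std() == 0 or v.std() == 0:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])


def module_error(
    X: np.ndarray,
    Y: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    x_loading: np.ndarray,
    y_loading: np.ndarray,
    scale_convention: str = "printed",
) -> float:
    """Weighted sum of squared reconstruction residuals of both blocks.

    ``printed`` weights both terms by p/n; ``symmetric`` uses (p/n, q/n).
    """
    n, p = X.shape
    q = Y.shape[1]
    rx = X - np.outer(u, x_loading)
    ry = Y - np.outer(v, y_loading)
    wx = p / n
    wy = p / n if scale_convention == "printed" else q / n
    return float(wx * (rx**2).sum() + wy * (ry**2).sum())


def _empty_module(index: int, n: int, p: int, q: int, obj: float = float("nan")) -> Module:
    return Module(
        index=index,
        x_indices=np.array([], dtype=int),
        x_zscores=np.zeros(p),
        y_indices=np.array([], dtype=int),
        y_zscores=np.zeros(q),
        sample_indices=np.array([], dtype=int),
        sample_scores=np.zeros(n),
        pcc=float("nan"),
        module_error=float("nan"),
        objective=obj,
        component=None,
        degenerate=True,
    )


def extract_modules(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: SolverConfig,
    hg1: Hypergraph | None = None,
    hg2: Hypergraph | None = None,
    x_ids: list | None = None,
    y_ids: list | None = None,
    sample_ids: list | None = None,
    n_modules: int | None = None,
) -> list[Module]:
    """Run the K-module pipeline on column-standardized X, Y.

    Fits a component, selects members by Z-score, computes PCC and module
    error, deflates both blocks by their latent scores, and repeats for
    ``cfg.n_modules`` (or ``n_modules``) rounds.  Hypergraphs are built
    from the original feature profiles once and reused for every module
    unless ``cfg.rebuild_laplacians`` is set.  Degenerate components yield
    empty modules and skip deflation; numerical rank collapse stops early.
    """
    X = np.asarray(X, float).copy()
    Y = np.asarray(Y, float).copy()
    n, p = X.shape
    q = Y.shape[1]
    K = cfg.n_modules if n_modules is None else n_modules
    if (cfg.beta1 > 0 or cfg.beta2 > 0) and hg1 is None:
        hg1 = build_knn_hypergraph(X.T, k=cfg.knn_k)
    if (cfg.beta1 > 0 or cfg.beta2 > 0) and hg2 is None:
        hg2 = build_knn_hypergraph(Y.T, k=cfg.knn_k)

    modules: list[Module] = []
    rng = np.random.default_rng(cfg.seed)
    for k in range(1, K + 1):
        if np.linalg.norm(X) < 1e-10 or np.linalg.norm(Y) < 1e-10:
            warnings.warn(
                f"data exhausted after {k - 1} modules (rank collapse); stopping early",
                stacklevel=2,
            )
            break
        h1, h2 = hg1, hg2
        if cfg.rebuild_laplacians and k > 1:
            if cfg.beta1 > 0:
                h1 = build_knn_hypergraph(X.T, k=cfg.knn_k)
            if cfg.beta2 > 0:
                h2 = build_knn_hypergraph(Y.T, k=cfg.knn_k)
        try:
            fit = fit_component(X, Y, h1, h2, cfg, seed=rng)
        except DegenerateComponentError:
            logger.info("module %d degenerate (full shrinkage); emitting empty module", k)
            modules.append(_empty_module(k, n, p, q))
            continue
        obj = fit.objective_trace[-1]
        if fit.degenerate:
            modules.append(_empty_module(k, n, p, q, obj=obj))
            continue

        xi, xz = select_features(fit.g, cfg.threshold, cfg.one_sided)
        yi, yz = select_features(fit.d, cfg.threshold, cfg.one_sided)
        si, ss = select_samples(fit.u, fit.v, cfg.threshold, cfg.one_sided, cfg.sample_rule)
        pcc = module_pcc(fit.u, fit.v)
        err = module_error(
            X, Y, fit.u, fit.v, fit.x_loading, fit.y_loading, cfg.error_scale
        )
        mod = Module(
            index=k,
            x_indices=xi,
            x_zscores=xz,
            y_indices=yi,
            y_zscores=yz,
            sample_indices=si,
            sample_scores=ss,
            pcc=pcc,
            module_error=err,
            objective=float(obj),
            component=fit,
            x_ids=[x_ids[i] for i in xi] if x_ids is not None else [],
            y_ids=[y_ids[i] for i in yi] if y_ids is not None else [],
            sample_ids=[sample_ids[i] for i in si] if sample_ids is not None else [],
        )
        modules.append(mod)
        logger.info(
            "module %d: |X|=%d |Y|=%d |samples|=%d pcc=%.4f error=%.4f",
            k, mod.n_x_features, mod.n_y_features, mod.n_samples, pcc, err,
        )
        X, _ = deflate(X, fit.u)
        Y, _ = deflate(Y, fit.v)
    return modules


def _mean_abs_pcc(modules: list[Module]) -> float:
    vals = [abs(m.pcc) for m in modules if not m.degenerate and np.isfinite(m.pcc)]
    return float(np.mean(vals)) if vals else float("nan")


def grid_search(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: SolverConfig,
    lambda1_grid=DEFAULT_PENALTY_GRID,
    lambda2_grid=DEFAULT_PENALTY_GRID,
    beta1_grid=DEFAULT_PENALTY_GRID,
    beta2_grid=DEFAULT_PENALTY_GRID,
    knn_k_grid=(2,),
    search_modules: int | None = None,
) -> tuple[SolverConfig, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by mean |PCC| over modules.

    Runs :func:`extract_modules` for every combination (optionally with a
    reduced module count ``search_modules`` for speed) and returns the best
    configuration plus the full score table.  Deterministic given
    ``cfg.seed``.
    """
    combos = list(
        itertools.product(knn_k_grid, lambda1_grid, lambda2_grid, beta1_grid, beta2_grid)
    )
    if not combos:
        raise ValueError("empty hyperparameter grid")
    rows = []
    hg_cache: dict[int, tuple[Hypergraph, Hypergraph]] = {}
    for knn_k, l1, l2, b1, b2 in combos:
        trial = cfg.replace(lambda1=l1, lambda2=l2, beta1=b1, beta2=b2, knn_k=knn_k)
        if knn_k not in hg_cache:
            hg_cache[knn_k] = (
                build_knn_hypergraph(np.asarray(X).T, k=knn_k),
                build_knn_hypergraph(np.asarray(Y).T, k=knn_k),
            )
        hg1, hg2 = hg_cache[knn_k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mods = extract_modules(
                X, Y, trial, hg1=hg1, hg2=hg2, n_modules=search_modules
            )
        rows.append(
            {
                "knn_k": knn_k,
                "lambda1": l1,
                "lambda2": l2,
                "beta1": b1,
                "beta2": b2,
                "mean_abs_pcc": _mean_abs_pcc(mods),
                "n_nondegenerate": sum(not m.degenerate for m in mods),
            }
        )
    table = pd.DataFrame(rows)
    if table["mean_abs_pcc"].isna().all():
        raise RuntimeError("every grid combination was degenerate; revise the grid")
    best = table["mean_abs_pcc"].idxmax()
    row = table.loc[best]
    best_cfg = cfg.replace(
        lambda1=float(row["lambda1"]),
        lambda2=float(row["lambda2"]),
        beta1=float(row["beta1"]),
        beta2=float(row["beta2"]),
        knn_k=int(row["knn_k"]),
    )
    return best_cfg, table


def modules_to_frames(modules: list[Module]):
    """Tidy DataFrames (features, samples, summary) for a module list."""
    feat_rows, samp_rows, summary_rows = [], [], []
    for m in modules:
        for omics, idx, zs, ids, comp_w in (
            ("X", m.x_indices, m.x_zscores, m.x_ids, m.component.g if m.component else None),
            ("Y", m.y_indices, m.y_zscores, m.y_ids, m.component.d if m.component else None),
        ):
            for pos, i in enumerate(idx):
                feat_rows.append(
                    {
                        "module_index": m.index,
                        "omics": omics,
                        "feature_id": ids[pos] if ids else str(i),
                        "weight": float(comp_w[i]) if comp_w is not None else float("nan"),
                        "z_score": float(zs[i]),
                    }
                )
        for pos, i in enumerate(m.sample_indices):
            samp_rows.append(
                {
                    "module_index": m.index,
                    "sample_id": m.sample_ids[pos] if m.sample_ids else str(i),
                    "combined_score": float(m.sample_scores[i]),
                }
            )
        summary_rows.append(
            {
                "module_index": m.index,
                "n_x_features": m.n_x_features,
                "n_y_features": m.n_y_features,
                "n_samples": m.n_samples,
                "pcc": m.pcc,
                "module_error": m.module_error,
                "objective": m.objective,
                "converged": bool(m.component.converged) if m.component else False,
            }
        )
    cols_f = ["module_index", "omics", "feature_id", "weight", "z_score"]
    cols_s = ["module_index", "sample_id", "combined_score"]
    return (
        pd.DataFrame(feat_rows, columns=cols_f),
        pd.DataFrame(samp_rows, columns=cols_s),
        pd.DataFrame(summary_rows),
    )


def write_module_tables(modules: list[Module], outdir) -> None:
    """Write modules.tsv, samples.tsv, summary.tsv into ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats, samps, summ = modules_to_frames(modules)
    feats.to_csv(outdir / "modules.tsv", sep="\t", index=False)
    samps.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    summ.to_csv(outdir / "summary.tsv", sep="\t", index=False)
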