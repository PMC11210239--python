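"""Baseline comparators realized through the same solver.

PLS, sparse PLS (SPLS) and network-regularized sparse PLS (SNPLS) are
nested restrictions of the hypergraph-regularized model:

* PLS: all penalties zero — the solver reduces to the power iteration on
  X^T Y and module 1 recovers its leading singular pair;
* SPLS: l1 penalties only (beta = gamma = 0);
* SNPLS: l1 penalties plus the symmetric-normalized Laplacian of the
  mutualized simple KNN graph instead of the hypergraph Laplacian;
* HR-SPLS: the full model.

The nesting is exact: running SPLS equals running HR-SPLS with beta = 0,
same seed, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypergraph import Hypergraph, build_knn_graph, build_knn_hypergraph
from .modules import Module, _mean_abs_pcc, extract_modules
from .solver import SolverConfig

__all__ = ["BaselineSpec", "make_baseline_spec", "fit_baseline", "compare_methods"]

_METHODS = ("PLS", "SPLS", "SNPLS", "HR-SPLS")


@dataclass
class BaselineSpec:
    """A named method = a solver configuration + a graph kind."""

    method: str
    config: SolverConfig
    graph_kind: str = "none"  # none | simple_knn | hypergraph

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        expected = {
            "PLS": "none",
            "SPLS": "none",
            "SNPLS": "simple_knn",
            "HR-SPLS": "hypergraph",
        }[self.method]
        if self.graph_kind != expected:
            raise ValueError(f"{self.method} requires graph_kind={expected!r}")
        c = self.config
        if self.method == "PLS" and any(
            (c.lambda1, c.lambda2, c.beta1, c.beta2, c.gamma1, c.gamma2)
        ):
            raise ValueError("PLS requires all penalties to be zero")
        if self.method in ("PLS", "SPLS") and (c.beta1 or c.beta2 or c.gamma1 or c.gamma2):
            raise ValueError(f"{self.method} requires beta = gamma = 0")


def make_baseline_spec(method: str, cfg: SolverConfig) -> BaselineSpec:
    """Restrict ``cfg`` to the given method's configuration."""
    if method == "PLS":
        c = cfg.replace(lambda1=0.0, lambda2=0.0, beta1=0.0, beta2=0.0, gamma1=0.0, gamma2=0.0)
        return BaselineSpec("PLS", c, "none")
    if method == "SPLS":
        return BaselineSpec("SPLS", cfg.replace(beta1=0.0, beta2=0.0, gamma1=0.0, gamma2=0.0), "none")
    if method == "SNPLS":
        return BaselineSpec("SNPLS", cfg, "simple_knn")
    if method == "HR-SPLS":
        return BaselineSpec("HR-SPLS", cfg, "hypergraph")
    raise ValueError(f"unknown method {method!r}")


def _graphs(X: np.ndarray, Y: np.ndarray, spec: BaselineSpec):
    k = spec.config.knn_k
    if spec.graph_kind == "none":
        return None, None
    if spec.graph_kind == "simple_knn":
        return build_knn_graph(X.T, k=k), build_knn_graph(Y.T, k=k)
    return build_knn_hypergraph(X.T, k=k), build_knn_hypergraph(Y.T, k=k)


def fit_baseline(
    X: np.ndarray,
    Y: np.ndarray,
    spec: BaselineSpec,
    n_modules: int | None = None,
    **ids,
) -> list[Module]:
    """Run the module pipeline under the baseline's restricted configuration."""
    hg1, hg2 = _graphs(np.asarray(X, float), np.asarray(Y, float), spec)
    return extract_modules(X, Y, spec.config, hg1=hg1, hg2=hg2, n_modules=n_modules, **ids)


def compare_methods(
    X: np.ndarray,
    Y: np.ndarray,
    specs: list[BaselineSpec],
    n_modules: int | None = None,
) -> tuple[pd.DataFrame, dict[str, list[Module]]]:
    """Per-method mean module error, mean |module correlation|, objective.

    The objective column is the sum of the final per-module objective
    values across non-degenerate modules.  Returns the comparison table
    plus the full module lists keyed by method.
    """
    if not specs:
        raise ValueError("need at least one BaselineSpec")
    rows = []
    all_modules: dict[str, list[Module]] = {}
    for spec in specs:
        mods = fit_baseline(X, Y, spec, n_modules=n_modules)
        all_modules[spec.method] = mods
        errors = [m.module_error for m in mods if not m.degenerate]
        objs = [m.objective for m in mods if np.isfinite(m.objective)]
        rows.append(
            {
                "method": spec.method,
                "mean_module_error": float(np.mean(errors)) if errors else float("nan"),
                "mean_module_correlation": _mean_abs_pcc(mods),
                "objective_value": float(np.sum(objs)) if objs else float("nan"),
            }
        )
    return pd.DataFrame(rows), all_modules
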