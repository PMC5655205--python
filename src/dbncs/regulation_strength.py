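"""Recursive optimization (RO): LAD + L1 regression as a linear program.

For a target gene y and candidate regulators X the regulation-intensity
vector beta minimizes

    sum_i |y_i - sum_j beta_j x_ji|  +  lambda * sum_j |beta_j|

which becomes a linear program by the standard positive/negative split
(u - v = residual, xi - eta = beta, all variables >= 0). The recursive part
zeroes every |beta_j| below a threshold theta0, re-solves restricted to the
survivors, and repeats until the survivor set is stable — removing
low-strength (redundant) regulations that noise alone supports.

``prune_skeleton`` applies this per target gene over its skeleton
neighbours (regulator activity = expression level), keeping an undirected
edge when either direction's fitted strength is non-zero; direction itself
is decided later by the comprehensive score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .io_formats import ExpressionMatrix
from .structure_learning import Skeleton

__all__ = ["ROConfig", "StrengthFit", "lad_lasso_lp", "recursive_optimize", "prune_skeleton"]


@dataclass
class ROConfig:
    """RO parameters.

    lam: sparsity weight lambda >= 0 (default 1.0, the convention of the
        recursive-optimization literature this stage follows).
    theta0: pruning threshold on |beta|; None means "inherit the skeleton
        independence threshold theta" (the pair-clique rule theta0 = theta),
        falling back to 0.15 when used standalone.
    max_refits: hard cap on threshold-and-refit rounds (termination
        guarantee on pathological data).
    """

    lam: float = 1.0
    theta0: float | None = None
    max_refits: int = 20

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.theta0 is not None and self.theta0 < 0:
            raise ValueError("theta0 must be >= 0")

    def resolved_theta0(self, fallback: float = 0.15) -> float:
        return fallback if self.theta0 is None else self.theta0


@dataclass
class StrengthFit:
    """Result of one RO run: signed strengths, LP objective, refit count."""

    beta: np.ndarray
    objective: float
    iterations: int


def lad_lasso_lp(y: np.ndarray, X: np.ndarray, lam: float) -> StrengthFit:
    """Solve the LAD + L1 problem exactly as a linear program.

    ``X`` is samples x regulators. Variables are ordered
    ``[u (m), v (m), xi (c), eta (c)]`` with equality constraints
    ``u - v + X(xi - eta) = y``; the optimum objective equals
    ``sum|residual| + lam * sum|beta|``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m, c = X.shape
    if y.size != m:
        raise ValueError(f"y has {y.size} samples, X has {m} rows")
    if m < 2 or c < 1:
        raise ValueError("need m >= 2 samples and c >= 1 regulators")
    cost = np.concatenate([np.ones(2 * m), np.full(2 * c, lam)])
    A_eq = np.hstack([np.eye(m), -np.eye(m), X, -X])
    res = linprog(cost, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs")
    if res.status != 0:
        raise RuntimeError(f"LP solver failed: status {res.status} ({res.message})")
    xi = res.x[2 * m : 2 * m + c]
    eta = res.x[2 * m + c :]
    return StrengthFit(beta=xi - eta, objective=float(res.fun), iterations=1)


def recursive_optimize(y: np.ndarray, X: np.ndarray, config: ROConfig) -> StrengthFit:
    """Threshold-and-refit loop around :func:`lad_lasso_lp`.

    Coordinates dropped along the way are exactly 0 in the returned beta.
    An all-zero result (every regulator pruned) is a valid outcome.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    theta0 = config.resolved_theta0()
    c = X.shape[1]
    active = np.arange(c)
    beta = np.zeros(c)
    objective = float(np.sum(np.abs(np.asarray(y, dtype=float))))
    iters = 0
    while active.size and iters < config.max_refits:
        fit = lad_lasso_lp(y, X[:, active], config.lam)
        iters += 1
        keep = np.abs(fit.beta) >= theta0
        beta = np.zeros(c)
        beta[active[keep]] = fit.beta[keep]
        objective = fit.objective
        if keep.all():
            break
        active = active[keep]
    else:
        if active.size:
            import warnings

            warnings.warn(f"recursive_optimize hit max_refits={config.max_refits}")
    if active.size == 0:
        beta = np.zeros(c)
    return StrengthFit(beta=beta, objective=objective, iterations=max(iters, 1))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def prune_skeleton(expr: ExpressionMatrix, skel: Skeleton, config: ROConfig) -> Skeleton:
    """Remove skeleton edges whose regulation strength vanishes both ways.

    For every gene g the target series is regressed on its skeleton
    neighbours (both z-scored, so theta0 is comparable across genes). The
    fitted |beta| is recorded per ordered (regulator, target) pair in the
    returned skeleton's ``beta`` matrix; an undirected edge survives when
    either direction is non-zero. Never adds edges.
    """
    n = expr.n_genes
    Z = np.vstack([_zscore(expr.values[i]) for i in range(n)])
    beta = np.zeros((n, n))  # beta[h, g]: strength of regulator h on target g
    for g in range(n):
        nbrs = [h for h in range(n) if skel.weight[g, h] > 0]
        if not nbrs:
            continue
        fit = recursive_optimize(Z[g], Z[nbrs].T, config)
        for h, b in zip(nbrs, fit.beta):
            beta[h, g] = b
    weight = skel.weight.copy()
    for i, j in skel.edges():
        if beta[i, j] == 0.0 and beta[j, i] == 0.0:
            weight[i, j] = weight[j, i] = 0.0
    return Skeleton(
        gene_ids=list(skel.gene_ids),
        weight=weight,
        order_reached=skel.order_reached,
        beta=np.abs(beta),
    )
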