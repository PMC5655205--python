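"""Transcriptional delay estimation and the transcriptional regulation score.

A target's response lags its regulator by an integer number of sampling
intervals. For a candidate delay m the two series are recombined as
``X^(m) = x[0 .. T-m-1]`` and ``Y^(m) = y[m .. T-1]`` and the Gaussian MI of
the aligned pair is computed; the delay maximizing MI (smallest m on ties)
is the transcription delay. Doing this in both directions over every
skeleton edge yields the (generally asymmetric) N x N delay matrix — the
transition network of the final dynamic Bayesian network.

TRS, the transcriptional regulation score, is a sign-consistency statistic
on the delay-aligned series: a step contributes when every regulator
changed at time t, with the sign of the target's change one step later;

    TRS = 1 - (1 / N_IC) * sum_t [prod_i f(dx_i,t)] * sign(dy_{t+1})

where f(k) = 1 for k != 0 else 0 and N_IC counts the steps at which the
*target* changes. The sum runs over the steps where all indices exist
(T - 2 of them); a zero target step contributes 0 and does not count toward
N_IC. TRS < 1 rewards co-ordinated regulator-then-target increases, and a
never-changing regulator leaves TRS at 1 (no dynamic evidence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .info_theory import DegenerateInputError, gaussian_mi
from .io_formats import ExpressionMatrix
from .structure_learning import Skeleton

__all__ = [
    "DelayMatrix",
    "TRSInput",
    "DegenerateTargetError",
    "recombine",
    "optimal_delay",
    "build_delay_matrix",
    "trs",
]


class DegenerateTargetError(ValueError):
    """The target series never changes over the scored window (N_IC = 0)."""


@dataclass
class DelayMatrix:
    """N x N integer transcription delays in sampling-interval units.

    ``delays[i, j]`` is the estimated delay for regulator i -> target j;
    entries for non-edges are 0, the diagonal is 0, and the matrix is in
    general asymmetric because the two directions are estimated separately.
    """

    delays: np.ndarray
    k_max: int

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=int)
        if self.delays.ndim != 2 or self.delays.shape[0] != self.delays.shape[1]:
            raise ValueError("delay matrix must be square")
        if np.any(np.diag(self.delays) != 0):
            raise ValueError("delay matrix diagonal must be 0")
        if self.delays.min() < 0 or self.delays.max() > self.k_max:
            raise ValueError(f"delays must lie in [0, {self.k_max}]")


@dataclass
class TRSInput:
    """Delay-aligned series entering the TRS statistic.

    regulator_series: (N_v, T') array (or list of equal-length vectors).
    target_series: length-T' vector aligned with the regulators.
    """

    regulator_series: np.ndarray
    target_series: np.ndarray

    def __post_init__(self) -> None:
        self.regulator_series = np.atleast_2d(np.asarray(self.regulator_series, dtype=float))
        self.target_series = np.asarray(self.target_series, dtype=float).ravel()
        if self.regulator_series.shape[1] != self.target_series.size:
            raise ValueError("regulator and target series must have equal length")
        if self.target_series.size < 3:
            raise ValueError("need at least 3 aligned time points")

    @property
    def n_regulators(self) -> int:
        return self.regulator_series.shape[0]


def recombine(x: np.ndarray, y: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Align regulator x against target y shifted by m sampling intervals.

    Returns ``(x[0:T-m], y[m:T])``, both of length T - m; element t of the
    first is simultaneous with element t + m of the original target.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    T = x.size
    if not 1 <= m <= T - 2:
        raise ValueError(f"delay m={m} outside [1, {T - 2}]")
    return x[: T - m], y[m:]


def optimal_delay(x: np.ndarray, y: np.ndarray, k: int) -> tuple[int, float]:
    """Delay in {1..k} maximizing the MI of the recombined pair.

    Ties break to the smallest delay (parsimony). Returns (m*, MI at m*).
    """
    x = np.asarray(x, dtype=float).ravel()
    T = x.size
    if k > T - 2:
        raise ValueError(f"max delay k={k} exceeds T-2={T - 2}")
    if k < 1:
        raise ValueError("k must be >= 1")
    best_m, best_mi = 0, -1.0
    for m in range(1, k + 1):
        xm, ym = recombine(x, y, m)
        mi = gaussian_mi(xm, ym)
        if mi > best_mi:
            best_m, best_mi = m, mi
    return best_m, best_mi


def build_delay_matrix(expr: ExpressionMatrix, skel: Skeleton, k: int) -> DelayMatrix:
    """Estimate both directed delays for every surviving skeleton edge.

    Degenerate pairs (constant sub-series) are left at delay 0 with a
    warning rather than aborting the run.
    """
    if not expr.time_ordered:
        raise ValueError("delay estimation requires time-ordered expression data")
    n = expr.n_genes
    delays = np.zeros((n, n), dtype=int)
    for i, j in skel.edges():
        for a, b in ((i, j), (j, i)):
            try:
                delays[a, b], _ = optimal_delay(expr.values[a], expr.values[b], k)
            except DegenerateInputError:
                warnings.warn(
                    f"degenerate series for delay {expr.gene_ids[a]}->{expr.gene_ids[b]}; left 0"
                )
    return DelayMatrix(delays=delays, k_max=k)


def trs(inp: TRSInput, change_eps: float = 0.0) -> float:
    """Transcriptional regulation score of delay-aligned series.

    ``change_eps`` lets small fluctuations count as "no change" on noisy
    real data (default 0: exact inequality). Raises
    :class:`DegenerateTargetError` when the target never changes within the
    scored window; callers substitute TRS = 0 with a warning in that case.
    """
    X = inp.regulator_series
    y = inp.target_series
    n = y.size
    dx = np.abs(np.diff(X, axis=1)) > change_eps  # (N_v, n-1)
    dy = np.diff(y)
    total = 0.0
    n_ic = 0
    for t in range(n - 2):  # needs dx at t and dy at t+1
        step = dy[t + 1]
        if abs(step) <= change_eps:
            continue
        n_ic += 1
        if dx[:, t].all():
            total += 1.0 if step > 0 else -1.0
    if n_ic == 0:
        raise DegenerateTargetError("target series never changes (N_IC = 0)")
    return 1.0 - total / n_ic
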