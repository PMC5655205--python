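"""Gaussian closed-form estimators of MI, CMI and CMI2.

All three statistics are computed through the Gaussian equivalents of their
definitional forms, so each reduces to determinants and traces of sample
correlation matrices:

* ``MI(X;Y) = -1/2 ln(1 - r^2)`` with ``r`` the Pearson correlation;
* ``CMI(X;Y|Z) = 1/2 ln(|C(X,Z)||C(Y,Z)| / (|C(Z)||C(X,Y,Z)|))``;
* ``CMI2(X;Y|Z)`` — conditional mutual *inclusive* information — augments
  CMI with two KL terms that measure how far the joint distribution is from
  the interventional distributions with the X->Y (resp. Y->X) edge removed:

  ``CMI2 = 1/2 [ KL(P || P_{X->Y}) + KL(P || P_{Y->X}) ]``

  where ``P_{X->Y}(x,y,z) = P(x,z) * q(y|z)`` and
  ``q(y|z) = ∫ P(y|x,z) P(x) dx``. For jointly Gaussian variables both
  interventional distributions are again Gaussian, so each KL term has a
  closed form in the joint covariance. CMI2 equals CMI plus two non-negative
  KL contributions, hence ``CMI2 >= CMI >= 0``, and it is symmetric in
  (X, Y). CMI keeps MI's ability to see direct dependence while the
  inclusive terms restore strength that conditioning alone underestimates.

Natural logarithms throughout (values in nats). Correlation matrices get a
ridge of 1e-8 on the diagonal before factorization; a constant input raises
:class:`DegenerateInputError` rather than silently returning 0, because a
silent zero would delete a true edge invisibly downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "DegenerateInputError",
    "CorrelationBlocks",
    "gaussian_mi",
    "gaussian_cmi",
    "gaussian_cmi2",
]

RIDGE = 1e-8


class DegenerateInputError(ValueError):
    """A sample vector is constant or a covariance block is singular."""


def _as_samples(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 3:
        raise ValueError(f"{name}: need at least 3 samples, got {v.size}")
    if np.ptp(v) == 0.0:
        raise DegenerateInputError(f"{name} is constant")
    return v


def _cond_matrix(z: np.ndarray | None, n: int) -> np.ndarray:
    """Coerce a conditioning set to shape (n_samples, nz); nz may be 0."""
    if z is None:
        return np.empty((n, 0))
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != n:
        raise ValueError(f"conditioning matrix has {z.shape[0]} rows, expected {n}")
    for j in range(z.shape[1]):
        if np.ptp(z[:, j]) == 0.0:
            raise DegenerateInputError(f"conditioning column {j} is constant")
    return z


@dataclass
class CorrelationBlocks:
    """Correlation/covariance structure of (x, y, z1..z_nz).

    Variable order is x (index 0), y (index 1), then the nz conditioners.
    ``n = nz + 2`` is the total dimension entering the CMI2 closed form.
    """

    rho: np.ndarray
    cov: np.ndarray
    nz: int

    @property
    def n(self) -> int:
        return self.nz + 2

    @classmethod
    def from_samples(cls, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> "CorrelationBlocks":
        data = np.column_stack([x, y, z])
        cov = np.cov(data, rowvar=False)
        cov = np.atleast_2d(cov)
        sd = np.sqrt(np.diag(cov))
        rho = cov / np.outer(sd, sd)
        np.fill_diagonal(rho, 1.0)
        return cls(rho=rho, cov=cov, nz=data.shape[1] - 2)


def _logdet(mat: np.ndarray) -> float:
    """log-determinant via Cholesky of the ridged matrix (stays in log space)."""
    if mat.size == 0:
        return 0.0
    m = mat + RIDGE * np.eye(mat.shape[0])
    try:
        chol = linalg.cholesky(m, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - ridge makes this rare
        raise DegenerateInputError("singular covariance block") from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information of two samples under the Gaussian assumption.

    Equals ``-1/2 ln(1 - r^2)`` where r is the sample Pearson correlation;
    symmetric and non-negative. ``|r| = 1`` is guarded by the ridge.
    """
    x = _as_samples(x, "x")
    y = _as_samples(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if y.tobytes() < x.tobytes():
        x, y = y, x  # canonical order: makes the symmetry bit-exact
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = min(r * r, 1.0 - RIDGE)
    return max(-0.5 * np.log1p(-r2), 0.0)


def gaussian_cmi(x: np.ndarray, y: np.ndarray, z: np.ndarray | None = None) -> float:
    """Conditional MI of x and y given the columns of z (possibly none).

    With an empty conditioning set this reduces exactly to
    :func:`gaussian_mi`. Computed from log-determinants of the sample
    correlation blocks; clamped at 0 against round-off.
    """
    x = _as_samples(x, "x")
    y = _as_samples(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    z = _cond_matrix(z, x.size)
    if z.shape[1] == 0:
        return gaussian_mi(x, y)
    blocks = CorrelationBlocks.from_samples(x, y, z)
    rho = blocks.rho
    zi = np.arange(2, blocks.n)
    xz = np.concatenate(([0], zi))
    yz = np.concatenate(([1], zi))
    val = 0.5 * (
        _logdet(rho[np.ix_(xz, xz)])
        + _logdet(rho[np.ix_(yz, yz)])
        - _logdet(rho[np.ix_(zi, zi)])
        - _logdet(rho)
    )
    return max(val, 0.0)


def _interventional_cov(S: np.ndarray, tgt: int, src: int, zi: np.ndarray) -> np.ndarray:
    """Covariance of P with the edge src->tgt removed.

    Under the edge-removed distribution the target is redistributed as
    ``q(tgt|z) = ∫ P(tgt|src,z) P(src) d src``: its regression on z keeps
    only the z coefficients of the joint (src, z) regression, while the
    variance absorbed by src moves into the conditional variance. The
    (src, z) block of the covariance is unchanged.
    """
    o = np.concatenate(([src], zi))  # predictors of the full regression
    b = linalg.solve(
        S[np.ix_(o, o)] + RIDGE * np.eye(o.size), S[o, tgt], assume_a="pos"
    )
    b_src, b_z = b[0], b[1:]
    s2 = S[tgt, tgt] - float(S[tgt, o] @ b)
    out = S.copy()
    Szz = S[np.ix_(zi, zi)]
    cov_tz = Szz @ b_z if zi.size else np.empty(0)
    out[tgt, zi] = cov_tz
    out[zi, tgt] = cov_tz
    out[tgt, src] = out[src, tgt] = float(b_z @ S[zi, src]) if zi.size else 0.0
    out[tgt, tgt] = s2 + b_src * b_src * S[src, src] + (
        float(b_z @ Szz @ b_z) if zi.size else 0.0
    )
    return out


def _gauss_kl(S0: np.ndarray, S1: np.ndarray) -> float:
    """KL(N(0,S0) || N(0,S1)) for equal means."""
    n = S0.shape[0]
    S1r = S1 + RIDGE * np.eye(n)
    tr = float(np.trace(linalg.solve(S1r, S0, assume_a="pos")))
    return 0.5 * (tr - n + _logdet(S1) - _logdet(S0))


def gaussian_cmi2(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Conditional mutual inclusive information of x and y given z (nz >= 1).

    Average of the two KL divergences from the joint Gaussian to the
    edge-removed interventional Gaussians; symmetric in (x, y) and bounded
    below by :func:`gaussian_cmi` up to round-off. For an empty conditioning
    set the pipeline uses :func:`gaussian_mi` instead.
    """
    x = _as_samples(x, "x")
    y = _as_samples(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    z = _cond_matrix(z, x.size)
    if z.shape[1] == 0:
        raise ValueError("gaussian_cmi2 requires nz >= 1; use gaussian_mi for nz = 0")
    if y.tobytes() < x.tobytes():
        x, y = y, x  # canonical order: makes the (x, y) symmetry bit-exact
    blocks = CorrelationBlocks.from_samples(x, y, z)
    S = blocks.rho  # correlation scale: MI-type quantities are affine-invariant
    zi = np.arange(2, blocks.n)
    kl_xy = _gauss_kl(S, _interventional_cov(S, tgt=1, src=0, zi=zi))
    kl_yx = _gauss_kl(S, _interventional_cov(S, tgt=0, src=1, zi=zi))
    return max(0.5 * (kl_xy + kl_yx), 0.0)
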