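"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: the inclusive-information
oracle evaluates the defining KL decomposition by Gauss-Hermite quadrature
(for the edge-removed conditional) plus Monte-Carlo averaging (for the outer
expectation), and the regression oracle evaluates the LAD + L1 objective on a
dense coefficient lattice.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def mc_cmi2(S: np.ndarray, n_draw: int = 20000, seed: int = 0, gh_nodes: int = 40):
    """Monte-Carlo estimate of the inclusive information of a Gaussian.

    For the joint N(0, S) over (x, y, z...), estimates
    ``E_P[ln p - 1/2 ln p_xy - 1/2 ln p_yx]`` where ``p_xy`` is the density
    with the x->y edge removed (x,z marginal times the x-marginalized
    conditional of y given z, the latter integrated by quadrature).
    Returns (estimate, standard error).
    """
    rng = np.random.default_rng(seed)
    n = S.shape[0]
    zi = list(range(2, n))
    draws = rng.standard_normal((n_draw, n)) @ np.linalg.cholesky(S).T
    nodes, wts = np.polynomial.hermite.hermgauss(gh_nodes)

    def log_q(tgt: int, src: int) -> np.ndarray:
        # q(tgt | z) = Int P(tgt | src, z) P(src) dsrc by Gauss-Hermite
        o = [src] + zi
        b = np.linalg.solve(S[np.ix_(o, o)], S[o, tgt])
        s2 = S[tgt, tgt] - S[tgt, o] @ b
        xs = nodes * np.sqrt(2.0 * S[src, src])
        ws = wts / np.sqrt(np.pi)
        zpart = draws[:, zi] @ b[1:] if zi else np.zeros(n_draw)
        mu = zpart[:, None] + b[0] * xs[None, :]
        dens = (
            ws[None, :]
            * np.exp(-((draws[:, tgt, None] - mu) ** 2) / (2.0 * s2))
            / np.sqrt(2.0 * np.pi * s2)
        ).sum(axis=1)
        return np.log(dens)

    def log_mvn(idxs: list[int]) -> np.ndarray:
        return multivariate_normal(
            mean=np.zeros(len(idxs)), cov=S[np.ix_(idxs, idxs)]
        ).logpdf(draws[:, idxs])

    lp = log_mvn(list(range(n)))
    l_xy = log_mvn([0] + zi) + log_q(tgt=1, src=0)
    l_yx = log_mvn([1] + zi) + log_q(tgt=0, src=1)
    vals = lp - 0.5 * l_xy - 0.5 * l_yx
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draw))


def random_spd_corr(rng: np.random.Generator, dim: int = 3) -> np.ndarray:
    """A random well-conditioned correlation matrix."""
    A = rng.standard_normal((dim, dim + 2))
    S = A @ A.T + dim * np.eye(dim)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def lad_lasso_grid(y: np.ndarray, X: np.ndarray, lam: float, step: float = 0.01, lim: float = 3.0):
    """Brute-force minimizer of the LAD + L1 objective on a 2-D lattice."""
    assert X.shape[1] == 2
    grid = np.arange(-lim, lim + step / 2, step)
    B1, B2 = np.meshgrid(grid, grid)
    resid = np.abs(
        y[:, None]
        - X[:, 0][:, None] * B1.ravel()[None, :]
        - X[:, 1][:, None] * B2.ravel()[None, :]
    ).sum(axis=0)
    obj = resid + lam * (np.abs(B1.ravel()) + np.abs(B2.ravel()))
    k = int(np.argmin(obj))
    return np.array([B1.ravel()[k], B2.ravel()[k]]), float(obj[k])
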