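"""2-Wasserstein distances between point clouds and diagonal Gaussians.

The variational prior term of the autoencoder measures how far each
latent sample cloud sits from a standard-normal cloud. The entropic
(Sinkhorn) solver below runs in the log domain, so it stays stable at the
small regularization strengths needed to approximate the exact optimal
matching; the exact value is available through the Hungarian algorithm
(`exact_w2`) and, for diagonal Gaussians, in closed form (`gaussian_w2`).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

__all__ = ["sinkhorn_w2", "sinkhorn_plan", "exact_w2", "gaussian_w2"]


def _sq_cost(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape[1] != Q.shape[1]:
        raise ValueError("point sets must share dimensionality")
    pn = (P**2).sum(axis=1)[:, None]
    qn = (Q**2).sum(axis=1)[None, :]
    C = pn + qn - 2.0 * P @ Q.T
    return np.maximum(C, 0.0)


def sinkhorn_plan(P: np.ndarray, Q: np.ndarray, epsilon: float,
                  iters: int = 1000, tol: float = 1e-10
                  ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Entropic optimal transport between uniform clouds P (n x d) and
    Q (m x d) with squared-Euclidean ground cost.

    Returns ``(plan, cost_matrix, converged)``. Log-domain iterations on
    the dual potentials keep the update stable for small epsilon.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    C = _sq_cost(P, Q)
    n, m = C.shape
    log_a = np.full(n, -np.log(n))
    log_b = np.full(m, -np.log(m))
    f = np.zeros(n)
    g = np.zeros(m)
    converged = False
    for _ in range(iters):
        f = epsilon * (log_a - logsumexp((-C + g[None, :]) / epsilon, axis=1))
        g_new = epsilon * (log_b - logsumexp((-C + f[:, None]) / epsilon, axis=0))
        if np.max(np.abs(g_new - g)) < tol:
            g = g_new
            converged = True
            break
        g = g_new
    plan = np.exp((-C + f[:, None] + g[None, :]) / epsilon)
    return plan, C, converged


def sinkhorn_w2(P: np.ndarray, Q: np.ndarray, epsilon: float = 0.005,
                iters: int = 1000, warn: bool = True) -> float:
    """Entropic approximation of the 2-Wasserstein distance between two
    equally weighted point clouds (square root of the transported squared
    cost under the Sinkhorn plan). Symmetric in its arguments; >= 0."""
    plan, C, converged = sinkhorn_plan(P, Q, epsilon, iters)
    if not converged and warn:
        warnings.warn(
            f"Sinkhorn did not reach tolerance within {iters} iterations",
            stacklevel=2,
        )
    return float(np.sqrt(max((plan * C).sum(), 0.0)))


def exact_w2(P: np.ndarray, Q: np.ndarray) -> float:
    """Exact 2-Wasserstein distance between two same-size uniform clouds:
    optimal transport between uniform discrete measures of equal size is a
    perfect matching, solved by the Hungarian algorithm."""
    C = _sq_cost(P, Q)
    if C.shape[0] != C.shape[1]:
        raise ValueError("exact matching requires equal-size point sets")
    r, c = linear_sum_assignment(C)
    return float(np.sqrt(C[r, c].mean()))


def gaussian_w2(mu1, sigma1, mu2, sigma2) -> float:
    """Closed-form W2 between diagonal Gaussians:
    ``sqrt(||mu1 - mu2||^2 + ||sigma1 - sigma2||^2)``."""
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    sigma1 = np.atleast_1d(np.asarray(sigma1, dtype=float))
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    return float(
        np.sqrt(((mu1 - mu2) ** 2).sum() + ((sigma1 - sigma2) ** 2).sum())
    )
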