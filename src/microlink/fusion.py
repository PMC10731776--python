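"""Similarity network fusion (SNF).

Multiple same-axis similarity matrices (views) are combined by iterative
cross-diffusion: each view is normalized into a status matrix P that keeps
half its mass on the diagonal, sparsified into a row-stochastic KNN local
affinity kernel S, and then repeatedly updated as
``P_v <- S_v @ mean(P_u, u != v) @ S_v.T``, re-normalized and
re-symmetrized each step (the renormalization is what makes the
cross-diffusion a contraction instead of a rank-collapsing random walk).
The fused network is the mean of the final status matrices, renormalized
with the identity added back, scaled into [0, 1] with diagonal 1, so the
result can serve directly as a [0, 1]-valued weighted adjacency. The
status normalization keeps half of each row's mass on the diagonal
throughout, so the fused network stays diagonally dominant and node
identity survives fusion.

Cross-diffusion needs at least two *distinct* information sources:
duplicate views carry no cross-view information, so `snf_fuse` collapses
them and passes a single remaining view through unchanged (up to the final
rescale), which keeps degenerate inputs loss-free.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SimilarityMatrix

__all__ = ["snf_normalize", "snf_local_affinity", "snf_fuse", "SimilarityNetworkFusion"]


def snf_normalize(W: np.ndarray) -> np.ndarray:
    """Status-matrix normalization: ``P(i,j) = W(i,j) / (2 * sum_{k != i}
    W(i,k))`` off-diagonal and ``P(i,i) = 1/2``; every row sums to 1.

    A row with no off-diagonal mass falls back to a uniform off-diagonal
    distribution (with a warning) rather than dividing by zero.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    dead = row == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} row(s) have zero off-diagonal similarity; "
            "using uniform fallback",
            stacklevel=2,
        )
        off[dead] = 1.0
        np.fill_diagonal(off, 0.0)
        row = off.sum(axis=1)
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def snf_local_affinity(W: np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic KNN kernel: keep the K largest off-diagonal entries
    of each row (ties at the K-th neighbour broken by ascending index, i.e.
    label order) and normalize them to sum 1; everything else is 0."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not 1 <= K < n:
        raise ValueError(f"K must satisfy 1 <= K < n (got K={K}, n={n})")
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    S = np.zeros_like(W)
    for i in range(n):
        # stable sort on descending value; equal values keep index order
        order = np.argsort(-off[i], kind="stable")
        nb = order[:K]
        mass = W[i, nb].sum()
        if mass > 0:
            S[i, nb] = W[i, nb] / mass
        else:  # all selected neighbours zero: uniform over them
            S[i, nb] = 1.0 / K
    return S


def _finalize(F: np.ndarray) -> np.ndarray:
    """Final cleanup of a fused status matrix: renormalize, reinforce the
    diagonal, scale into [0, 1] with diagonal exactly 1."""
    F = snf_normalize(F)
    F = (F + F.T + np.eye(F.shape[0])) / 2.0
    F = F / F.max()
    np.fill_diagonal(F, 1.0)
    return np.clip(F, 0.0, 1.0)


def _rescale_unit(F: np.ndarray) -> np.ndarray:
    """Symmetrize, min-max rescale off-diagonal entries to [0, 1], diag 1.
    Used for the degenerate single-view pass-through."""
    F = (F + F.T) / 2.0
    n = F.shape[0]
    mask = ~np.eye(n, dtype=bool)
    lo, hi = F[mask].min(), F[mask].max()
    out = np.zeros_like(F)
    if hi > lo:
        out[mask] = (F[mask] - lo) / (hi - lo)
    np.fill_diagonal(out, 1.0)
    return out


def snf_fuse(views: list[SimilarityMatrix | np.ndarray], K: int, t: int = 20,
             tol: float = 1e-8, labels: list[str] | None = None) -> SimilarityMatrix:
    """Fuse similarity views into one network by iterative cross-diffusion."""
    if not views:
        raise ValueError("need at least one view")
    mats, lab = [], labels
    for v in views:
        if isinstance(v, SimilarityMatrix):
            if lab is None:
                lab = list(v.labels)
            elif list(v.labels) != list(lab):
                raise ValueError("all views must share identical labels")
            mats.append(v.values)
        else:
            mats.append(np.asarray(v, dtype=float))
    n = mats[0].shape[0]
    if lab is None:
        lab = [f"n{i}" for i in range(n)]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("views must share one square shape")

    # collapse exact duplicates: identical views carry no cross-view signal
    distinct: list[np.ndarray] = []
    for m in mats:
        if not any(np.array_equal(m, d) for d in distinct):
            distinct.append(m)
    if len(distinct) == 1:
        return SimilarityMatrix(_rescale_unit(distinct[0]), lab, kind="fused")

    P = [(lambda p: (p + p.T) / 2.0)(snf_normalize(m)) for m in distinct]
    S = [snf_local_affinity(m, K) for m in distinct]
    V = len(distinct)
    for _ in range(t):
        newP = []
        for v in range(V):
            M = np.mean([P[u] for u in range(V) if u != v], axis=0)
            Pn = snf_normalize(S[v] @ M @ S[v].T)
            newP.append((Pn + Pn.T) / 2.0)
        delta = max(np.abs(a - b).max() for a, b in zip(newP, P))
        P = newP
        if delta < tol:
            break
    return SimilarityMatrix(_finalize(np.mean(P, axis=0)), lab, kind="fused")


class SimilarityNetworkFusion(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`snf_fuse`.

    Parameters
    ----------
    n_neighbors : K for the local affinity kernel.
    n_iterations : diffusion steps t.
    tol : early-stopping threshold on the max status-matrix change.
    """

    def __init__(self, n_neighbors: int = 5, n_iterations: int = 20,
                 tol: float = 1e-8):
        self.n_neighbors = n_neighbors
        self.n_iterations = n_iterations
        self.tol = tol

    def fit(self, X, y=None):
        """X: list of views (SimilarityMatrix or square arrays)."""
        fused = snf_fuse(list(X), K=self.n_neighbors, t=self.n_iterations,
                         tol=self.tol)
        self.fused_network_ = fused
        self.n_features_in_ = fused.values.shape[0]
        return self

    def transform(self, X=None):
        """Return the fused network (X is accepted for sklearn-API
        compatibility and ignored: fusion is a fit-time operation)."""
        if not hasattr(self, "fused_network_"):
            raise AttributeError("SimilarityNetworkFusion is not fitted")
        return self.fused_network_.values

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)
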