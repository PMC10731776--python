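"""Similarity networks over diseases and microbes.

Five families are computed from raw inputs:

* **DSS1** — disease semantic similarity over rooted ontology ancestor
  DAGs. Each ancestor d of a disease D contributes
  ``C_D(d) = max over paths of omega^depth`` (the contribution factor
  omega decays per hop away from the root, and the most favourable path
  counts); the semantic value ``V(D)`` sums contributions over the DAG,
  and two diseases are compared by the contributions of their shared
  ancestors normalized by ``V(D1) + V(D2)``.
* **DSS2** — cosine similarity between nonnegative disease symptom-weight
  vectors.
* **GIP** — Gaussian interaction-profile kernel over rows (microbes) or
  columns (diseases) of the binary association matrix, bandwidth
  normalized by the mean squared profile norm.
* **DFS** — functional similarity between entities of one axis induced by
  a similarity over the partner axis and the entities' partner sets
  (best-match average; used for disease-based and drug-based microbe
  similarity).
* **merge_two_sources** — the two-database combination rule: average where
  both are nonzero, take the nonzero one otherwise.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np
from scipy.spatial.distance import cdist

from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix, SymptomProfile

__all__ = [
    "semantic_contribution",
    "semantic_value",
    "dss1",
    "dss1_matrix",
    "dss2",
    "gip_kernel",
    "set_similarity",
    "functional_similarity",
    "merge_two_sources",
]


def _children_of(dag: DiseaseDAG) -> dict[str, list[str]]:
    """parent -> children map (edges point child -> parent)."""
    out: dict[str, list[str]] = {n: [] for n in dag.nodes}
    for c, p in dag.edges:
        out[p].append(c)
    return out


def semantic_contribution(dag: DiseaseDAG, omega: float) -> dict[str, float]:
    """Semantic contribution C_D(d) of every node in the ancestor DAG.

    The root contributes 1; any other node contributes
    ``max(omega * C_D(child))`` over its children, i.e. ``omega**depth``
    along the shortest child->parent path from the root. Since omega <= 1
    the max-rule over paths is exactly a BFS shortest-hop distance.
    """
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must lie in (0, 1]")
    depth = {dag.root: 0}
    parents = dag.parents_of()
    queue = deque([dag.root])
    while queue:
        node = queue.popleft()
        for parent in parents[node]:
            if parent not in depth:
                depth[parent] = depth[node] + 1
                queue.append(parent)
    missing = dag.nodes - set(depth)
    if missing:
        raise ValueError(
            f"DAG of {dag.root!r}: nodes unreachable from root along "
            f"parent edges: {sorted(missing)}"
        )
    return {n: float(omega**d) for n, d in depth.items()}


def semantic_value(dag: DiseaseDAG, omega: float) -> float:
    """V(D): sum of semantic contributions over the DAG; >= 1 always."""
    return float(sum(semantic_contribution(dag, omega).values()))


def dss1(dag1: DiseaseDAG, dag2: DiseaseDAG, omega: float) -> float:
    """Semantic similarity of two diseases via shared ancestors."""
    c1 = semantic_contribution(dag1, omega)
    c2 = semantic_contribution(dag2, omega)
    shared = set(c1) & set(c2)
    if not shared:
        return 0.0
    num = sum(c1[d] + c2[d] for d in shared)
    den = sum(c1.values()) + sum(c2.values())
    return float(num / den)


def dss1_matrix(dags: dict[str, DiseaseDAG], omega: float,
                labels: list[str] | None = None) -> SimilarityMatrix:
    """Pairwise DSS1 over a DAG forest. Diseases without a DAG get zero
    similarity off-diagonal (and 1 on the diagonal)."""
    if labels is None:
        labels = sorted(dags)
    n = len(labels)
    contrib = {}
    for lab in labels:
        if lab in dags:
            contrib[lab] = semantic_contribution(dags[lab], omega)
    vals = np.zeros((n, n))
    for i, a in enumerate(labels):
        vals[i, i] = 1.0
        for j in range(i + 1, n):
            b = labels[j]
            if a in contrib and b in contrib:
                ca, cb = contrib[a], contrib[b]
                shared = set(ca) & set(cb)
                if shared:
                    num = sum(ca[d] + cb[d] for d in shared)
                    den = sum(ca.values()) + sum(cb.values())
                    vals[i, j] = vals[j, i] = num / den
    return SimilarityMatrix(vals, list(labels), kind="DSS1")


def dss2(profiles: SymptomProfile) -> SimilarityMatrix:
    """Cosine similarity between disease symptom vectors.

    All-zero symptom rows would make cosine undefined; such diseases get
    zero similarity to everything (diagonal 1) with a warning, so NaNs
    never propagate into fusion.
    """
    X = profiles.values
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} disease(s) have empty symptom profiles; "
            "their DSS2 similarity is set to 0 off-diagonal",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    unit = X / safe[:, None]
    vals = unit @ unit.T
    vals[zero, :] = 0.0
    vals[:, zero] = 0.0
    np.fill_diagonal(vals, 1.0)
    vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(vals, list(profiles.disease_labels), kind="DSS2")


def gip_kernel(A: AssociationMatrix, axis: str, eta_prime: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity.

    ``K(i, j) = exp(-eta * ||p_i - p_j||^2)`` with bandwidth
    ``eta = eta_prime / mean_k ||p_k||^2``, where the profiles p are the
    columns of A for the disease axis and the rows for the microbe axis.
    """
    if axis == "disease":
        profiles = A.values.T.astype(float)
        labels = list(A.col_labels)
    elif axis == "microbe":
        profiles = A.values.astype(float)
        labels = list(A.row_labels)
    else:
        raise ValueError("axis must be 'disease' or 'microbe'")
    mean_sq = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq == 0.0:
        raise ValueError("association matrix is all-zero; GIP bandwidth undefined")
    eta = eta_prime / mean_sq
    sq = cdist(profiles, profiles, metric="sqeuclidean")
    vals = np.exp(-eta * sq)
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix((vals + vals.T) / 2.0, labels, kind="GIP")


def set_similarity(d: str, ds: list[str], base: SimilarityMatrix) -> float:
    """Best-match similarity SS(d, ds) = max over d_i in ds of base(d, d_i)."""
    if not ds:
        raise ValueError("partner set is empty")
    i = base.index_of(d)
    idx = [base.index_of(x) for x in ds]
    return float(base.values[i, idx].max())


def functional_similarity(A_partner: AssociationMatrix,
                          base: SimilarityMatrix) -> SimilarityMatrix:
    """Functional similarity over the row axis of ``A_partner`` induced by
    a similarity matrix over its column (partner) axis.

    ``DFS(x, y) = (sum_{d in ds_y} SS(d, ds_x) + sum_{d in ds_x} SS(d, ds_y))
    / (|ds_x| + |ds_y|)`` with ds the partner sets read off A. Entities with
    empty partner sets get 0 off-diagonal and 1 on the diagonal.
    """
    if list(A_partner.col_labels) != list(base.labels):
        raise ValueError("base similarity labels must match partner axis of A")
    A = A_partner.values
    B = base.values
    n = A.shape[0]
    sets = [np.flatnonzero(A[i]) for i in range(n)]
    empty = [len(s) == 0 for s in sets]
    if any(empty):
        warnings.warn(
            f"{sum(empty)} entity(ies) have no partner associations; their "
            "functional similarity is 0 off-diagonal",
            stacklevel=2,
        )
    vals = np.zeros((n, n))
    for i in range(n):
        vals[i, i] = 1.0
        si = sets[i]
        if len(si) == 0:
            continue
        for j in range(i + 1, n):
            sj = sets[j]
            if len(sj) == 0:
                continue
            sub = B[np.ix_(si, sj)]
            # SS(d, ds_x) for d in ds_y is a column-wise max; vice versa rows
            score = (sub.max(axis=0).sum() + sub.max(axis=1).sum()) / (
                len(si) + len(sj)
            )
            vals[i, j] = vals[j, i] = score
    return SimilarityMatrix(vals, list(A_partner.row_labels), kind="DFS")


def merge_two_sources(S_a: SimilarityMatrix, S_b: SimilarityMatrix) -> SimilarityMatrix:
    """Combine two same-axis similarity matrices: average entries where both
    are nonzero, keep the nonzero entry where only one is, zero otherwise."""
    if list(S_a.labels) != list(S_b.labels):
        raise ValueError("similarity matrices must share labels")
    a, b = S_a.values, S_b.values
    both = (a != 0) & (b != 0)
    vals = np.where(both, (a + b) / 2.0, a + b)
    return SimilarityMatrix(vals, list(S_a.labels), kind=S_a.kind)
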