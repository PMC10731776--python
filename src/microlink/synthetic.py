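"""Synthetic study worlds with planted structure.

The generator emulates the statistical shape of curated microbe-disease
data: a sparse bipartite 0/1 association matrix with planted block
structure (cluster-compatible cells associate with probability p_in,
incompatible cells with p_out << p_in, then independent flip noise), toy
ontology ancestor forests in which same-cluster diseases share ancestor
chains, nonnegative disease x symptom weight matrices with
cluster-specific loadings, and optional microbe x drug data for the
drug-based similarity path. Default sizes mirror the curated databases'
aspect ratio (many more microbes than diseases), so the default KNN
neighbour counts of the fusion step remain sensible.

All randomness flows from one integer seed through named substreams
(stage-name-keyed), so regenerating any piece is reproducible and
independent of the order stages run in.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix, SymptomProfile

__all__ = [
    "PlantedWorld",
    "substream",
    "make_planted_association",
    "make_dag_forest",
    "make_symptom_matrix",
    "make_drug_data",
]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Named substream: a generator keyed by (seed, crc32(stage))."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


@dataclass
class PlantedWorld:
    A: AssociationMatrix
    microbe_clusters: np.ndarray
    disease_clusters: np.ndarray
    cluster_link: np.ndarray
    p_in: float
    p_out: float
    flip_noise: float
    seed: int


def make_planted_association(nm: int = 150, nd: int = 30, n_clusters: int = 4,
                             p_in: float = 0.3, p_out: float = 0.02,
                             flip_noise: float = 0.01, seed: int = 0
                             ) -> PlantedWorld:
    """Planted-block bipartite association matrix.

    Entities get round-robin cluster labels; microbe cluster c links to
    disease cluster c (identity compatibility). A(i, j) ~ Bernoulli(p_in)
    for compatible cluster pairs, Bernoulli(p_out) otherwise, then each
    cell flips independently with probability flip_noise.
    """
    if not (nm >= n_clusters and nd >= n_clusters and n_clusters >= 1):
        raise ValueError("need nm, nd >= n_clusters >= 1")
    # p_in == p_out is allowed: it is the null world with no planted signal
    if not 0 <= p_out <= p_in <= 1:
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = substream(seed, "association")
    mc = np.arange(nm) % n_clusters
    dc = np.arange(nd) % n_clusters
    link = np.eye(n_clusters, dtype=int)
    compatible = link[mc][:, dc].astype(bool)
    probs = np.where(compatible, p_in, p_out)
    A = (rng.random((nm, nd)) < probs).astype(np.int8)
    if flip_noise > 0:
        flips = rng.random((nm, nd)) < flip_noise
        A = np.where(flips, 1 - A, A).astype(np.int8)
    assoc = AssociationMatrix(
        A,
        [f"m{i:03d}" for i in range(nm)],
        [f"d{j:03d}" for j in range(nd)],
    )
    return PlantedWorld(assoc, mc, dc, link, p_in, p_out, flip_noise, seed)


def make_dag_forest(disease_labels: list[str], disease_clusters: np.ndarray,
                    depth: int = 3, branching: int = 2,
                    share_prob: float = 0.8, seed: int = 0
                    ) -> dict[str, DiseaseDAG]:
    """Toy ontology ancestor forest.

    Each cluster owns a shared ancestor chain of the given depth. With
    probability ``share_prob`` a disease roots into its cluster's chain
    (attaching to the first ``branching`` chain nodes directly, which
    creates diamond-shaped multi-path DAGs); otherwise it gets a private
    chain. share_prob=0 therefore yields pairwise-disjoint ancestor sets,
    share_prob=1 maximal within-cluster sharing.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = substream(seed, "dag-forest")
    n_clusters = int(np.max(disease_clusters)) + 1 if len(disease_clusters) else 1
    shared_chains = {
        c: [f"anc_c{c}_{k}" for k in range(depth)] for c in range(n_clusters)
    }
    out: dict[str, DiseaseDAG] = {}
    for lab, c in zip(disease_labels, disease_clusters):
        use_shared = rng.random() < share_prob
        chain = shared_chains[int(c)] if use_shared else [
            f"anc_{lab}_{k}" for k in range(depth)
        ]
        edges = [(lab, chain[0])]
        edges += [(chain[k], chain[k + 1]) for k in range(depth - 1)]
        if use_shared:  # extra direct edges exercise the max-over-paths rule
            for b in range(1, min(branching, depth)):
                edges.append((lab, chain[b]))
        nodes = frozenset([lab, *chain])
        out[lab] = DiseaseDAG(lab, nodes, tuple(edges))
    return out


def make_symptom_matrix(world: PlantedWorld, n_symptoms: int = 40,
                        signal: float = 2.0, seed: int = 0) -> SymptomProfile:
    """Nonnegative symptom-weight matrix: uniform noise plus a
    cluster-specific loading template scaled by ``signal`` (signal=0 gives
    pure noise, i.e. no within-cluster cosine excess)."""
    rng = substream(seed, "symptoms")
    nd = world.A.n_diseases
    n_clusters = int(world.cluster_link.shape[0])
    noise = rng.uniform(0.0, 1.0, size=(nd, n_symptoms))
    templates = np.zeros((n_clusters, n_symptoms))
    block = max(n_symptoms // n_clusters, 1)
    for c in range(n_clusters):
        lo = (c * block) % n_symptoms
        templates[c, lo:lo + block] = rng.uniform(0.5, 1.0, size=min(block, n_symptoms - lo))
    vals = noise + signal * templates[world.disease_clusters]
    return SymptomProfile(vals, list(world.A.col_labels))


def make_drug_data(world: PlantedWorld, n_drugs: int = 40, p_in: float = 0.3,
                   p_out: float = 0.02, seed: int = 0
                   ) -> tuple[AssociationMatrix, AssociationMatrix, SimilarityMatrix]:
    """Microbe x drug association matrices from two synthetic sources plus
    a block-structured drug similarity matrix, for the drug-based
    functional-similarity path."""
    rng = substream(seed, "drugs")
    nm = world.A.n_microbes
    n_clusters = int(world.cluster_link.shape[0])
    drug_clusters = np.arange(n_drugs) % n_clusters
    compatible = (world.microbe_clusters[:, None] == drug_clusters[None, :])
    probs = np.where(compatible, p_in, p_out)
    drug_labels = [f"g{k:03d}" for k in range(n_drugs)]
    mats = []
    for _ in range(2):
        M = (rng.random((nm, n_drugs)) < probs).astype(np.int8)
        mats.append(AssociationMatrix(M, list(world.A.row_labels), drug_labels))
    within = drug_clusters[:, None] == drug_clusters[None, :]
    sim = np.where(within, 0.8, 0.1)
    np.fill_diagonal(sim, 1.0)
    drug_sim = SimilarityMatrix(sim, drug_labels, kind="drug")
    return mats[0], mats[1], drug_sim
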