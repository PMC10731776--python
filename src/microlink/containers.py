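"""Labelled in-memory containers shared across pipeline stages.

These are deliberately thin wrappers around NumPy arrays plus label lists:
everything numerical flows through plain arrays, while the containers carry
identity (labels) and enforce the structural invariants each stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "DiseaseDAG",
    "SimilarityMatrix",
    "SymptomProfile",
]

_SYM_TOL = 1e-12


@dataclass
class AssociationMatrix:
    """Binary microbe x disease association matrix A.

    Rows are microbes, columns diseases; entry 1 marks a curated
    association. Column vectors are the disease interaction profiles,
    row vectors the microbe interaction profiles.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        nm, nd = self.values.shape
        if nm < 2 or nd < 2:
            raise ValueError("need at least 2 microbes and 2 diseases")
        if len(self.row_labels) != nm or len(self.col_labels) != nd:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.row_labels)) != nm or len(set(self.col_labels)) != nd:
            raise ValueError("labels must be unique")

    @property
    def n_microbes(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    def disease_sets(self) -> dict[str, list[str]]:
        """Per-microbe list of associated disease labels (the sets ds_x)."""
        cols = np.asarray(self.col_labels)
        return {
            m: [str(d) for d in cols[self.values[i] == 1]]
            for i, m in enumerate(self.row_labels)
        }


@dataclass
class DiseaseDAG:
    """Rooted ancestor DAG of one disease: the root plus all its ontology
    ancestors, with edges pointing child -> parent."""

    root: str
    nodes: frozenset[str]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        self.edges = tuple((str(c), str(p)) for c, p in self.edges)
        if self.root not in self.nodes:
            raise ValueError(f"root {self.root!r} missing from node set")
        for c, p in self.edges:
            if c not in self.nodes or p not in self.nodes:
                raise ValueError(f"edge ({c}, {p}) references unknown node")
        g = nx.DiGraph(self.edges)
        g.add_nodes_from(self.nodes)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"DAG of disease {self.root!r} contains a cycle")

    def parents_of(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.nodes}
        for c, p in self.edges:
            out[c].append(p)
        return out


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    labels: list[str]
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match labels")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-9:
            raise ValueError("similarity matrix is not symmetric")
        # exact symmetrization so downstream equality checks are clean
        self.values = (self.values + self.values.T) / 2.0
        if self.values.min(initial=0.0) < -_SYM_TOL or self.values.max(initial=0.0) > 1 + 1e-9:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class SymptomProfile:
    """Nonnegative disease x symptom weight matrix (IDF-style weights)."""

    values: np.ndarray
    disease_labels: list[str]
    symptom_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("symptom profile must be 2-D")
        if self.values.min(initial=0.0) < 0:
            raise ValueError("symptom weights must be nonnegative")
        if len(self.disease_labels) != self.values.shape[0]:
            raise ValueError("disease label count does not match rows")
        if not self.symptom_labels:
            self.symptom_labels = [f"s{j}" for j in range(self.values.shape[1])]
        if len(self.symptom_labels) != self.values.shape[1]:
            raise ValueError("symptom label count does not match columns")
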