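"""Readers and writers for the TSV formats the pipeline exchanges.

Association tables come either as two-column pair lists (the shape the
curated databases distribute) or as dense labelled 0/1 matrices. Ontology
DAGs arrive as three-column edge lists (disease, child, parent). All
matrices round-trip losslessly: floats are written with 17 significant
digits.
"""

from __future__ import annotations

import logging
import pathlib

import numpy as np
import pandas as pd

from .containers import AssociationMatrix, DiseaseDAG

logger = logging.getLogger("microlink")

_FLOAT_FMT = "%.17g"


def read_association_table(path, format: str = "pairs") -> AssociationMatrix:
    """Read a microbe-disease association table.

    ``pairs``: TSV with >= 2 columns (microbe id, disease id, extras
    ignored), no header; duplicates collapse to a single association.
    ``matrix``: dense labelled TSV with a header row of disease ids and a
    first column of microbe ids; entries must be 0/1.

    Labels are sorted lexicographically so matrix layout is deterministic
    regardless of row order in the file.
    """
    path = pathlib.Path(path)
    if format == "pairs":
        pairs: set[tuple[str, str]] = set()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                    raise ValueError(
                        f"{path.name}:{lineno}: malformed pair row {line!r}"
                    )
                pairs.add((parts[0].strip(), parts[1].strip()))
        if not pairs:
            raise ValueError(f"{path.name}: no association pairs found")
        microbes = sorted({m for m, _ in pairs})
        diseases = sorted({d for _, d in pairs})
        values = np.zeros((len(microbes), len(diseases)), dtype=np.int8)
        mi = {m: i for i, m in enumerate(microbes)}
        di = {d: j for j, d in enumerate(diseases)}
        for m, d in pairs:
            values[mi[m], di[d]] = 1
        return AssociationMatrix(values, microbes, diseases)
    if format == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.empty:
            raise ValueError(f"{path.name}: empty matrix")
        arr = df.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValueError(
                f"{path.name}: non-binary cell at row {df.index[bad[0]]!r}, "
                f"column {df.columns[bad[1]]!r}"
            )
        df = df.sort_index(axis=0).sort_index(axis=1)
        return AssociationMatrix(
            df.to_numpy(), [str(x) for x in df.index], [str(x) for x in df.columns]
        )
    raise ValueError(f"unknown association format {format!r}")


def write_association_pairs(assoc: AssociationMatrix, path) -> None:
    """Write the positive cells of an association matrix as a pair list."""
    rows, cols = np.nonzero(assoc.values)
    with open(path, "w") as fh:
        for i, j in zip(rows, cols):
            fh.write(f"{assoc.row_labels[i]}\t{assoc.col_labels[j]}\n")


def read_dag_edges(path) -> dict[str, DiseaseDAG]:
    """Read a forest of rooted ancestor DAGs from a 3-column edge list
    (disease_id, child, parent). One DAG is built per distinct disease_id,
    rooted at that disease; cycles and missing roots raise."""
    path = pathlib.Path(path)
    edges_by_disease: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 3 or not all(parts[:3]):
                raise ValueError(f"{path.name}:{lineno}: malformed DAG row {line!r}")
            disease, child, parent = parts[:3]
            edges_by_disease.setdefault(disease, [])
            if child == parent == disease:
                continue  # marker row for a single-node DAG
            edges_by_disease[disease].append((child, parent))
    if not edges_by_disease:
        raise ValueError(f"{path.name}: no DAG edges found")
    out: dict[str, DiseaseDAG] = {}
    for disease in sorted(edges_by_disease):
        edges = edges_by_disease[disease]
        nodes = {disease} | {n for e in edges for n in e}
        try:
            out[disease] = DiseaseDAG(disease, frozenset(nodes), tuple(edges))
        except ValueError as exc:
            raise ValueError(f"{path.name}: disease {disease!r}: {exc}") from exc
    return out


def write_dag_edges(dags: dict[str, DiseaseDAG], path) -> None:
    with open(path, "w") as fh:
        for disease in sorted(dags):
            dag = dags[disease]
            if not dag.edges:  # single-node DAG: self-loop-free marker row
                fh.write(f"{disease}\t{disease}\t{disease}\n")
                continue
            for c, p in dag.edges:
                fh.write(f"{disease}\t{c}\t{p}\n")


def write_matrix(values, row_labels, col_labels, path) -> None:
    """Write a labelled matrix as TSV with a header row and a label column.

    17 significant digits, so float round-trips are bit-lossless.
    """
    values = np.asarray(values)
    df = pd.DataFrame(values, index=list(row_labels), columns=list(col_labels))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="id")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled TSV matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return (
        df.to_numpy(dtype=float),
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
    )


def log_stage(stage: str, seed: int, elapsed: float, **shapes) -> None:
    """One structured log line per pipeline stage."""
    shape_str = " ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("stage=%s seed=%d elapsed=%.3fs %s", stage, seed, elapsed, shape_str)
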