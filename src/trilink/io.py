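"""Readers and writers for the tool's file formats.

All files are tab-separated UTF-8 text; lines starting with ``#`` are
comments.  Pair lists (association files) carry no header; labeled matrix
files require a header row of column ids.  Disease DAG files hold rows
``<disease_id>\t<child>\t<parent>``; a single-field line ``<disease_id>``
declares a root-only DAG (a disease with no recorded ancestors).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    AnnotationSets,
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    ParseError,
    SimilarityMatrix,
    UniverseLookupError,
    ValidationError,
)

__all__ = [
    "read_association_pairs",
    "write_association_pairs",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_annotation_sets",
    "write_annotation_sets",
    "read_disease_dags",
    "write_disease_dags",
]


def _data_lines(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _read_pairs(path: Path, n_fields: int) -> list[tuple[int, list[str]]]:
    rows = []
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != n_fields or not all(fields):
            raise ParseError(
                f"{path}:{lineno}: expected {n_fields} non-empty tab-separated fields, "
                f"got {line!r}"
            )
        rows.append((lineno, fields))
    return rows


def read_association_pairs(
    path,
    row_index: EntityIndex | None = None,
    col_index: EntityIndex | None = None,
    row_kind: str = "",
    col_kind: str = "",
) -> AssociationMatrix:
    """Read a two-column ``row_id<TAB>col_id`` association list.

    Duplicated pairs collapse to a single 1 entry.  When an index is not
    supplied it is inferred in first-appearance order.
    """
    path = Path(path)
    pairs = [(f[0], f[1]) for _, f in _read_pairs(path, 2)]
    if row_index is None:
        row_index = EntityIndex(dict.fromkeys(r for r, _ in pairs))
    if col_index is None:
        col_index = EntityIndex(dict.fromkeys(c for _, c in pairs))
    values = np.zeros((len(row_index), len(col_index)))
    for r, c in pairs:
        values[row_index.position(r), col_index.position(c)] = 1.0
    return AssociationMatrix(values, row_index, col_index, row_kind, col_kind)


def write_association_pairs(matrix: AssociationMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r, c in matrix.pairs():
            fh.write(f"{r}\t{c}\n")


def read_similarity_matrix(path, index: EntityIndex | None = None, kind: str = "") -> SimilarityMatrix:
    """Read a labeled square similarity matrix (header row/column of ids).

    The matrix is reindexed to ``index`` order when given.  Asymmetry beyond
    1e-6 or entries outside [0, 1] reject the file; smaller numerical
    deviations are symmetrized/clipped and the diagonal is forced to 1.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse matrix file: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.shape[0] != frame.shape[1] or set(frame.index) != set(frame.columns):
        raise ValidationError(f"{path}: matrix is not square over one id set")
    frame = frame.loc[:, frame.index]  # align column order with row order
    if index is not None:
        missing = [i for i in index if i not in frame.index]
        if missing:
            raise UniverseLookupError(f"{path}: ids missing from matrix: {missing[:5]}")
        extra = [i for i in frame.index if i not in index]
        if extra:
            raise UniverseLookupError(f"{path}: matrix ids not in universe: {extra[:5]}")
        frame = frame.loc[list(index.ids), list(index.ids)]
    else:
        index = EntityIndex(frame.index)
    return SimilarityMatrix(frame.to_numpy(dtype=float), index, kind)


def write_similarity_matrix(matrix: SimilarityMatrix, path) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.index.ids, columns=matrix.index.ids)
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation_sets(path, kind: str = "") -> AnnotationSets:
    """Read ``entity_id<TAB>item_id`` rows into per-entity annotation sets."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    for _, fields in _read_pairs(path, 2):
        sets.setdefault(fields[0], set()).add(fields[1])
    return AnnotationSets({k: frozenset(v) for k, v in sets.items()}, kind)


def write_annotation_sets(sets: AnnotationSets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entity in sorted(sets.sets):
            for item in sorted(sets.sets[entity]):
                fh.write(f"{entity}\t{item}\n")


def read_disease_dags(path) -> dict[str, DiseaseDAG]:
    """Read per-disease ancestor DAGs.

    Rows are ``disease_id<TAB>child_term<TAB>parent_term``; a bare
    ``disease_id`` line declares a root-only DAG.  Cyclic inputs are
    rejected with the offending cycle named.
    """
    path = Path(path)
    edges: dict[str, set[tuple[str, str]]] = {}
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t") if f.strip()]
        if len(fields) == 1:
            edges.setdefault(fields[0], set())
        elif len(fields) == 3:
            edges.setdefault(fields[0], set()).add((fields[1], fields[2]))
        else:
            raise ParseError(
                f"{path}:{lineno}: expected 'disease<TAB>child<TAB>parent' or a bare "
                f"disease id, got {line!r}"
            )
    for d, e in edges.items():
        terms = {t for pair in e for t in pair}
        if e and d not in terms:
            raise ValidationError(f"{path}: root term {d!r} absent from its own DAG edges")
    return {d: DiseaseDAG(d, frozenset(), frozenset(e)) for d, e in edges.items()}


def write_disease_dags(dags: Mapping[str, DiseaseDAG], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for disease_id in sorted(dags):
            dag = dags[disease_id]
            if not dag.edges:
                fh.write(f"{disease_id}\n")
            for child, parent in sorted(dag.edges):
                fh.write(f"{disease_id}\t{child}\t{parent}\n")
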