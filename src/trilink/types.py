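"""Core domain types for the triple-layer association network.

The network has three node layers — small molecules (SMs), miRNAs and
diseases — connected by two bipartite association matrices (SM x miRNA and
miRNA x disease) and three within-layer similarity matrices.  These classes
hold the ordered entity universes and validate the matrix invariants every
other module relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "ValidationError",
    "ParseError",
    "UniverseLookupError",
    "EntityIndex",
    "EntityUniverse",
    "AssociationMatrix",
    "SimilarityMatrix",
    "AnnotationSets",
    "DiseaseDAG",
]


class ValidationError(ValueError):
    """An object violates a structural invariant (shape, range, symmetry, acyclicity)."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries the offending line number."""


class UniverseLookupError(KeyError):
    """An identifier does not belong to the entity universe it was resolved against."""


class EntityIndex:
    """Ordered, immutable list of unique entity identifiers with O(1) position lookup."""

    __slots__ = ("ids", "_pos")

    def __init__(self, ids: Iterable[str]):
        ids = tuple(str(i) for i in ids)
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate entity id {dup!r}")
        self.ids = ids
        self._pos = {v: i for i, v in enumerate(ids)}

    def position(self, entity_id: str) -> int:
        try:
            return self._pos[entity_id]
        except KeyError:
            raise UniverseLookupError(f"unknown entity id {entity_id!r}") from None

    def positions(self, entity_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.position(i) for i in entity_ids], dtype=int)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, entity_id: object) -> bool:
        return entity_id in self._pos

    def __getitem__(self, pos: int) -> str:
        return self.ids[pos]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EntityIndex) and self.ids == other.ids

    def __hash__(self) -> int:
        return hash(self.ids)

    def __repr__(self) -> str:
        return f"EntityIndex(n={len(self.ids)})"


@dataclass(frozen=True)
class EntityUniverse:
    """The three ordered entity lists of the triple-layer network.

    ``ns``, ``nm`` and ``nd`` denote the number of SMs, miRNAs and diseases.
    """

    sm: EntityIndex
    mirna: EntityIndex
    disease: EntityIndex

    @property
    def ns(self) -> int:
        return len(self.sm)

    @property
    def nm(self) -> int:
        return len(self.mirna)

    @property
    def nd(self) -> int:
        return len(self.disease)


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary bipartite adjacency between two entity layers.

    ``A`` (SM x miRNA) holds the known SM-miRNA associations; ``B``
    (miRNA x disease) the known miRNA-disease associations.  Entries are
    strictly 0/1 and rows/columns follow the attached indexes.
    """

    values: np.ndarray
    row_index: EntityIndex
    col_index: EntityIndex
    row_kind: str = ""
    col_kind: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (len(self.row_index), len(self.col_index)):
            raise ValidationError(
                f"association matrix shape {values.shape} does not match universes "
                f"({len(self.row_index)}, {len(self.col_index)})"
            )
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValidationError("association matrix entries must be 0 or 1")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """Known associations as (row_id, col_id), row-major order."""
        rows, cols = np.nonzero(self.values)
        return [(self.row_index[i], self.col_index[j]) for i, j in zip(rows, cols)]

    def transpose(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.T, self.col_index, self.row_index, self.col_kind, self.row_kind
        )


# Tolerances for similarity-matrix validation: asymmetry beyond ASYM_HARD or
# entries outside [0,1] by more than RANGE_TOL reject the input; smaller
# deviations are repaired (symmetrized / clipped).
ASYM_HARD = 1e-6
RANGE_TOL = 1e-8


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] over one entity layer, unit diagonal."""

    values: np.ndarray
    index: EntityIndex
    kind: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if values.shape != (n, n):
            raise ValidationError(f"similarity matrix shape {values.shape}, expected ({n}, {n})")
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > ASYM_HARD:
            raise ValidationError(f"similarity matrix asymmetric (max |M - M.T| = {asym:.3g})")
        values = (values + values.T) / 2.0
        low, high = values.min(initial=1.0), values.max(initial=0.0)
        if low < -RANGE_TOL or high > 1.0 + RANGE_TOL:
            raise ValidationError(
                f"similarity entries outside [0, 1] (min {low:.3g}, max {high:.3g})"
            )
        values = np.clip(values, 0.0, 1.0)
        np.fill_diagonal(values, 1.0)
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class AnnotationSets:
    """Per-entity annotation item sets (side effects, related diseases, target genes).

    Feeds the Jaccard similarity; sets may be empty.
    """

    sets: Mapping[str, frozenset[str]]
    kind: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sets", {str(k): frozenset(map(str, v)) for k, v in self.sets.items()}
        )

    def get(self, entity_id: str) -> frozenset[str]:
        return self.sets.get(entity_id, frozenset())

    def restricted_to(self, index: EntityIndex) -> "AnnotationSets":
        missing = [i for i in self.sets if i not in index]
        if missing:
            raise UniverseLookupError(f"annotated entities not in universe: {missing[:5]}")
        return self

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class DiseaseDAG:
    """Rooted ancestor graph of one disease term, MeSH style.

    ``DAG(D) = (D, T(D), E(D))``: the node set ``T(D)`` contains the disease
    itself plus all its ancestors, and ``E(D)`` holds child -> parent edges.
    """

    disease_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        nodes = frozenset(map(str, self.nodes)) | {str(self.disease_id)}
        edges = frozenset((str(c), str(p)) for c, p in self.edges)
        for c, p in edges:
            nodes = nodes | {c, p}
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"disease DAG for {self.disease_id!r} contains a cycle: {cycle}")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    def children_of(self, term: str) -> frozenset[str]:
        """Terms with a child -> parent edge into ``term`` (i.e. its children in the DAG)."""
        return frozenset(c for c, p in self.edges if p == term)

    def __contains__(self, term: object) -> bool:
        return term in self.nodes
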