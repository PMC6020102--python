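"""Similarity models over the three network layers.

Implements the annotation-set Jaccard similarity, the two MeSH-DAG disease
semantic similarity models, the Gaussian interaction profile (GIP) kernel on
disease interaction profiles, and the weighted integrations that combine the
per-source matrices into one similarity per layer.

Notation used throughout: for a disease D, ``DAG(D) = (D, T(D), E(D))`` with
``T(D)`` the term plus its MeSH ancestors; model 1 scores each ancestor term
by a contribution decaying geometrically (factor Δ) with distance from D,
model 2 by an information-content weight ``-log(n_DAGs containing t / n_diseases)``
that rewards specific terms.  The GIP kernel treats each disease's column of
the miRNA-disease adjacency as its interaction profile and applies a Gaussian
kernel whose bandwidth is scaled by the mean squared profile norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .types import (
    AnnotationSets,
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "IntegrationWeights",
    "jaccard_similarity",
    "semantic_contribution_m1",
    "semantic_value",
    "semantic_similarity_m1",
    "semantic_contribution_m2",
    "semantic_similarity_m2",
    "gip_kernel_disease",
    "integrate_sm_similarity",
    "integrate_mirna_similarity",
    "integrate_disease_similarity",
    "disease_similarity",
]

#: Default semantic contribution factor Δ; the convention in the
#: disease-semantic-similarity literature.
DEFAULT_DELTA = 0.5

#: Default GIP bandwidth scale γ'.
DEFAULT_GAMMA_PRIME = 1.0


@dataclass(frozen=True)
class IntegrationWeights:
    """Nonnegative weights for the per-layer similarity integrations.

    ``beta`` weights the four SM sources (disease-phenotype, target-gene,
    chemical-structure, side-effect, in that order); ``alpha`` weights the two
    miRNA sources (disease-phenotype, target-gene).  Default 1 everywhere:
    every available source counts equally.
    """

    beta: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    alpha: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name, w in (("beta", self.beta), ("alpha", self.alpha)):
            if any(x < 0 for x in w):
                raise ValidationError(f"{name} weights must be nonnegative")
            if not any(x > 0 for x in w):
                raise ValidationError(f"at least one {name} weight must be positive")


def jaccard_similarity(sets: AnnotationSets, index: EntityIndex) -> SimilarityMatrix:
    """Jaccard similarity ``|N(i) ∩ N(j)| / |N(i) ∪ N(j)|`` over annotation sets.

    Entities sharing no items score 0; an empty union also scores 0
    off-diagonal.  The diagonal is 1 by the self-similarity convention.
    """
    sets.restricted_to(index)
    n = len(index)
    items = sorted({it for e in index for it in sets.get(e)})
    pos = {it: k for k, it in enumerate(items)}
    member = np.zeros((n, max(len(items), 1)))
    for i, e in enumerate(index):
        for it in sets.get(e):
            member[i, pos[it]] = 1.0
    inter = member @ member.T
    sizes = member.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, index, kind=f"jaccard[{sets.kind}]" if sets.kind else "jaccard")


def semantic_contribution_m1(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> dict[str, float]:
    """Model-1 semantic contributions of each term in ``T(D)`` to disease D.

    The disease contributes 1 to itself; every ancestor contributes
    ``Δ * max(contribution of its children within the DAG)``, so contributions
    decay with distance from D.
    """
    if not 0 < delta < 1:
        raise ValidationError(f"delta must lie in (0, 1), got {delta}")
    root = dag.disease_id
    children: dict[str, set[str]] = {t: set() for t in dag.nodes}
    for c, p in dag.edges:
        children[p].add(c)
    contrib: dict[str, float] = {}

    def value(term: str, stack: frozenset[str]) -> float:
        if term in contrib:
            return contrib[term]
        if term == root:
            contrib[term] = 1.0
            return 1.0
        kids = children[term]
        if not kids:
            raise ValidationError(
                f"term {term!r} in DAG({root!r}) is unreachable from the root"
            )
        contrib[term] = delta * max(value(k, stack | {term}) for k in kids)
        return contrib[term]

    for term in dag.nodes:
        value(term, frozenset())
    return contrib


def semantic_value(contrib: Mapping[str, float]) -> float:
    """Semantic value DV of a disease: the sum of its term contributions."""
    if not contrib:
        raise ValidationError("empty semantic contribution map")
    return float(sum(contrib.values()))


def _shared_term_similarity(
    contribs: Mapping[str, Mapping[str, float]], index: EntityIndex, kind: str
) -> SimilarityMatrix:
    """Similarity from per-disease term contributions:
    S(i,j) = sum over shared terms of (c_i(t) + c_j(t)) / (DV(i) + DV(j))."""
    n = len(index)
    dvs = {d: semantic_value(contribs[d]) for d in index}
    sim = np.zeros((n, n))
    for i, di in enumerate(index):
        ci = contribs[di]
        for j in range(i, n):
            dj = index[j]
            cj = contribs[dj]
            shared = ci.keys() & cj.keys()
            denom = dvs[di] + dvs[dj]
            if denom == 0:
                val = 1.0 if ci.keys() == cj.keys() else 0.0
            else:
                val = sum(ci[t] + cj[t] for t in shared) / denom
            sim[i, j] = sim[j, i] = val
    np.fill_diagonal(sim, 1.0)
    if sim.max(initial=0.0) > 1.0 + 1e-12 or sim.min(initial=0.0) < 0.0:
        raise ValidationError(f"{kind} similarity left [0, 1]; DAG inputs are inconsistent")
    return SimilarityMatrix(sim, index, kind)


def semantic_similarity_m1(
    dags: Mapping[str, DiseaseDAG], index: EntityIndex, delta: float = DEFAULT_DELTA
) -> SimilarityMatrix:
    """Model-1 semantic similarity: shared-term contribution mass over total mass.

    Requires a DAG for every disease in ``index``; diseases without DAGs are
    handled upstream by :func:`integrate_disease_similarity`.
    """
    missing = [d for d in index if d not in dags]
    if missing:
        raise ValidationError(f"no DAG for diseases: {missing[:5]}")
    contribs = {d: semantic_contribution_m1(dags[d], delta) for d in index}
    return _shared_term_similarity(contribs, index, "semantic_m1")


def semantic_contribution_m2(
    dags: Mapping[str, DiseaseDAG],
    n_diseases: int | None = None,
    base: float = math.e,
) -> dict[str, float]:
    """Model-2 (information-content) contribution of every term appearing in any DAG.

    ``-log(count of DAGs containing t / n_diseases)``; a term shared by all
    DAGs of a complete universe contributes 0, rare terms contribute most.
    The contribution of a term is the same in every DAG that contains it.
    """
    if not dags:
        raise ValidationError("at least one disease DAG is required")
    if n_diseases is None:
        n_diseases = len(dags)
    if len(dags) > n_diseases:
        raise ValidationError("more DAGs than diseases in the universe")
    counts: dict[str, int] = {}
    for dag in dags.values():
        for t in dag.nodes:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n_diseases, base) for t, c in counts.items()}


def semantic_similarity_m2(
    dags: Mapping[str, DiseaseDAG],
    index: EntityIndex,
    base: float = math.e,
) -> SimilarityMatrix:
    """Model-2 semantic similarity; invariant to the logarithm base.

    Degenerate diseases whose terms are all ubiquitous (DV2 = 0) score 1
    against an identical term set and 0 otherwise (the limit behavior).
    """
    missing = [d for d in index if d not in dags]
    if missing:
        raise ValidationError(f"no DAG for diseases: {missing[:5]}")
    global_contrib = semantic_contribution_m2(
        {d: dags[d] for d in index}, n_diseases=len(index), base=base
    )
    contribs = {d: {t: global_contrib[t] for t in dags[d].nodes} for d in index}
    return _shared_term_similarity(contribs, index, "semantic_m2")


def gip_kernel_disease(
    B: AssociationMatrix | np.ndarray,
    gamma_prime: float = DEFAULT_GAMMA_PRIME,
    gamma: float | None = None,
    index: EntityIndex | None = None,
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity between diseases.

    The interaction profile ``IP(d(u))`` of disease u is its column of the
    miRNA x disease adjacency ``B``.  The bandwidth is
    ``γ_d = γ' / mean_u ||IP(d(u))||²`` and
    ``KD(u, v) = exp(-γ_d ||IP(u) - IP(v)||²)``.  Pass ``gamma`` to override
    the bandwidth directly (required when ``B`` is all-zero).
    """
    values = np.asarray(getattr(B, "values", B), dtype=float)
    if index is None:
        index = getattr(B, "col_index", None) or EntityIndex(
            f"d{j}" for j in range(values.shape[1])
        )
    profiles = values.T  # one row per disease
    sq_norms = (profiles**2).sum(axis=1)
    if gamma is None:
        mean_sq = sq_norms.mean()
        if mean_sq == 0:
            raise ValidationError(
                "adjacency is all-zero, GIP bandwidth undefined; pass gamma explicitly"
            )
        gamma = gamma_prime / mean_sq
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    kernel = np.exp(-gamma * np.maximum(d2, 0.0))
    np.fill_diagonal(kernel, 1.0)
    return SimilarityMatrix(kernel, index, "gip")


def _weighted_integration(
    sources: Sequence[SimilarityMatrix | np.ndarray | None],
    weights: Sequence[float],
    coverages: Sequence[np.ndarray | None] | None,
    index: EntityIndex,
    kind: str,
) -> SimilarityMatrix:
    """Per-cell weighted mean over the sources available at that cell.

    A source contributes at cell (i, j) only if it exists and both entities
    are covered by it; the divisor is the sum of weights of contributing
    sources.  Cells no source covers fall back to 0 (diagonal to 1).
    """
    if coverages is None:
        coverages = [None] * len(sources)
    if len(weights) != len(sources) or len(coverages) != len(sources):
        raise ValidationError("sources, weights and coverages must align")
    if any(w < 0 for w in weights):
        raise ValidationError("integration weights must be nonnegative")
    n = len(index)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    any_source = False
    for src, w, cov in zip(sources, weights, coverages):
        if src is None or w == 0:
            continue
        any_source = True
        values = np.asarray(getattr(src, "values", src), dtype=float)
        if values.shape != (n, n):
            raise ValidationError(f"source shape {values.shape} != ({n}, {n})")
        if cov is None:
            mask = np.ones((n, n), dtype=bool)
        else:
            cov = np.asarray(cov, dtype=bool)
            mask = cov[:, None] & cov[None, :]
        num += np.where(mask, w * values, 0.0)
        den += np.where(mask, w, 0.0)
    if not any_source:
        raise ValidationError("no similarity source available for integration")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(out, index, kind)


def integrate_sm_similarity(
    disease: SimilarityMatrix | np.ndarray | None = None,
    target: SimilarityMatrix | np.ndarray | None = None,
    chemical: SimilarityMatrix | np.ndarray | None = None,
    side_effect: SimilarityMatrix | np.ndarray | None = None,
    weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
    coverages: Sequence[np.ndarray | None] | None = None,
    index: EntityIndex | None = None,
) -> SimilarityMatrix:
    """Integrated SM similarity: weighted mean of the four SM sources.

    Source order (matching the ``beta`` weights): disease-phenotype,
    target-gene, chemical-structure (e.g. SIMCOMP), side-effect.
    """
    index = _resolve_index(index, disease, target, chemical, side_effect)
    return _weighted_integration(
        [disease, target, chemical, side_effect], weights, coverages, index, "sm_integrated"
    )


def integrate_mirna_similarity(
    disease: SimilarityMatrix | np.ndarray | None = None,
    target: SimilarityMatrix | np.ndarray | None = None,
    weights: Sequence[float] = (1.0, 1.0),
    coverages: Sequence[np.ndarray | None] | None = None,
    index: EntityIndex | None = None,
) -> SimilarityMatrix:
    """Integrated miRNA similarity: weighted mean of disease-phenotype and
    target-gene functional similarity."""
    index = _resolve_index(index, disease, target)
    return _weighted_integration([disease, target], weights, coverages, index, "mirna_integrated")


def integrate_disease_similarity(
    ss1: SimilarityMatrix | np.ndarray,
    ss2: SimilarityMatrix | np.ndarray,
    kd: SimilarityMatrix | np.ndarray,
    has_dag: np.ndarray,
    index: EntityIndex | None = None,
) -> SimilarityMatrix:
    """Integrated disease similarity.

    Disease pairs where both members have a MeSH DAG take the mean of the two
    semantic models; every other pair falls back to the GIP kernel.
    """
    index = _resolve_index(index, ss1, ss2, kd)
    n = len(index)
    a1 = np.asarray(getattr(ss1, "values", ss1), dtype=float)
    a2 = np.asarray(getattr(ss2, "values", ss2), dtype=float)
    ak = np.asarray(getattr(kd, "values", kd), dtype=float)
    has_dag = np.asarray(has_dag, dtype=bool)
    if has_dag.shape != (n,):
        raise ValidationError(f"has_dag must have one flag per disease ({n})")
    both = has_dag[:, None] & has_dag[None, :]
    out = np.where(both, (a1 + a2) / 2.0, ak)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(out, index, "disease_integrated")


def disease_similarity(
    dags: Mapping[str, DiseaseDAG],
    B: AssociationMatrix,
    delta: float = DEFAULT_DELTA,
    gamma_prime: float = DEFAULT_GAMMA_PRIME,
) -> SimilarityMatrix:
    """Full disease-similarity pipeline over the disease universe of ``B``.

    Computes both semantic models on the subset of diseases that have DAGs,
    the GIP kernel on all diseases, and integrates them.
    """
    index = B.col_index
    n = len(index)
    has_dag = np.array([d in dags for d in index], dtype=bool)
    kd = gip_kernel_disease(B, gamma_prime=gamma_prime)
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    with_dag = [d for d in index if d in dags]
    if with_dag:
        sub = EntityIndex(with_dag)
        sub_dags = {d: dags[d] for d in with_dag}
        m1 = semantic_similarity_m1(sub_dags, sub, delta)
        m2 = semantic_similarity_m2(sub_dags, sub, base=math.e)
        rows = index.positions(with_dag)
        s1[np.ix_(rows, rows)] = m1.values
        s2[np.ix_(rows, rows)] = m2.values
    return integrate_disease_similarity(s1, s2, kd.values, has_dag, index)


def _resolve_index(index: EntityIndex | None, *sources) -> EntityIndex:
    if index is not None:
        return index
    for src in sources:
        found = getattr(src, "index", None)
        if isinstance(found, EntityIndex):
            return found
    for src in sources:
        if src is not None:
            n = np.asarray(getattr(src, "values", src)).shape[0]
            return EntityIndex(f"e{i}" for i in range(n))
    raise ValidationError("no similarity source available for integration")
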