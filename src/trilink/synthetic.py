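"""Synthetic triple-layer datasets with planted block structure.

The generator emulates the statistical structure the propagation method
assumes: entities fall into latent clusters, within-cluster similarity is
high, and associations preferentially connect matching clusters ("similar
SMs associate with similar miRNAs").  The ``coherence`` knob interpolates
between fully cluster-respecting associations (1.0) and uniformly random
ones (0.0), which makes recovery performance a controlled function of the
planted signal.  Two dataset regimes are supported: "sparse" keeps entities
with zero associations in the universes (Dataset-1-like), "dense" restricts
every universe to entities carrying at least one association
(Dataset-2-like).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import SimilaritySet
from .types import (
    AnnotationSets,
    AssociationMatrix,
    EntityIndex,
    EntityUniverse,
    SimilarityMatrix,
    ValidationError,
)

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "generate_annotation_sets", "structureless_spec"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults are desk-scale: a 30 x 40 x 20 universe with 60 SM-miRNA and
    120 miRNA-disease associations runs a full LOOCV in seconds.  Real
    SM-miRNA association data concentrate on a minority of entities (most
    catalogued SMs have no known miRNA at all, while the involved ones carry
    many associations); ``frac_sm_active`` / ``frac_mirna_active`` reproduce
    that regime by restricting the block-coherent association draws to an
    active subset of each universe.  Incoherent (noise) draws remain uniform
    over the whole grid.
    """

    ns: int = 30
    nm: int = 40
    nd: int = 20
    n_blocks: int = 4
    n_assoc_sm: int = 60
    n_assoc_dis: int = 120
    coherence: float = 1.0
    sim_within: float = 0.8
    sim_between: float = 0.1
    noise_sd: float = 0.05
    frac_sm_active: float = 0.4
    frac_mirna_active: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coherence <= 1:
            raise ValidationError("coherence must lie in [0, 1]")
        if not 0 <= self.sim_between <= self.sim_within <= 1:
            raise ValidationError("require 0 <= sim_between <= sim_within <= 1")
        if not (0 < self.frac_sm_active <= 1 and 0 < self.frac_mirna_active <= 1):
            raise ValidationError("active fractions must lie in (0, 1]")
        if self.n_assoc_sm > self.ns * self.nm or self.n_assoc_dis > self.nm * self.nd:
            raise ValidationError("requested associations exceed matrix size")
        if min(self.ns, self.nm, self.nd, self.n_blocks) < 1:
            raise ValidationError("sizes and block count must be positive")


def structureless_spec(**overrides) -> SyntheticSpec:
    """A spec with no planted signal: flat similarities and coherence 0.

    Used by the randomization control; similarity matrices carry only noise
    around a constant level and associations are uniform.
    """
    base = SyntheticSpec(
        coherence=0.0,
        sim_within=0.2,
        sim_between=0.2,
        frac_sm_active=1.0,
        frac_mirna_active=1.0,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class SyntheticDataset:
    universe: EntityUniverse
    A: AssociationMatrix  # SM x miRNA
    B: AssociationMatrix  # miRNA x disease
    s_sm: SimilarityMatrix
    s_mirna: SimilarityMatrix
    s_disease: SimilarityMatrix
    labels: dict[str, np.ndarray]  # block label per entity, keys sm/mirna/disease
    spec: SyntheticSpec

    @property
    def sims(self) -> SimilaritySet:
        return SimilaritySet(self.s_sm.values, self.s_mirna.values, self.s_disease.values)


def _label_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), 17]))


def _labels(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = _label_rng(spec)
    return (
        rng.integers(0, spec.n_blocks, spec.ns),
        rng.integers(0, spec.n_blocks, spec.nm),
        rng.integers(0, spec.n_blocks, spec.nd),
    )


def _block_similarity(labels: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    base = np.where(labels[:, None] == labels[None, :], spec.sim_within, spec.sim_between)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, base.shape)
        noise = (noise + noise.T) / 2.0
        base = base + noise
    sim = np.clip(base, 0.0, 1.0)  # truncate noise to keep entries in [0, 1]
    np.fill_diagonal(sim, 1.0)
    return sim


def _active_subset(labels: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Pick round(frac * n) entities, balanced across blocks, to carry associations."""
    n = len(labels)
    if frac >= 1:
        return np.arange(n)
    k = max(1, round(frac * n))
    by_block: dict[int, list[int]] = {}
    for idx in rng.permutation(n):
        by_block.setdefault(int(labels[idx]), []).append(int(idx))
    blocks = sorted(by_block)
    chosen: list[int] = []
    b = 0
    while len(chosen) < k and any(by_block.values()):
        pool = by_block[blocks[b % len(blocks)]]
        if pool:
            chosen.append(pool.pop())
        b += 1
    return np.array(sorted(chosen), dtype=int)


def _sample_pairs(
    row_labels: np.ndarray,
    col_labels: np.ndarray,
    n: int,
    coherence: float,
    rng: np.random.Generator,
    active_rows: np.ndarray | None = None,
    active_cols: np.ndarray | None = None,
) -> np.ndarray:
    """Draw n distinct pairs; each is block-coherent with probability ``coherence``.

    Coherent draws come from same-block pairs of the active entities;
    incoherent draws are uniform over the full grid.
    """
    nr, nc = len(row_labels), len(col_labels)
    rows = np.arange(nr) if active_rows is None else active_rows
    cols = np.arange(nc) if active_cols is None else active_cols
    coherent = [
        (int(i), int(j)) for i in rows for j in cols if row_labels[i] == col_labels[j]
    ]
    everything = [(i, j) for i in range(nr) for j in range(nc)]
    rng.shuffle(coherent)
    rng.shuffle(everything)
    chosen: set[tuple[int, int]] = set()
    ci = ei = 0
    for _ in range(n):
        if rng.random() < coherence:
            while ci < len(coherent) and coherent[ci] in chosen:
                ci += 1
            if ci >= len(coherent):
                raise ValidationError(
                    "infeasible spec: requested coherent associations exceed the "
                    "available same-block pairs"
                )
            chosen.add(coherent[ci])
        else:
            while ei < len(everything) and everything[ei] in chosen:
                ei += 1
            if ei >= len(everything):
                raise ValidationError("requested associations exceed available pairs")
            chosen.add(everything[ei])
    return np.array(sorted(chosen), dtype=int)


def _ids(prefix: str, n: int) -> EntityIndex:
    return EntityIndex(f"{prefix}{k:03d}" for k in range(1, n + 1))


def generate(spec: SyntheticSpec, regime: str = "sparse") -> SyntheticDataset:
    """Generate a full triple-layer dataset from ``spec``.

    ``regime="sparse"`` keeps all entities; ``regime="dense"`` drops SMs and
    miRNAs with no SM-miRNA association and diseases with no miRNA-disease
    association, so every remaining entity is associated.
    """
    if regime not in ("sparse", "dense"):
        raise ValidationError(f"unknown regime {regime!r}")
    sm_lab, mi_lab, di_lab = _labels(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 23]))

    s_sm = _block_similarity(sm_lab, spec, rng)
    s_mi = _block_similarity(mi_lab, spec, rng)
    s_di = _block_similarity(di_lab, spec, rng)

    active_sm = _active_subset(sm_lab, spec.frac_sm_active, rng)
    active_mi = _active_subset(mi_lab, spec.frac_mirna_active, rng)
    a_pairs = _sample_pairs(
        sm_lab, mi_lab, spec.n_assoc_sm, spec.coherence, rng, active_sm, active_mi
    )
    b_pairs = _sample_pairs(mi_lab, di_lab, spec.n_assoc_dis, spec.coherence, rng)
    A = np.zeros((spec.ns, spec.nm))
    A[a_pairs[:, 0], a_pairs[:, 1]] = 1.0
    B = np.zeros((spec.nm, spec.nd))
    B[b_pairs[:, 0], b_pairs[:, 1]] = 1.0

    sm_idx = _ids("SM", spec.ns)
    mi_idx = _ids("MIR", spec.nm)
    di_idx = _ids("DIS", spec.nd)

    if regime == "dense":
        keep_sm = A.sum(axis=1) > 0
        keep_mi = A.sum(axis=0) > 0
        A = A[np.ix_(keep_sm, keep_mi)]
        B = B[keep_mi, :]
        keep_di = B.sum(axis=0) > 0
        B = B[:, keep_di]
        sm_idx = EntityIndex(np.array(sm_idx.ids)[keep_sm])
        mi_idx = EntityIndex(np.array(mi_idx.ids)[keep_mi])
        di_idx = EntityIndex(np.array(di_idx.ids)[keep_di])
        s_sm = s_sm[np.ix_(keep_sm, keep_sm)]
        s_mi = s_mi[np.ix_(keep_mi, keep_mi)]
        s_di = s_di[np.ix_(keep_di, keep_di)]
        sm_lab, mi_lab, di_lab = sm_lab[keep_sm], mi_lab[keep_mi], di_lab[keep_di]

    universe = EntityUniverse(sm_idx, mi_idx, di_idx)
    return SyntheticDataset(
        universe=universe,
        A=AssociationMatrix(A, sm_idx, mi_idx, "sm", "mirna"),
        B=AssociationMatrix(B, mi_idx, di_idx, "mirna", "disease"),
        s_sm=SimilarityMatrix(s_sm, sm_idx, "synthetic_sm"),
        s_mirna=SimilarityMatrix(s_mi, mi_idx, "synthetic_mirna"),
        s_disease=SimilarityMatrix(s_di, di_idx, "synthetic_disease"),
        labels={"sm": sm_lab, "mirna": mi_lab, "disease": di_lab},
        spec=spec,
    )


def generate_annotation_sets(
    spec: SyntheticSpec,
    kind: str = "sm",
    pool_size: int = 20,
    pool_fraction: float = 1.0,
    n_noise: int = 0,
) -> AnnotationSets:
    """Annotation sets whose Jaccard similarity recovers the block structure.

    Each block owns a disjoint pool of ``pool_size`` items; every entity
    draws ``round(pool_fraction * pool_size)`` items from its block's pool
    plus ``n_noise`` private items.  With ``pool_fraction=1`` and no noise,
    within-block Jaccard is exactly 1 and between-block Jaccard 0.
    """
    if kind not in ("sm", "mirna", "disease"):
        raise ValidationError(f"unknown annotation kind {kind!r}")
    if not 0 < pool_fraction <= 1:
        raise ValidationError("pool_fraction must lie in (0, 1]")
    sm_lab, mi_lab, di_lab = _labels(spec)
    labels = {"sm": sm_lab, "mirna": mi_lab, "disease": di_lab}[kind]
    prefix = {"sm": "SM", "mirna": "MIR", "disease": "DIS"}[kind]
    index = _ids(prefix, len(labels))
    kind_tag = {"sm": 1, "mirna": 2, "disease": 3}[kind]
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 29, kind_tag]))
    take = max(1, round(pool_fraction * pool_size))
    sets = {}
    for pos, entity in enumerate(index):
        block = int(labels[pos])
        pool = [f"item_b{block}_{k}" for k in range(pool_size)]
        picked = set(rng.choice(pool, size=take, replace=False))
        picked |= {f"noise_{entity}_{k}" for k in range(n_noise)}
        sets[entity] = frozenset(picked)
    return AnnotationSets(sets, kind=f"synthetic_{kind}")
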