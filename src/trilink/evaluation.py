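"""Cross-validation protocols and ranking metrics for association prediction.

The protocols follow the standard link-prediction recipe for bipartite
association data: each known SM-miRNA association is held out (LOOCV) or
grouped into folds (k-fold), removed from the training matrix, the scorer is
re-run on the reduced data, and the held-out pair's score is ranked against
candidate pairs — every pair without a known association.  "Global" ranking
compares against all candidates; "local" ranking restricts candidates to the
pairs sharing the held-out pair's SM (or miRNA).

The per-test percentile is the fraction of candidates scored strictly below
the test pair plus half the ties; the AUC is the mean percentile over tests
(the rank-sum form of AUC).  A pooled ROC curve over (test, candidate)
labels is computed alongside.  The randomization control replaces the known
associations with uniformly random pairs; on clean data the resulting AUC
distribution should center on 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .nbi import nbi_scores
from .propagation import PropagationConfig, propagate
from .types import ValidationError

__all__ = [
    "SimilaritySet",
    "CVResult",
    "RandomizationResult",
    "tlhn_scorer",
    "nbi_scorer",
    "rank_percentile",
    "roc_auc",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "randomization_test",
]


class SimilaritySet(NamedTuple):
    """The three integrated similarity matrices (SM, miRNA, disease)."""

    sm: np.ndarray
    mirna: np.ndarray
    disease: np.ndarray


#: A scorer maps (A_train, B, sims, config) to an SM x miRNA score matrix.
Scorer = Callable[[np.ndarray, np.ndarray, SimilaritySet, PropagationConfig], np.ndarray]


def tlhn_scorer(A_train, B, sims: SimilaritySet, config: PropagationConfig) -> np.ndarray:
    """Triple-layer network propagation scorer (the main method)."""
    result = propagate(A_train, B, sims.sm, sims.mirna, sims.disease, config)
    return result.w_sm


def nbi_scorer(A_train, B=None, sims=None, config=None) -> np.ndarray:
    """NBI baseline scorer; uses only the training association matrix."""
    return nbi_scores(A_train)


def rank_percentile(test_score: float, candidate_scores: np.ndarray) -> float:
    """Fraction of candidates below the test score, ties counted half."""
    candidate_scores = np.asarray(candidate_scores, dtype=float)
    if candidate_scores.size == 0:
        raise ValidationError("empty candidate set")
    below = np.count_nonzero(candidate_scores < test_score)
    ties = np.count_nonzero(candidate_scores == test_score)
    return (below + 0.5 * ties) / candidate_scores.size


@dataclass
class CVResult:
    """Outcome of one cross-validation protocol."""

    per_test_percentiles: np.ndarray
    auc: float
    pooled_auc: float
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    per_repeat_aucs: list[float] | None = None
    settings: dict = field(default_factory=dict)

    @property
    def auc_sd(self) -> float | None:
        if not self.per_repeat_aucs or len(self.per_repeat_aucs) < 2:
            return None
        return float(np.std(self.per_repeat_aucs, ddof=1))


def roc_auc(
    test_scores: Sequence[float],
    candidate_scores: Sequence[np.ndarray] | np.ndarray,
    settings: dict | None = None,
) -> CVResult:
    """Aggregate held-out test scores against their candidate sets.

    ``candidate_scores`` is either one array per test or a single pooled
    array shared by all tests.  Tests with an empty candidate set are
    skipped with a warning.
    """
    test_scores = np.asarray(test_scores, dtype=float)
    if test_scores.size == 0:
        raise ValidationError("at least one test score is required")
    if isinstance(candidate_scores, np.ndarray) and candidate_scores.ndim == 1:
        candidate_scores = [candidate_scores] * test_scores.size
    if len(candidate_scores) != test_scores.size:
        raise ValidationError("one candidate set per test score is required")

    percentiles = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for t, cands in zip(test_scores, candidate_scores):
        cands = np.asarray(cands, dtype=float)
        if cands.size == 0:
            warnings.warn("skipping a test with an empty candidate set", stacklevel=2)
            continue
        percentiles.append(rank_percentile(t, cands))
        pooled_scores.append(np.concatenate(([t], cands)))
        pooled_labels.append(np.concatenate(([1], np.zeros(cands.size))))
    if not percentiles:
        raise ValidationError("every test had an empty candidate set")
    percentiles = np.asarray(percentiles)

    from sklearn.metrics import roc_curve

    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    roc_points = np.column_stack([fpr, tpr])
    pooled_auc = float(np.trapezoid(tpr, fpr))
    return CVResult(
        per_test_percentiles=percentiles,
        auc=float(percentiles.mean()),
        pooled_auc=pooled_auc,
        roc_points=roc_points,
        settings=settings or {},
    )


def _held_out_scores(
    scorer: Scorer,
    A: np.ndarray,
    B,
    sims: SimilaritySet,
    config: PropagationConfig,
    folds: Sequence[np.ndarray],
    candidate_mask_fn: Callable[[tuple[int, int]], np.ndarray],
):
    """Run the scorer once per fold with the fold's pairs zeroed out.

    Yields (pair, test_score, candidate_scores) per held-out pair.  Asserts
    the held-out edges really are absent from the training matrix (leakage
    guard) and aborts on scorer failure.
    """
    for fold in folds:
        A_train = A.copy()
        rows, cols = fold[:, 0], fold[:, 1]
        if not (A[rows, cols] == 1).all():
            raise ValidationError("fold contains pairs that are not known associations")
        A_train[rows, cols] = 0.0
        assert A_train.sum() == A.sum() - len(fold), "held-out pairs leaked into training"
        scores = scorer(A_train, B, sims, config)
        for i, j in fold:
            mask = candidate_mask_fn((int(i), int(j)))
            yield (int(i), int(j)), float(scores[i, j]), scores[mask]


def _known_pairs(A: np.ndarray) -> np.ndarray:
    pairs = np.argwhere(A == 1)
    if len(pairs) == 0:
        raise ValidationError("association matrix has no known pairs")
    return pairs


def _as_arrays(A, B, sims) -> tuple[np.ndarray, np.ndarray, SimilaritySet]:
    get = lambda x: np.asarray(getattr(x, "values", x), dtype=float)
    sims = SimilaritySet(get(sims[0]), get(sims[1]), get(sims[2]))
    return get(A), get(B), sims


def global_loocv(
    scorer: Scorer,
    A,
    B,
    sims: SimilaritySet,
    config: PropagationConfig | None = None,
) -> CVResult:
    """Global LOOCV: each known pair held out in turn, ranked against all
    pairs unknown in the *original* matrix."""
    A, B, sims = _as_arrays(A, B, sims)
    config = config or PropagationConfig()
    pairs = _known_pairs(A)
    if len(pairs) < 2:
        raise ValidationError("global LOOCV needs at least two known associations")
    candidate_mask = A == 0
    folds = [pairs[k : k + 1] for k in range(len(pairs))]
    tests, cands = [], []
    for _, t, c in _held_out_scores(
        scorer, A, B, sims, config, folds, lambda pair: candidate_mask
    ):
        tests.append(t)
        cands.append(c)
    return roc_auc(tests, cands, settings={"protocol": "global-loocv", "n_folds": len(pairs)})


def local_loocv(
    scorer: Scorer,
    A,
    B,
    sims: SimilaritySet,
    config: PropagationConfig | None = None,
    fixed: str = "sm",
) -> CVResult:
    """Local LOOCV: candidates restricted to the held-out pair's row (fixed
    SM, ranking miRNAs) or column (fixed miRNA, ranking SMs)."""
    if fixed not in ("sm", "mirna"):
        raise ValidationError(f"fixed must be 'sm' or 'mirna', got {fixed!r}")
    A, B, sims = _as_arrays(A, B, sims)
    config = config or PropagationConfig()
    pairs = _known_pairs(A)
    unknown = A == 0

    def candidate_mask(pair: tuple[int, int]) -> np.ndarray:
        i, j = pair
        mask = np.zeros_like(unknown)
        if fixed == "sm":
            mask[i, :] = unknown[i, :]
        else:
            mask[:, j] = unknown[:, j]
        return mask

    folds = [pairs[k : k + 1] for k in range(len(pairs))]
    tests, cands = [], []
    for _, t, c in _held_out_scores(scorer, A, B, sims, config, folds, candidate_mask):
        tests.append(t)
        cands.append(c)
    return roc_auc(
        tests, cands, settings={"protocol": f"local-loocv-{fixed}", "n_folds": len(pairs)}
    )


def kfold_cv(
    scorer: Scorer,
    A,
    B,
    sims: SimilaritySet,
    config: PropagationConfig | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold CV over the known pairs.

    Per repeat the known pairs are randomly split into ``k`` near-equal
    groups (sizes differ by at most one); each group is zeroed in turn and
    its pairs ranked against all unknown pairs.  Per-repeat AUCs are
    recorded; the headline AUC is their mean.
    """
    A, B, sims = _as_arrays(A, B, sims)
    config = config or PropagationConfig()
    if k < 2:
        raise ValidationError("k must be >= 2")
    pairs = _known_pairs(A)
    if k > len(pairs):
        raise ValidationError(f"k={k} exceeds the {len(pairs)} known associations")
    candidate_mask = A == 0
    rng = np.random.default_rng(seed)
    per_repeat: list[float] = []
    all_tests, all_cands = [], []
    for _ in range(repeats):
        perm = rng.permutation(len(pairs))
        folds = [pairs[idx] for idx in np.array_split(perm, k)]
        tests, cands = [], []
        for _, t, c in _held_out_scores(
            scorer, A, B, sims, config, folds, lambda pair: candidate_mask
        ):
            tests.append(t)
            cands.append(c)
        rep = roc_auc(tests, cands)
        per_repeat.append(rep.auc)
        all_tests.extend(tests)
        all_cands.extend(cands)
    result = roc_auc(
        all_tests,
        all_cands,
        settings={"protocol": "kfold", "k": k, "repeats": repeats, "seed": seed},
    )
    result.per_repeat_aucs = per_repeat
    result.auc = float(np.mean(per_repeat))
    return result


@dataclass
class RandomizationResult:
    """AUC distribution under randomly drawn association matrices."""

    aucs: np.ndarray
    mean: float
    sd: float
    t_statistic: float
    p_value: float
    settings: dict = field(default_factory=dict)


def randomization_test(
    shape: tuple[int, int],
    n_assoc: int,
    B,
    sims: SimilaritySet,
    config: PropagationConfig | None = None,
    repeats: int = 20,
    seed: int = 0,
    protocol: str = "global",
    scorer: Scorer = tlhn_scorer,
) -> RandomizationResult:
    """Control experiment: random association matrices should score AUC ~ 0.5.

    Per repeat, ``n_assoc`` distinct SM-miRNA pairs are drawn uniformly as
    the "known" set, the requested LOOCV protocol is run, and its AUC is
    recorded.  A two-sided one-sample t test against 0.5 summarizes whether
    the scorer extracts signal where there is none.
    """
    ns, nm = shape
    if repeats < 2:
        raise ValidationError("repeats must be >= 2 for the t test")
    if n_assoc >= ns * nm:
        raise ValidationError("n_assoc must leave at least one candidate pair")
    if protocol not in ("global", "local-sm", "local-mirna"):
        raise ValidationError(f"unknown protocol {protocol!r}")
    config = config or PropagationConfig()
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(repeats):
        cells = rng.choice(ns * nm, size=n_assoc, replace=False)
        A = np.zeros((ns, nm))
        A[np.unravel_index(cells, (ns, nm))] = 1.0
        if protocol == "global":
            res = global_loocv(scorer, A, B, sims, config)
        else:
            res = local_loocv(scorer, A, B, sims, config, fixed=protocol.split("-")[1])
        aucs.append(res.auc)
    aucs = np.asarray(aucs)
    t_stat, p_value = stats.ttest_1samp(aucs, 0.5)
    return RandomizationResult(
        aucs=aucs,
        mean=float(aucs.mean()),
        sd=float(aucs.std(ddof=1)),
        t_statistic=float(t_stat),
        p_value=float(p_value),
        settings={
            "protocol": protocol,
            "n_assoc": n_assoc,
            "repeats": repeats,
            "seed": seed,
            "shape": (ns, nm),
        },
    )
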