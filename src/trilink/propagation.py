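"""Triple-layer heterogeneous network propagation.

The predictor iterates two coupled score matrices — SM x miRNA (``W_sm``)
and miRNA x disease (``W_md``) — over the degree-normalized network:

    W_sm(k+1) = a * W_sm(k) @ (S_M @ W_md(k) @ S_D @ W_md(k).T) + (1 - a) * A
    W_md(k+1) = a * (W_sm(k).T @ S_S @ W_sm(k) @ S_M) @ W_md(k) + (1 - a) * B

with decay factor ``a`` in (0, 1), anchor matrices A/B (the normalized known
associations) and the three integrated similarities S_S, S_M, S_D.  Each
iteration propagates score mass along similarity edges and across both
bipartite layers; the (1 - a) anchor keeps known associations dominant and
makes the fixed point independent of the initialization.  Iteration stops
once the L1 change of both matrices falls below a cutoff.  A by-product
SM x disease score ``W_sd = W_sm @ S_M @ W_md`` is returned alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import ValidationError

__all__ = [
    "PropagationConfig",
    "ScoreMatrices",
    "normalize_bipartite",
    "normalize_similarity",
    "propagate",
    "sm_disease_scores",
]


class NonConvergenceWarning(UserWarning):
    """Raised as a warning when the iteration hits max_iter before the cutoff."""


@dataclass(frozen=True)
class PropagationConfig:
    """Tunable parameters of the propagation.

    alpha:     decay factor in (0, 1); 0.4 keeps slightly more weight on the
               known-association anchor than on propagated mass.
    cutoff:    L1 convergence threshold on the per-iteration change (1e-6).
    max_iter:  iteration cap; non-convergence is reported, not fatal.
    normalize: "symmetric" (D^-1/2 W D^-1/2, the default, bounds the spectral
               radius by 1) or "row" (row-stochastic, for sensitivity checks).
    """

    alpha: float = 0.4
    cutoff: float = 1e-6
    max_iter: int = 1000
    normalize: str = "symmetric"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.normalize not in ("symmetric", "row"):
            raise ValidationError(f"unknown normalization {self.normalize!r}")


@dataclass
class ScoreMatrices:
    """Propagation result: final scores plus the convergence trace."""

    w_sm: np.ndarray
    w_md: np.ndarray
    w_sd: np.ndarray
    n_iter: int
    residuals_sm: list[float] = field(default_factory=list)
    residuals_md: list[float] = field(default_factory=list)
    converged: bool = True


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def normalize_bipartite(W, scheme: str = "symmetric") -> np.ndarray:
    """Degree-normalize a nonnegative bipartite weight matrix.

    Symmetric scheme: ``W'(i,j) = W(i,j) / sqrt(r(i) c(j))`` with r/c the
    row/column sums, so each edge is damped by the degrees of both endpoints.
    Zero rows/columns stay zero.
    """
    W = _values(W)
    if (W < 0).any():
        raise ValidationError("bipartite matrix must be nonnegative")
    r = W.sum(axis=1)
    c = W.sum(axis=0)
    if scheme == "symmetric":
        with np.errstate(divide="ignore"):
            ri = np.where(r > 0, 1.0 / np.sqrt(np.where(r > 0, r, 1.0)), 0.0)
            ci = np.where(c > 0, 1.0 / np.sqrt(np.where(c > 0, c, 1.0)), 0.0)
        return W * ri[:, None] * ci[None, :]
    if scheme == "row":
        ri = np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0), 0.0)
        return W * ri[:, None]
    raise ValidationError(f"unknown normalization {scheme!r}")


def normalize_similarity(S, scheme: str = "symmetric") -> np.ndarray:
    """Degree-normalize a symmetric nonnegative similarity matrix.

    Symmetric scheme ``D^-1/2 S D^-1/2`` keeps the output symmetric with
    spectral radius <= 1; rows summing to zero are left zero.
    """
    S = _values(S)
    if (S < 0).any():
        raise ValidationError("similarity matrix must be nonnegative")
    d = S.sum(axis=1)
    if scheme == "symmetric":
        di = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        return S * di[:, None] * di[None, :]
    if scheme == "row":
        di = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
        return S * di[:, None]
    raise ValidationError(f"unknown normalization {scheme!r}")


def propagate(
    A,
    B,
    S_S,
    S_M,
    S_D,
    config: PropagationConfig | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> ScoreMatrices:
    """Run the propagation to its fixed point.

    ``A`` (ns x nm) and ``B`` (nm x nd) are the known association matrices;
    ``S_S``, ``S_M``, ``S_D`` the integrated SM/miRNA/disease similarities.
    All five are degree-normalized once before iterating.  ``init``
    optionally replaces the default start (the normalized A and B); the
    anchored update converges to the same fixed point either way.
    """
    config = config or PropagationConfig()
    A = _values(A)
    B = _values(B)
    ns, nm = A.shape
    nm2, nd = B.shape
    Ss, Sm, Sd = _values(S_S), _values(S_M), _values(S_D)
    if nm2 != nm or Ss.shape != (ns, ns) or Sm.shape != (nm, nm) or Sd.shape != (nd, nd):
        raise ValidationError(
            f"inconsistent shapes: A{A.shape} B{B.shape} "
            f"S_S{Ss.shape} S_M{Sm.shape} S_D{Sd.shape}"
        )
    An = normalize_bipartite(A, config.normalize)
    Bn = normalize_bipartite(B, config.normalize)
    Ss = normalize_similarity(Ss, config.normalize)
    Sm = normalize_similarity(Sm, config.normalize)
    Sd = normalize_similarity(Sd, config.normalize)

    if init is None:
        w_sm, w_md = An.copy(), Bn.copy()
    else:
        w_sm = np.asarray(init[0], dtype=float).copy()
        w_md = np.asarray(init[1], dtype=float).copy()
        if w_sm.shape != A.shape or w_md.shape != B.shape:
            raise ValidationError("init matrices must match A and B shapes")

    a = config.alpha
    res_sm: list[float] = []
    res_md: list[float] = []
    converged = False
    k = 0
    for k in range(1, config.max_iter + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            right = Sm @ w_md @ Sd @ w_md.T  # nm x nm: miRNA-miRNA flux via diseases
            left = w_sm.T @ Ss @ w_sm @ Sm  # nm x nm: miRNA-miRNA flux via SMs
            new_sm = a * (w_sm @ right) + (1.0 - a) * An
            new_md = a * (left @ w_md) + (1.0 - a) * Bn
        if not (np.isfinite(new_sm).all() and np.isfinite(new_md).all()):
            raise ArithmeticError(f"propagation produced non-finite values at iteration {k}")
        d_sm = float(np.abs(new_sm - w_sm).sum())
        d_md = float(np.abs(new_md - w_md).sum())
        res_sm.append(d_sm)
        res_md.append(d_md)
        w_sm, w_md = new_sm, new_md
        if d_sm < config.cutoff and d_md < config.cutoff:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"propagation did not converge within {config.max_iter} iterations "
            f"(last residuals {res_sm[-1]:.3g}, {res_md[-1]:.3g})",
            NonConvergenceWarning,
            stacklevel=2,
        )
    w_sd = sm_disease_scores(w_sm, Sm, w_md)
    return ScoreMatrices(
        w_sm=w_sm,
        w_md=w_md,
        w_sd=w_sd,
        n_iter=k,
        residuals_sm=res_sm,
        residuals_md=res_md,
        converged=converged,
    )


def sm_disease_scores(w_sm, S_M, w_md) -> np.ndarray:
    """By-product SM x disease score: ``W_sd = W_sm @ S_M @ W_md``."""
    return _values(w_sm) @ _values(S_M) @ _values(w_md)
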